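energy_mev,pe,incoherent,pair
1.00000000e-02,5.25973460e+01,1.92489219e-01,0.00000000e+00
1.12421004e-02,3.61626795e+01,1.91614448e-01,0.00000000e+00
1.26384820e-02,2.48633653e+01,1.90643452e-01,0.00000000e+00
1.42083083e-02,1.70947400e+01,1.89567247e-01,0.00000000e+00
1.59731228e-02,1.17535575e+01,1.88376398e-01,0.00000000e+00
1.79571449e-02,8.08130814e+00,1.87061091e-01,0.00000000e+00
2.01876025e-02,5.55649723e+00,1.85611241e-01,0.00000000e+00
2.26951054e-02,3.82058380e+00,1.84016630e-01,0.00000000e+00
2.55140652e-02,2.62706155e+00,1.82267078e-01,0.00000000e+00
2.86831681e-02,1.80645084e+00,1.80352658e-01,0.00000000e+00
3.22459055e-02,1.24222979e+00,1.78263955e-01,0.00000000e+00
3.62511705e-02,8.54286328e-01,1.75992356e-01,0.00000000e+00
4.07539297e-02,5.87541084e-01,1.73530383e-01,0.00000000e+00
4.58159767e-02,4.04125296e-01,1.70872050e-01,0.00000000e+00
5.15067808e-02,2.78002965e-01,1.68013240e-01,0.00000000e+00
5.79044398e-02,1.91273440e-01,1.64952073e-01,0.00000000e+00
6.50967523e-02,1.31629348e-01,1.61689259e-01,0.00000000e+00
7.31824222e-02,9.06088571e-02,1.58228395e-01,0.00000000e+00
8.22724134e-02,6.23940623e-02,1.54576191e-01,0.00000000e+00
9.24914728e-02,4.29848453e-02,1.50742585e-01,0.00000000e+00
1.03979842e-01,2.96308775e-02,1.46740729e-01,0.00000000e+00
1.16895182e-01,2.04411085e-02,1.42586825e-01,0.00000000e+00
1.31414736e-01,1.41152770e-02,1.38299798e-01,0.00000000e+00
1.47737765e-01,9.75931659e-03,1.33900823e-01,0.00000000e+00
1.66088278e-01,6.75844172e-03,1.29412706e-01,0.00000000e+00
1.86718109e-01,4.68988921e-03,1.24859177e-01,0.00000000e+00
2.09910372e-01,3.26292527e-03,1.20264127e-01,0.00000000e+00
2.35983347e-01,2.27759765e-03,1.15650851e-01,0.00000000e+00
2.65294846e-01,1.59637593e-03,1.11041358e-01,0.00000000e+00
2.98247129e-01,1.12465261e-03,1.06455801e-01,0.00000000e+00
3.35292415e-01,7.97336557e-04,1.01912058e-01,0.00000000e+00
3.76939098e-01,5.69634897e-04,9.74255068e-02,0.00000000e+00
4.23758716e-01,4.10714890e-04,9.30089692e-02,0.00000000e+00
4.76393801e-01,2.99345753e-04,8.86728342e-02,0.00000000e+00
5.35566692e-01,2.20901880e-04,8.44253082e-02,0.00000000e+00
6.02089449e-01,1.65302077e-04,8.02727582e-02,0.00000000e+00
6.76875001e-01,1.25592392e-04,7.62200981e-02,0.00000000e+00
7.60949669e-01,9.69714542e-05,7.22711746e-02,0.00000000e+00
8.55467254e-01,7.61200937e-05,6.84291157e-02,0.00000000e+00
9.61724871e-01,6.07401931e-05,6.46966149e-02,0.00000000e+00
1.08118075e+00,4.92374117e-05,6.10761396e-02,6.68446982e-07
1.21547425e+00,4.05028558e-05,5.75700579e-02,1.84652182e-05
1.36644835e+00,3.37627971e-05,5.41806916e-02,8.13862521e-05
1.53617495e+00,2.84751934e-05,5.09103077e-02,2.09379797e-04
1.72698329e+00,2.42584075e-05,4.77610633e-02,4.14026885e-04
1.94149195e+00,2.08420751e-05,4.47349231e-02,6.99929026e-04
2.18264473e+00,1.80332164e-05,4.18335628e-02,1.06633033e-03
2.45375111e+00,1.56928396e-05,3.90582736e-02,1.50866557e-03
2.75853162e+00,1.37197687e-05,3.64098776e-02,2.01989349e-03
3.10116893e+00,1.20394471e-05,3.38886609e-02,2.59156999e-03
3.48636523e+00,1.05961720e-05,3.14943290e-02,3.21466637e-03
3.91940677e+00,9.34769359e-06,2.92259849e-02,3.88016211e-03
4.40623643e+00,8.26144845e-06,2.70821293e-02,4.57945049e-03
4.95353521e+00,7.31192092e-06,2.50606809e-02,5.30459601e-03
5.56881399e+00,6.47878652e-06,2.31590133e-02,6.04847897e-03
6.26051657e+00,5.74559719e-06,2.13740053e-02,6.80485726e-03
7.03813555e+00,5.09884335e-06,1.97020994e-02,7.56836983e-03
7.91234262e+00,4.52727895e-06,1.81393674e-02,8.33450103e-03
8.89513497e+00,4.02143044e-06,1.66815773e-02,9.09952044e-03
1.00000000e+01,3.57323538e-06,1.53242612e-02,9.86040906e-03
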