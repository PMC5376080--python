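energy_mev,pe,incoherent,pair
1.00000000e-02,6.14729316e+01,1.84962049e-01,0.00000000e+00
1.12421004e-02,4.22650229e+01,1.84121485e-01,0.00000000e+00
1.26384820e-02,2.90590191e+01,1.83188460e-01,0.00000000e+00
1.42083083e-02,1.99794824e+01,1.82154339e-01,0.00000000e+00
1.59731228e-02,1.37370020e+01,1.81010057e-01,0.00000000e+00
1.79571449e-02,9.44507580e+00,1.79746184e-01,0.00000000e+00
2.01876025e-02,6.49421075e+00,1.78353030e-01,0.00000000e+00
2.26951054e-02,4.46536476e+00,1.76820775e-01,0.00000000e+00
2.55140652e-02,3.07043537e+00,1.75139638e-01,0.00000000e+00
2.86831681e-02,2.11134447e+00,1.73300081e-01,0.00000000e+00
3.22459055e-02,1.45190791e+00,1.71293055e-01,0.00000000e+00
3.62511705e-02,9.98495248e-01,1.69110285e-01,0.00000000e+00
4.07539297e-02,6.86732791e-01,1.66744586e-01,0.00000000e+00
4.58159767e-02,4.72361646e-01,1.64190206e-01,0.00000000e+00
5.15067808e-02,3.24952373e-01,1.61443188e-01,0.00000000e+00
5.79044398e-02,2.23583661e-01,1.58501726e-01,0.00000000e+00
6.50967523e-02,1.53871305e-01,1.55366502e-01,0.00000000e+00
7.31824222e-02,1.05925556e-01,1.52040973e-01,0.00000000e+00
8.22724134e-02,7.29467352e-02,1.48531586e-01,0.00000000e+00
9.24914728e-02,5.02596958e-02,1.44847891e-01,0.00000000e+00
1.03979842e-01,3.46499763e-02,1.41002525e-01,0.00000000e+00
1.16895182e-01,2.39073936e-02,1.37011057e-01,0.00000000e+00
1.31414736e-01,1.65122486e-02,1.32891671e-01,0.00000000e+00
1.47737765e-01,1.14195827e-02,1.28664715e-01,0.00000000e+00
1.66088278e-01,7.91084689e-03,1.24352103e-01,0.00000000e+00
1.86718109e-01,5.49191979e-03,1.19976637e-01,0.00000000e+00
2.09910372e-01,3.82299040e-03,1.15561274e-01,0.00000000e+00
2.35983347e-01,2.67034997e-03,1.11128397e-01,0.00000000e+00
2.65294846e-01,1.87324653e-03,1.06699156e-01,0.00000000e+00
2.98247129e-01,1.32109557e-03,1.02292913e-01,0.00000000e+00
3.35292415e-01,9.37810928e-04,9.79268512e-02,0.00000000e+00
3.76939098e-01,6.71031212e-04,9.36157435e-02,0.00000000e+00
4.23758716e-01,4.84711901e-04,8.93719118e-02,0.00000000e+00
4.76393801e-01,3.54031687e-04,8.52053387e-02,0.00000000e+00
5.35566692e-01,2.61889892e-04,8.11239095e-02,0.00000000e+00
6.02089449e-01,1.96497873e-04,7.71337423e-02,0.00000000e+00
6.76875001e-01,1.49722625e-04,7.32395590e-02,0.00000000e+00
7.60949669e-01,1.15947574e-04,6.94450557e-02,0.00000000e+00
8.55467254e-01,9.12890152e-05,6.57532380e-02,0.00000000e+00
9.61724871e-01,7.30570788e-05,6.21666944e-02,0.00000000e+00
1.08118075e+00,5.93848677e-05,5.86877955e-02,6.80090593e-07
1.21547425e+00,4.89732364e-05,5.53188169e-02,1.87868620e-05
1.36644835e+00,4.09151073e-05,5.20619897e-02,8.28039111e-05
1.53617495e+00,3.45744928e-05,4.89194920e-02,2.13026962e-04
1.72698329e+00,2.95031510e-05,4.58933969e-02,4.21238777e-04
1.94149195e+00,2.53831332e-05,4.29855920e-02,7.12121019e-04
2.18264473e+00,2.19871500e-05,4.01976876e-02,1.08490463e-03
2.45375111e+00,1.91512032e-05,3.75309243e-02,1.53494487e-03
2.75853162e+00,1.67556626e-05,3.49860921e-02,2.05507781e-03
3.10116893e+00,1.47121623e-05,3.25634660e-02,2.63671228e-03
3.48636523e+00,1.29545071e-05,3.02627630e-02,3.27066232e-03
3.91940677e+00,1.14323458e-05,2.80831211e-02,3.94775027e-03
4.40623643e+00,1.01067552e-05,2.60230996e-02,4.65921948e-03
4.95353521e+00,8.94714510e-06,2.40806987e-02,5.39699624e-03
5.56881399e+00,7.92907710e-06,2.22533946e-02,6.15383682e-03
6.26051657e+00,7.03271903e-06,2.05381882e-02,6.92339039e-03
7.03813555e+00,6.24174033e-06,1.89316612e-02,7.70020251e-03
7.91234262e+00,5.54251569e-06,1.74300388e-02,8.47967886e-03
8.89513497e+00,4.92354463e-06,1.60292547e-02,9.25802408e-03
1.00000000e+01,4.37502320e-06,1.47250156e-02,1.00321665e-02
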