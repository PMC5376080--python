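energy_mev,pe,incoherent,pair
1.00000000e-02,4.14349795e+01,1.86785823e-01,0.00000000e+00
1.12421004e-02,2.84880998e+01,1.85936971e-01,0.00000000e+00
1.26384820e-02,1.95867441e+01,1.84994746e-01,0.00000000e+00
1.42083083e-02,1.34667916e+01,1.83950429e-01,0.00000000e+00
1.59731228e-02,9.25912758e+00,1.82794864e-01,0.00000000e+00
1.79571449e-02,6.36621388e+00,1.81518529e-01,0.00000000e+00
2.01876025e-02,4.37722775e+00,1.80111638e-01,0.00000000e+00
2.26951054e-02,3.00971802e+00,1.78564275e-01,0.00000000e+00
2.55140652e-02,2.06949218e+00,1.76866561e-01,0.00000000e+00
2.86831681e-02,1.42303769e+00,1.75008865e-01,0.00000000e+00
3.22459055e-02,9.78561103e-01,1.72982049e-01,0.00000000e+00
3.62511705e-02,6.72951825e-01,1.70777757e-01,0.00000000e+00
4.07539297e-02,4.62819511e-01,1.68388731e-01,0.00000000e+00
4.58159767e-02,3.18331983e-01,1.65809164e-01,0.00000000e+00
5.15067808e-02,2.18978664e-01,1.63035060e-01,0.00000000e+00
5.79044398e-02,1.50657831e-01,1.60064594e-01,0.00000000e+00
6.50967523e-02,1.03674027e-01,1.56898456e-01,0.00000000e+00
7.31824222e-02,7.13612293e-02,1.53540137e-01,0.00000000e+00
8.22724134e-02,4.91362427e-02,1.49996147e-01,0.00000000e+00
9.24914728e-02,3.38478836e-02,1.46276129e-01,0.00000000e+00
1.03979842e-01,2.33295245e-02,1.42392847e-01,0.00000000e+00
1.16895182e-01,1.60914568e-02,1.38362022e-01,0.00000000e+00
1.31414736e-01,1.11093809e-02,1.34202018e-01,0.00000000e+00
1.47737765e-01,7.67898739e-03,1.29933383e-01,0.00000000e+00
1.66088278e-01,5.31597623e-03,1.25578247e-01,0.00000000e+00
1.86718109e-01,3.68731726e-03,1.21159638e-01,0.00000000e+00
2.09910372e-01,2.56398872e-03,1.16700738e-01,0.00000000e+00
2.35983347e-01,1.78848338e-03,1.12224152e-01,0.00000000e+00
2.65294846e-01,1.25246739e-03,1.07751237e-01,0.00000000e+00
2.98247129e-01,8.81419632e-04,1.03301548e-01,0.00000000e+00
3.35292415e-01,6.24070403e-04,9.88924357e-02,0.00000000e+00
3.76939098e-01,4.45139713e-04,9.45388193e-02,0.00000000e+00
4.23758716e-01,3.20344303e-04,9.02531423e-02,0.00000000e+00
4.76393801e-01,2.32964467e-04,8.60454857e-02,0.00000000e+00
5.35566692e-01,1.71483314e-04,8.19238126e-02,0.00000000e+00
6.02089449e-01,1.27963415e-04,7.78943013e-02,0.00000000e+00
6.76875001e-01,9.69304346e-05,7.39617202e-02,0.00000000e+00
7.60949669e-01,7.46053766e-05,7.01298022e-02,0.00000000e+00
8.55467254e-01,5.83765128e-05,6.64015822e-02,0.00000000e+00
9.61724871e-01,4.64361421e-05,6.27796743e-02,0.00000000e+00
1.08118075e+00,3.75306851e-05,5.92664726e-02,6.10485746e-07
1.21547425e+00,3.07887218e-05,5.58642750e-02,1.68640937e-05
1.36644835e+00,2.56026314e-05,5.25753346e-02,7.43292261e-05
1.53617495e+00,2.15471005e-05,4.94018511e-02,1.91224412e-04
1.72698329e+00,1.83229916e-05,4.63459178e-02,3.78126491e-04
1.94149195e+00,1.57186591e-05,4.34094412e-02,6.39237973e-04
2.18264473e+00,1.35832715e-05,4.05940474e-02,9.73868515e-04
2.45375111e+00,1.18083956e-05,3.79009891e-02,1.37784873e-03
2.75853162e+00,1.03152715e-05,3.53310642e-02,1.84474793e-03
3.10116893e+00,9.04600534e-06,3.28845504e-02,2.36685419e-03
3.48636523e+00,7.95746273e-06,3.05611618e-02,2.93592170e-03
3.91940677e+00,7.01702505e-06,2.83600281e-02,3.54371211e-03
4.40623643e+00,6.19963076e-06,2.62796942e-02,4.18236498e-03
4.95353521e+00,5.48570514e-06,2.43181407e-02,4.84463292e-03
5.56881399e+00,4.85970486e-06,2.24728189e-02,5.52401357e-03
6.26051657e+00,4.30908865e-06,2.07407001e-02,6.21480607e-03
7.03813555e+00,3.82358414e-06,1.91183323e-02,6.91211424e-03
7.91234262e+00,3.39466122e-06,1.76019036e-02,7.61181398e-03
8.89513497e+00,3.01514973e-06,1.61873074e-02,8.31049833e-03
1.00000000e+01,2.67895879e-06,1.48702081e-02,9.00541007e-03
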