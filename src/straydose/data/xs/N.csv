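energy_mev,pe,incoherent,pair
1.00000000e-02,3.64674638e+00,1.92753759e-01,0.00000000e+00
1.12421004e-02,2.50725361e+00,1.91877786e-01,0.00000000e+00
1.26384820e-02,1.72382158e+00,1.90905456e-01,0.00000000e+00
1.42083083e-02,1.18519033e+00,1.89827772e-01,0.00000000e+00
1.59731228e-02,8.14865872e-01,1.88635286e-01,0.00000000e+00
1.79571449e-02,5.60256711e-01,1.87318171e-01,0.00000000e+00
2.01876025e-02,3.85204868e-01,1.85866329e-01,0.00000000e+00
2.26951054e-02,2.64850826e-01,1.84269527e-01,0.00000000e+00
2.55140652e-02,1.82103037e-01,1.82517570e-01,0.00000000e+00
2.86831681e-02,1.25210627e-01,1.80600519e-01,0.00000000e+00
3.22459055e-02,8.60945625e-02,1.78508945e-01,0.00000000e+00
3.62511705e-02,5.92002963e-02,1.76234224e-01,0.00000000e+00
4.07539297e-02,4.07089273e-02,1.73768868e-01,0.00000000e+00
4.58159767e-02,2.79948553e-02,1.71106882e-01,0.00000000e+00
5.15067808e-02,1.92529050e-02,1.68244143e-01,0.00000000e+00
5.79044398e-02,1.32419644e-02,1.65178769e-01,0.00000000e+00
6.50967523e-02,9.10872997e-03,1.61911470e-01,0.00000000e+00
7.31824222e-02,6.26652696e-03,1.58445850e-01,0.00000000e+00
8.22724134e-02,4.31199520e-03,1.54788627e-01,0.00000000e+00
9.24914728e-02,2.96780858e-03,1.50949753e-01,0.00000000e+00
1.03979842e-01,2.04329316e-03,1.46942397e-01,0.00000000e+00
1.16895182e-01,1.40735108e-03,1.42782784e-01,0.00000000e+00
1.31414736e-01,9.69845052e-04,1.38489865e-01,0.00000000e+00
1.47737765e-01,6.68799621e-04,1.34084844e-01,0.00000000e+00
1.66088278e-01,4.61601736e-04,1.29590559e-01,0.00000000e+00
1.86718109e-01,3.18950837e-04,1.25030773e-01,0.00000000e+00
2.09910372e-01,2.20699366e-04,1.20429408e-01,0.00000000e+00
2.35983347e-01,1.52992975e-04,1.15809791e-01,0.00000000e+00
2.65294846e-01,1.06304322e-04,1.11193964e-01,0.00000000e+00
2.98247129e-01,7.40812174e-05,1.06602104e-01,0.00000000e+00
3.35292415e-01,5.18171783e-05,1.02052117e-01,0.00000000e+00
3.76939098e-01,3.64123786e-05,9.75593999e-02,0.00000000e+00
4.23758716e-01,2.57342714e-05,9.31367926e-02,0.00000000e+00
4.76393801e-01,1.83154855e-05,8.87946984e-02,0.00000000e+00
5.35566692e-01,1.31461061e-05,8.45413350e-02,0.00000000e+00
6.02089449e-01,9.53084819e-06,8.03830780e-02,0.00000000e+00
6.76875001e-01,6.99084671e-06,7.63248483e-02,0.00000000e+00
7.60949669e-01,5.19612335e-06,7.23704978e-02,0.00000000e+00
8.55467254e-01,3.91914558e-06,6.85231587e-02,0.00000000e+00
9.61724871e-01,3.00288828e-06,6.47855283e-02,0.00000000e+00
1.08118075e+00,2.33886718e-06,6.11600773e-02,3.14995594e-07
1.21547425e+00,1.85202910e-06,5.76491772e-02,8.70145655e-06
1.36644835e+00,1.49035724e-06,5.42551529e-02,3.83520481e-05
1.53617495e+00,1.21771879e-06,5.09802744e-02,9.86670823e-05
1.72698329e+00,1.00894247e-06,4.78267019e-02,1.95103947e-04
1.94149195e+00,8.46429691e-07,4.47964029e-02,3.29831034e-04
2.18264473e+00,7.17820586e-07,4.18910552e-02,5.02492144e-04
2.45375111e+00,6.14385834e-07,3.91119519e-02,7.10935976e-04
2.75853162e+00,5.29917782e-07,3.64599161e-02,9.51844449e-04
3.10116893e+00,4.59965252e-07,3.39352345e-02,1.22123841e-03
3.48636523e+00,4.01304931e-07,3.15376121e-02,1.51486321e-03
3.91940677e+00,3.51575707e-07,2.92661506e-02,1.82846808e-03
4.40623643e+00,3.09025274e-07,2.71193486e-02,2.15799722e-03
4.95353521e+00,2.72334143e-07,2.50951221e-02,2.49971115e-03
5.56881399e+00,2.40493078e-07,2.31908410e-02,2.85025481e-03
6.26051657e+00,2.12717421e-07,2.14033799e-02,3.20668671e-03
7.03813555e+00,1.88386950e-07,1.97291763e-02,3.56648054e-03
7.91234262e+00,1.67003419e-07,1.81642966e-02,3.92750835e-03
8.89513497e+00,1.48160377e-07,1.67045030e-02,4.28801225e-03
1.00000000e+01,1.31521545e-07,1.53453216e-02,4.64656957e-03
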