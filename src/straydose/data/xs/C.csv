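energy_mev,pe,incoherent,pair
1.00000000e-02,2.21556686e+00,1.92673519e-01,0.00000000e+00
1.12421004e-02,1.52327058e+00,1.91797910e-01,0.00000000e+00
1.26384820e-02,1.04729840e+00,1.90825985e-01,0.00000000e+00
1.42083083e-02,7.20054501e-01,1.89748750e-01,0.00000000e+00
1.59731228e-02,4.95065079e-01,1.88556760e-01,0.00000000e+00
1.79571449e-02,3.40378248e-01,1.87240193e-01,0.00000000e+00
2.01876025e-02,2.34026288e-01,1.85788956e-01,0.00000000e+00
2.26951054e-02,1.60905842e-01,1.84192818e-01,0.00000000e+00
2.55140652e-02,1.10632969e-01,1.82441590e-01,0.00000000e+00
2.86831681e-02,7.60684479e-02,1.80525338e-01,0.00000000e+00
3.22459055e-02,5.23038788e-02,1.78434635e-01,0.00000000e+00
3.62511705e-02,3.59646087e-02,1.76160861e-01,0.00000000e+00
4.07539297e-02,2.47304736e-02,1.73696530e-01,0.00000000e+00
4.58159767e-02,1.70062974e-02,1.71035653e-01,0.00000000e+00
5.15067808e-02,1.16953517e-02,1.68174105e-01,0.00000000e+00
5.79044398e-02,8.04360352e-03,1.65110007e-01,0.00000000e+00
6.50967523e-02,5.53263209e-03,1.61844069e-01,0.00000000e+00
7.31824222e-02,3.80600630e-03,1.58379892e-01,0.00000000e+00
8.22724134e-02,2.61866729e-03,1.54724191e-01,0.00000000e+00
9.24914728e-02,1.80212783e-03,1.50886915e-01,0.00000000e+00
1.03979842e-01,1.24054584e-03,1.46881227e-01,0.00000000e+00
1.16895182e-01,8.54274477e-04,1.42723345e-01,0.00000000e+00
1.31414736e-01,5.88552231e-04,1.38432214e-01,0.00000000e+00
1.47737765e-01,4.05727160e-04,1.34029027e-01,0.00000000e+00
1.66088278e-01,2.79910787e-04,1.29536612e-01,0.00000000e+00
1.86718109e-01,1.93302508e-04,1.24978724e-01,0.00000000e+00
2.09910372e-01,1.33662513e-04,1.20379275e-01,0.00000000e+00
2.35983347e-01,9.25743338e-05,1.15761582e-01,0.00000000e+00
2.65294846e-01,6.42502868e-05,1.11147675e-01,0.00000000e+00
2.98247129e-01,4.47101703e-05,1.06557727e-01,0.00000000e+00
3.35292415e-01,3.12165837e-05,1.02009635e-01,0.00000000e+00
3.76939098e-01,2.18866836e-05,9.75187874e-02,0.00000000e+00
4.23758716e-01,1.54252456e-05,9.30980212e-02,0.00000000e+00
4.76393801e-01,1.09411277e-05,8.87577345e-02,0.00000000e+00
5.35566692e-01,7.82107531e-06,8.45061417e-02,0.00000000e+00
6.02089449e-01,5.64295159e-06,8.03496158e-02,0.00000000e+00
6.76875001e-01,4.11607418e-06,7.62930754e-02,0.00000000e+00
7.60949669e-01,3.04018886e-06,7.23403711e-02,0.00000000e+00
8.55467254e-01,2.27725752e-06,6.84946335e-02,0.00000000e+00
9.61724871e-01,1.73205670e-06,6.47585590e-02,0.00000000e+00
1.08118075e+00,1.33883435e-06,6.11346173e-02,2.75506408e-07
1.21547425e+00,1.05213204e-06,5.76251787e-02,7.61060498e-06
1.36644835e+00,8.40471572e-07,5.42325673e-02,3.35440724e-05
1.53617495e+00,6.82011296e-07,5.09590520e-02,8.62977576e-05
1.72698329e+00,5.61556986e-07,4.78067924e-02,1.70644887e-04
1.94149195e+00,4.68504296e-07,4.47777548e-02,2.88482014e-04
2.18264473e+00,3.95421984e-07,4.18736166e-02,4.39497593e-04
2.45375111e+00,3.37075920e-07,3.90956702e-02,6.21810021e-04
2.75853162e+00,2.89756348e-07,3.64447384e-02,8.32517184e-04
3.10116893e+00,2.50813839e-07,3.39211077e-02,1.06813877e-03
3.48636523e+00,2.18338890e-07,3.15244834e-02,1.32495352e-03
3.91940677e+00,1.90940432e-07,2.92539675e-02,1.59924355e-03
4.40623643e+00,1.67592478e-07,2.71080592e-02,1.88746152e-03
4.95353521e+00,1.47527732e-07,2.50846753e-02,2.18633673e-03
5.56881399e+00,1.30163594e-07,2.31811870e-02,2.49293476e-03
6.26051657e+00,1.15050531e-07,2.13944699e-02,2.80468284e-03
7.03813555e+00,1.01835910e-07,1.97209633e-02,3.11937138e-03
7.91234262e+00,9.02385288e-08,1.81567350e-02,3.43513921e-03
8.89513497e+00,8.00305835e-08,1.66975492e-02,3.75044881e-03
1.00000000e+01,7.10247868e-08,1.53389335e-02,4.06405587e-03
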