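energy_mev,pe,incoherent,pair
1.00000000e-02,2.59658008e+01,1.85831426e-01,0.00000000e+00
1.12421004e-02,1.78524250e+01,1.84986912e-01,0.00000000e+00
1.26384820e-02,1.22742474e+01,1.84049501e-01,0.00000000e+00
1.42083083e-02,8.43908438e+00,1.83010519e-01,0.00000000e+00
1.59731228e-02,5.80228962e+00,1.81860859e-01,0.00000000e+00
1.79571449e-02,3.98940528e+00,1.80591045e-01,0.00000000e+00
2.01876025e-02,2.74298208e+00,1.79191343e-01,0.00000000e+00
2.26951054e-02,1.88601706e+00,1.77651886e-01,0.00000000e+00
2.55140652e-02,1.29681611e+00,1.75962847e-01,0.00000000e+00
2.86831681e-02,8.91711340e-01,1.74114643e-01,0.00000000e+00
3.22459055e-02,6.13178810e-01,1.72098184e-01,0.00000000e+00
3.62511705e-02,4.21669236e-01,1.69905155e-01,0.00000000e+00
4.07539297e-02,2.89991359e-01,1.67528336e-01,0.00000000e+00
4.58159767e-02,1.99450381e-01,1.64961949e-01,0.00000000e+00
5.15067808e-02,1.37193044e-01,1.62202019e-01,0.00000000e+00
5.79044398e-02,9.43823082e-02,1.59246732e-01,0.00000000e+00
6.50967523e-02,6.49423914e-02,1.56096771e-01,0.00000000e+00
7.31824222e-02,4.46959566e-02,1.52755611e-01,0.00000000e+00
8.22724134e-02,3.07709031e-02,1.49229729e-01,0.00000000e+00
9.24914728e-02,2.11925210e-02,1.45528720e-01,0.00000000e+00
1.03979842e-01,1.46030863e-02,1.41665280e-01,0.00000000e+00
1.16895182e-01,1.00690749e-02,1.37655050e-01,0.00000000e+00
1.31414736e-01,6.94861657e-03,1.33516302e-01,0.00000000e+00
1.47737765e-01,4.80036565e-03,1.29269478e-01,0.00000000e+00
1.66088278e-01,3.32084704e-03,1.24936595e-01,0.00000000e+00
1.86718109e-01,2.30137927e-03,1.20540564e-01,0.00000000e+00
2.09910372e-01,1.59845767e-03,1.16104447e-01,0.00000000e+00
2.35983347e-01,1.11339166e-03,1.11650734e-01,0.00000000e+00
2.65294846e-01,7.78304489e-04,1.07200674e-01,0.00000000e+00
2.98247129e-01,5.46507378e-04,1.02773721e-01,0.00000000e+00
3.35292415e-01,3.85881211e-04,9.83871369e-02,0.00000000e+00
3.76939098e-01,2.74326017e-04,9.40557657e-02,0.00000000e+00
4.23758716e-01,1.96632148e-04,8.97919868e-02,0.00000000e+00
4.76393801e-01,1.42328916e-04,8.56058295e-02,0.00000000e+00
5.35566692e-01,1.04205298e-04,8.15052163e-02,0.00000000e+00
6.02089449e-01,7.72927133e-05,7.74962942e-02,0.00000000e+00
6.76875001e-01,5.81655129e-05,7.35838070e-02,0.00000000e+00
7.60949669e-01,4.44599134e-05,6.97714684e-02,0.00000000e+00
8.55467254e-01,3.45431372e-05,6.60622981e-02,0.00000000e+00
9.61724871e-01,2.72858323e-05,6.24588966e-02,0.00000000e+00
1.08118075e+00,2.19055133e-05,5.89636458e-02,5.31445618e-07
1.21547425e+00,1.78588401e-05,5.55788320e-02,1.46806846e-05
1.36644835e+00,1.47674829e-05,5.23066967e-02,6.47057557e-05
1.53617495e+00,1.23670880e-05,4.91494284e-02,1.66466419e-04
1.72698329e+00,1.04721316e-05,4.61091097e-02,3.29170121e-04
1.94149195e+00,8.95170448e-06,4.31876373e-02,5.56475269e-04
2.18264473e+00,7.71281698e-06,4.03866289e-02,8.47780899e-04
2.45375111e+00,6.68888027e-06,3.77073310e-02,1.19945744e-03
2.75853162e+00,5.83175010e-06,3.51505373e-02,1.60590679e-03
3.10116893e+00,5.10622435e-06,3.27165241e-02,2.06041549e-03
3.48636523e+00,4.48623120e-06,3.04050071e-02,2.55580533e-03
3.91940677e+00,3.95218264e-06,2.82151203e-02,3.08490457e-03
4.40623643e+00,3.48913223e-06,2.61454160e-02,3.64087050e-03
4.95353521e+00,3.08548811e-06,2.41938852e-02,4.21739402e-03
5.56881399e+00,2.73211018e-06,2.23579923e-02,4.80881466e-03
6.26051657e+00,2.42167330e-06,2.06347239e-02,5.41016965e-03
7.03813555e+00,2.14821516e-06,1.90206457e-02,6.01719672e-03
7.91234262e+00,1.90681279e-06,1.75119653e-02,6.62630571e-03
8.89513497e+00,1.69334877e-06,1.61045971e-02,7.23453079e-03
1.00000000e+01,1.50434049e-06,1.47942276e-02,7.83947169e-03
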