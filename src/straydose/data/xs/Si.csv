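energy_mev,pe,incoherent,pair
1.00000000e-02,3.41306149e+01,1.92266470e-01,0.00000000e+00
1.12421004e-02,2.34660526e+01,1.91392712e-01,0.00000000e+00
1.26384820e-02,1.61338590e+01,1.90422839e-01,0.00000000e+00
1.42083083e-02,1.10927554e+01,1.89347880e-01,0.00000000e+00
1.59731228e-02,7.62683665e+00,1.88158408e-01,0.00000000e+00
1.79571449e-02,5.24390012e+00,1.86844623e-01,0.00000000e+00
2.01876025e-02,3.60554391e+00,1.85396452e-01,0.00000000e+00
2.26951054e-02,2.47910808e+00,1.83803686e-01,0.00000000e+00
2.55140652e-02,1.70463289e+00,1.82056158e-01,0.00000000e+00
2.86831681e-02,1.17214178e+00,1.80143954e-01,0.00000000e+00
3.22459055e-02,8.06022893e-01,1.78057668e-01,0.00000000e+00
3.62511705e-02,5.54290999e-01,1.75788697e-01,0.00000000e+00
4.07539297e-02,3.81204746e-01,1.73329573e-01,0.00000000e+00
4.58159767e-02,2.62190886e-01,1.70674317e-01,0.00000000e+00
5.15067808e-02,1.80354535e-01,1.67818815e-01,0.00000000e+00
5.79044398e-02,1.24079891e-01,1.64761190e-01,0.00000000e+00
6.50967523e-02,8.53806673e-02,1.61502152e-01,0.00000000e+00
7.31824222e-02,5.87659719e-02,1.58045293e-01,0.00000000e+00
8.22724134e-02,4.04605726e-02,1.54397315e-01,0.00000000e+00
9.24914728e-02,2.78688070e-02,1.50568146e-01,0.00000000e+00
1.03979842e-01,1.92060063e-02,1.46570921e-01,0.00000000e+00
1.16895182e-01,1.32450898e-02,1.42421823e-01,0.00000000e+00
1.31414736e-01,9.14234034e-03,1.38139757e-01,0.00000000e+00
1.47737765e-01,6.31762040e-03,1.33745872e-01,0.00000000e+00
1.66088278e-01,4.37201665e-03,1.29262949e-01,0.00000000e+00
1.86718109e-01,3.03121787e-03,1.24714690e-01,0.00000000e+00
2.09910372e-01,2.10658516e-03,1.20124957e-01,0.00000000e+00
2.35983347e-01,1.46838624e-03,1.15517020e-01,0.00000000e+00
2.65294846e-01,1.02739281e-03,1.10912861e-01,0.00000000e+00
2.98247129e-01,7.22227821e-04,1.06332610e-01,0.00000000e+00
3.35292415e-01,5.10665996e-04,1.01794126e-01,0.00000000e+00
3.76939098e-01,3.63652365e-04,9.73127658e-02,0.00000000e+00
4.23758716e-01,2.61189521e-04,9.29013391e-02,0.00000000e+00
4.76393801e-01,1.89509719e-04,8.85702219e-02,0.00000000e+00
5.35566692e-01,1.39130360e-04,8.43276111e-02,0.00000000e+00
6.02089449e-01,1.03516863e-04,8.01798664e-02,0.00000000e+00
6.76875001e-01,7.81631410e-05,7.61318961e-02,0.00000000e+00
7.60949669e-01,5.99592314e-05,7.21875423e-02,0.00000000e+00
8.55467254e-01,4.67563548e-05,6.83499294e-02,0.00000000e+00
9.61724871e-01,3.70677418e-05,6.46217479e-02,0.00000000e+00
1.08118075e+00,2.98628127e-05,6.10054622e-02,5.89123636e-07
1.21547425e+00,2.44255562e-05,5.75034378e-02,1.62739855e-05
1.36644835e+00,2.02570594e-05,5.41179937e-02,7.17282987e-05
1.53617495e+00,1.70084025e-05,5.08513942e-02,1.84533090e-04
1.72698329e+00,1.44344429e-05,4.77057941e-02,3.64895093e-04
1.94149195e+00,1.23619668e-05,4.46831558e-02,6.16869765e-04
2.18264473e+00,1.06677299e-05,4.17851530e-02,9.39790919e-04
2.45375111e+00,9.26330236e-06,3.90130753e-02,1.32963507e-03
2.75853162e+00,8.08459814e-06,3.63677440e-02,1.78019653e-03
3.10116893e+00,7.08463175e-06,3.38494448e-02,2.28403325e-03
3.48636523e+00,6.22849787e-06,3.14578837e-02,2.83318796e-03
3.91940677e+00,5.48988396e-06,2.91921646e-02,3.41971057e-03
4.40623643e+00,4.84864099e-06,2.70507898e-02,4.03601571e-03
4.95353521e+00,4.28908489e-06,2.50316806e-02,4.67510958e-03
5.56881399e+00,3.79880371e-06,2.31322137e-02,5.33071735e-03
6.26051657e+00,3.36781507e-06,2.13492713e-02,5.99733765e-03
7.03813555e+00,2.98796712e-06,1.96793001e-02,6.67024562e-03
7.91234262e+00,2.65250888e-06,1.81183765e-02,7.34546147e-03
8.89513497e+00,2.35577917e-06,1.66622734e-02,8.01969747e-03
1.00000000e+01,2.09297878e-06,1.53065280e-02,8.69029287e-03
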