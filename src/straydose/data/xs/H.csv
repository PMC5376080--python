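energy_mev,pe,incoherent,pair
1.00000000e-02,1.34900441e-02,3.82639159e-01,0.00000000e+00
1.12421004e-02,9.27475673e-03,3.80900248e-01,0.00000000e+00
1.26384820e-02,6.37664125e-03,3.78970057e-01,0.00000000e+00
1.42083083e-02,4.38411391e-03,3.76830726e-01,0.00000000e+00
1.59731228e-02,3.01420077e-03,3.74463499e-01,0.00000000e+00
1.79571449e-02,2.07235033e-03,3.71848869e-01,0.00000000e+00
2.01876025e-02,1.42480363e-03,3.68966790e-01,0.00000000e+00
2.26951054e-02,9.79598108e-04,3.65796947e-01,0.00000000e+00
2.55140652e-02,6.73507243e-04,3.62319104e-01,0.00000000e+00
2.86831681e-02,4.63061233e-04,3.58513530e-01,0.00000000e+00
3.22459055e-02,3.18373515e-04,3.54361508e-01,0.00000000e+00
3.62511705e-02,2.18896334e-04,3.49845916e-01,0.00000000e+00
4.07539297e-02,1.50502594e-04,3.44951889e-01,0.00000000e+00
4.58159767e-02,1.03479563e-04,3.39667530e-01,0.00000000e+00
5.15067808e-02,7.11494881e-05,3.33984652e-01,0.00000000e+00
5.79044398e-02,4.89212460e-05,3.27899520e-01,0.00000000e+00
6.50967523e-02,3.36383186e-05,3.21413544e-01,0.00000000e+00
7.31824222e-02,2.31305165e-05,3.14533875e-01,0.00000000e+00
8.22724134e-02,1.59057756e-05,3.07273852e-01,0.00000000e+00
9.24914728e-02,1.09382605e-05,2.99653230e-01,0.00000000e+00
1.03979842e-01,7.52267952e-06,2.91698151e-01,0.00000000e+00
1.16895182e-01,5.17412362e-06,2.83440824e-01,0.00000000e+00
1.31414736e-01,3.55920229e-06,2.74918869e-01,0.00000000e+00
1.47737765e-01,2.44869827e-06,2.66174378e-01,0.00000000e+00
1.66088278e-01,1.68501625e-06,2.57252687e-01,0.00000000e+00
1.86718109e-01,1.15980308e-06,2.48200968e-01,0.00000000e+00
2.09910372e-01,7.98561101e-07,2.39066711e-01,0.00000000e+00
2.35983347e-01,5.50069349e-07,2.29896223e-01,0.00000000e+00
2.65294846e-01,3.79110394e-07,2.20733256e-01,0.00000000e+00
2.98247129e-01,2.61469816e-07,2.11617868e-01,0.00000000e+00
3.35292415e-01,1.80498207e-07,2.02585602e-01,0.00000000e+00
3.76939098e-01,1.24747446e-07,1.93667023e-01,0.00000000e+00
4.23758716e-01,8.63455628e-08,1.84887621e-01,0.00000000e+00
4.76393801e-01,5.98793971e-08,1.76268047e-01,0.00000000e+00
5.35566692e-01,4.16263928e-08,1.67824614e-01,0.00000000e+00
6.02089449e-01,2.90264207e-08,1.59569979e-01,0.00000000e+00
6.76875001e-01,2.03186355e-08,1.51513910e-01,0.00000000e+00
7.60949669e-01,1.42917953e-08,1.43664054e-01,0.00000000e+00
8.55467254e-01,1.01125926e-08,1.36026627e-01,0.00000000e+00
9.61724871e-01,7.20761948e-09,1.28606986e-01,0.00000000e+00
1.08118075e+00,5.18220927e-09,1.21410034e-01,1.56325938e-07
1.21547425e+00,3.76463250e-09,1.14440480e-01,4.31835679e-06
1.36644835e+00,2.76772462e-09,1.07702937e-01,1.90333453e-05
1.53617495e+00,2.06249954e-09,1.01201914e-01,4.89664761e-05
1.72698329e+00,1.56000408e-09,9.49416970e-02,9.68261403e-05
1.94149195e+00,1.19883871e-09,8.89261927e-02,1.63688467e-04
2.18264473e+00,9.36574499e-10,8.31587317e-02,2.49376681e-04
2.45375111e+00,7.43848994e-10,7.76418807e-02,3.52823137e-04
2.75853162e+00,6.00304458e-10,7.23772740e-02,4.72381137e-04
3.10116893e+00,4.91792926e-10,6.73654803e-02,6.06075906e-04
3.48636523e+00,4.08452546e-10,6.26059144e-02,7.51795954e-04
3.91940677e+00,3.43383163e-10,5.80967930e-02,9.07431703e-04
4.40623643e+00,2.91734109e-10,5.38351355e-02,1.07097035e-03
4.95353521e+00,2.50075572e-10,4.98168048e-02,1.24055605e-03
5.56881399e+00,2.15965090e-10,4.60365803e-02,1.41452378e-03
6.26051657e+00,1.87648356e-10,4.24882570e-02,1.59141372e-03
7.03813555e+00,1.63852476e-10,3.91647636e-02,1.76997211e-03
7.91234262e+00,1.43642916e-10,3.60582911e-02,1.94914291e-03
8.89513497e+00,1.26324336e-10,3.31604272e-02,2.12805370e-03
1.00000000e+01,1.11371683e-10,3.04622901e-02,2.30599844e-03
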