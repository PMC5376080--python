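energy_mev,pe,incoherent,pair
1.00000000e-02,2.35432337e+02,1.79572157e-01,0.00000000e+00
1.12421004e-02,1.61870161e+02,1.78756088e-01,0.00000000e+00
1.26384820e-02,1.11293851e+02,1.77850251e-01,0.00000000e+00
1.42083083e-02,7.65209430e+01,1.76846265e-01,0.00000000e+00
1.59731228e-02,5.26133100e+01,1.75735328e-01,0.00000000e+00
1.79571449e-02,3.61758645e+01,1.74508285e-01,0.00000000e+00
2.01876025e-02,2.48743956e+01,1.73155728e-01,0.00000000e+00
2.26951054e-02,1.71040717e+01,1.71668124e-01,0.00000000e+00
2.55140652e-02,1.17615283e+01,1.70035976e-01,0.00000000e+00
2.86831681e-02,8.08817140e+00,1.68250024e-01,0.00000000e+00
3.22459055e-02,5.56244624e+00,1.66301484e-01,0.00000000e+00
3.62511705e-02,3.82576830e+00,1.64182322e-01,0.00000000e+00
4.07539297e-02,2.63159952e+00,1.61885560e-01,0.00000000e+00
4.58159767e-02,1.81043674e+00,1.59405616e-01,0.00000000e+00
5.15067808e-02,1.24574045e+00,1.56738648e-01,0.00000000e+00
5.79044398e-02,8.57385157e-01,1.53882901e-01,0.00000000e+00
6.50967523e-02,5.90281064e-01,1.50839039e-01,0.00000000e+00
7.31824222e-02,4.06551220e-01,1.47610418e-01,0.00000000e+00
8.22724134e-02,2.80153072e-01,1.44203297e-01,0.00000000e+00
9.24914728e-02,1.93180637e-01,1.40626947e-01,0.00000000e+00
1.03979842e-01,1.33322145e-01,1.36893637e-01,0.00000000e+00
1.16895182e-01,9.21120923e-02,1.33018482e-01,0.00000000e+00
1.31414736e-01,6.37294708e-02,1.29019137e-01,0.00000000e+00
1.47737765e-01,4.41715131e-02,1.24915357e-01,0.00000000e+00
1.66088278e-01,3.06856122e-02,1.20728417e-01,0.00000000e+00
1.86718109e-01,2.13787439e-02,1.16480454e-01,0.00000000e+00
2.09910372e-01,1.49489276e-02,1.12193757e-01,0.00000000e+00
2.35983347e-01,1.05005929e-02,1.07890057e-01,0.00000000e+00
2.65294846e-01,7.41763328e-03,1.03589886e-01,0.00000000e+00
2.98247129e-01,5.27612268e-03,9.93120437e-02,0.00000000e+00
3.35292415e-01,3.78430100e-03,9.50732108e-02,0.00000000e+00
3.76939098e-01,2.74130869e-03,9.08877310e-02,0.00000000e+00
4.23758716e-01,2.00881211e-03,8.67675669e-02,0.00000000e+00
4.76393801e-01,1.49149194e-03,8.27224099e-02,0.00000000e+00
5.35566692e-01,1.12362568e-03,7.87599157e-02,0.00000000e+00
6.02089449e-01,8.59860137e-04,7.48860241e-02,0.00000000e+00
6.76875001e-01,6.68864986e-04,7.11053193e-02,0.00000000e+00
7.60949669e-01,5.28967442e-04,6.74213899e-02,0.00000000e+00
8.55467254e-01,4.25149136e-04,6.38371538e-02,0.00000000e+00
9.61724871e-01,3.46979787e-04,6.03551239e-02,0.00000000e+00
1.08118075e+00,2.87195118e-04,5.69776020e-02,9.90408588e-07
1.21547425e+00,2.40717851e-04,5.37067972e-02,2.73591043e-05
1.36644835e+00,2.03983485e-04,5.05448757e-02,1.20586442e-04
1.53617495e+00,1.74475739e-04,4.74939521e-02,3.10228865e-04
1.72698329e+00,1.50406257e-04,4.45560389e-02,6.13445484e-04
1.94149195e+00,1.30493595e-04,4.17329691e-02,1.03705415e-03
2.18264473e+00,1.13810557e-04,3.90263057e-02,1.57993491e-03
2.45375111e+00,9.96786078e-05,3.64372533e-02,2.23532364e-03
2.75853162e+00,8.75947034e-05,3.39665788e-02,2.99278763e-03
3.10116893e+00,7.71804948e-05,3.16145494e-02,3.83981563e-03
3.48636523e+00,6.81469527e-05,2.93808901e-02,4.76303023e-03
3.91940677e+00,6.02696513e-05,2.72647641e-02,5.74906609e-03
4.40623643e+00,5.33714215e-05,2.52647727e-02,6.78517103e-03
4.95353521e+00,4.73101117e-05,2.33789743e-02,7.85958735e-03
5.56881399e+00,4.19698934e-05,2.16049189e-02,8.96176612e-03
6.26051657e+00,3.72550348e-05,1.99396945e-02,1.00824587e-02
7.03813555e+00,3.30854000e-05,1.83799825e-02,1.12137218e-02
7.91234262e+00,2.93931574e-05,1.69221182e-02,1.23488648e-02
8.89513497e+00,2.61203420e-05,1.55621537e-02,1.34823605e-02
1.00000000e+01,2.32170242e-05,1.42959208e-02,1.46097358e-02
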