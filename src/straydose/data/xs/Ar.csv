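energy_mev,pe,incoherent,pair
1.00000000e-02,6.94720745e+01,1.73791051e-01,0.00000000e+00
1.12421004e-02,4.77647885e+01,1.73001254e-01,0.00000000e+00
1.26384820e-02,3.28403841e+01,1.72124580e-01,0.00000000e+00
1.42083083e-02,2.25793893e+01,1.71152916e-01,0.00000000e+00
1.59731228e-02,1.55246137e+01,1.70077744e-01,0.00000000e+00
1.79571449e-02,1.06742023e+01,1.68890204e-01,0.00000000e+00
2.01876025e-02,7.33935397e+00,1.67581192e-01,0.00000000e+00
2.26951054e-02,5.04650031e+00,1.66141479e-01,0.00000000e+00
2.55140652e-02,3.47005048e+00,1.64561876e-01,0.00000000e+00
2.86831681e-02,2.38615208e+00,1.62833421e-01,0.00000000e+00
3.22459055e-02,1.64090042e+00,1.60947612e-01,0.00000000e+00
3.62511705e-02,1.12848163e+00,1.58896673e-01,0.00000000e+00
4.07539297e-02,7.76145566e-01,1.56673853e-01,0.00000000e+00
4.58159767e-02,5.33874216e-01,1.54273748e-01,0.00000000e+00
5.15067808e-02,3.67278551e-01,1.51692639e-01,0.00000000e+00
5.79044398e-02,2.52714882e-01,1.48928830e-01,0.00000000e+00
6.50967523e-02,1.73927253e-01,1.45982961e-01,0.00000000e+00
7.31824222e-02,1.19738990e-01,1.42858282e-01,0.00000000e+00
8.22724134e-02,8.24655847e-02,1.39560849e-01,0.00000000e+00
9.24914728e-02,5.68235073e-02,1.36099634e-01,0.00000000e+00
1.03979842e-01,3.91799868e-02,1.32486514e-01,0.00000000e+00
1.16895182e-01,2.70372126e-02,1.28736115e-01,0.00000000e+00
1.31414736e-01,1.86777084e-02,1.24865524e-01,0.00000000e+00
1.47737765e-01,1.29205157e-02,1.20893860e-01,0.00000000e+00
1.66088278e-01,8.95356177e-03,1.16841713e-01,0.00000000e+00
1.86718109e-01,6.21840668e-03,1.12730509e-01,0.00000000e+00
2.09910372e-01,4.33100271e-03,1.08581816e-01,0.00000000e+00
2.35983347e-01,3.02721269e-03,1.04416668e-01,0.00000000e+00
2.65294846e-01,2.12535141e-03,1.00254936e-01,0.00000000e+00
2.98247129e-01,1.50043076e-03,9.61148141e-02,0.00000000e+00
3.35292415e-01,1.06645149e-03,9.20124452e-02,0.00000000e+00
3.76939098e-01,7.64227629e-04,8.79617119e-02,0.00000000e+00
4.23758716e-01,5.53014470e-04,8.39741914e-02,0.00000000e+00
4.76393801e-01,4.04752017e-04,8.00592633e-02,0.00000000e+00
5.35566692e-01,3.00106503e-04,7.62243367e-02,0.00000000e+00
6.02089449e-01,2.25748279e-04,7.24751603e-02,0.00000000e+00
6.76875001e-01,1.72479786e-04,6.88161707e-02,0.00000000e+00
7.60949669e-01,1.33948037e-04,6.52508409e-02,0.00000000e+00
8.55467254e-01,1.05759007e-04,6.17819948e-02,0.00000000e+00
9.61724871e-01,8.48684005e-05,5.84120646e-02,0.00000000e+00
1.08118075e+00,6.91624692e-05,5.51432779e-02,6.74516605e-07
1.21547425e+00,5.71695263e-05,5.19777727e-02,1.86328858e-05
1.36644835e+00,4.78613552e-05,4.89176453e-02,8.21252545e-05
1.53617495e+00,4.05164477e-05,4.59649425e-02,2.11281004e-04
1.72698329e+00,3.46257761e-05,4.31216119e-02,4.17786326e-04
1.94149195e+00,2.98278319e-05,4.03894273e-02,7.06284512e-04
2.18264473e+00,2.58638042e-05,3.77699016e-02,1.07601281e-03
2.45375111e+00,2.25466240e-05,3.52642006e-02,1.52236454e-03
2.75853162e+00,1.97395545e-05,3.28730665e-02,2.03823450e-03
3.10116893e+00,1.73413619e-05,3.05967577e-02,2.61510193e-03
3.48636523e+00,1.52760188e-05,2.84350083e-02,3.24385614e-03
3.91940677e+00,1.34855385e-05,2.63870084e-02,3.91539471e-03
4.40623643e+00,1.19249692e-05,2.44514043e-02,4.62103275e-03
4.95353521e+00,1.05588822e-05,2.26263169e-02,5.35276273e-03
5.56881399e+00,9.35889667e-06,2.09093750e-02,6.10340029e-03
6.26051657e+00,8.30192111e-06,1.92977605e-02,6.86664664e-03
7.03813555e+00,7.36889646e-06,1.77882615e-02,7.63709204e-03
7.91234262e+00,6.54388756e-06,1.63773314e-02,8.41017985e-03
8.89513497e+00,5.81341990e-06,1.50611493e-02,9.18214579e-03
1.00000000e+01,5.16598901e-06,1.38356812e-02,9.94994341e-03
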