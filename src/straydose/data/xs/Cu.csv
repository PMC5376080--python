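energy_mev,pe,incoherent,pair
1.00000000e-02,2.28358269e+02,1.76019071e-01,0.00000000e+00
1.12421004e-02,2.25774034e+02,1.75219149e-01,0.00000000e+00
1.26384820e-02,1.55231477e+02,1.74331236e-01,0.00000000e+00
1.42083083e-02,1.06731048e+02,1.73347115e-01,0.00000000e+00
1.59731228e-02,7.33851977e+01,1.72258159e-01,0.00000000e+00
1.79571449e-02,5.04585591e+01,1.71055395e-01,0.00000000e+00
2.01876025e-02,3.46954441e+01,1.69729601e-01,0.00000000e+00
2.26951054e-02,2.38574808e+01,1.68271431e-01,0.00000000e+00
2.55140652e-02,1.64057278e+01,1.66671577e-01,0.00000000e+00
2.86831681e-02,1.12821201e+01,1.64920963e-01,0.00000000e+00
3.22459055e-02,7.75920732e+00,1.63010978e-01,0.00000000e+00
3.62511705e-02,5.33684535e+00,1.60933746e-01,0.00000000e+00
4.07539297e-02,3.67116917e+00,1.58682429e-01,0.00000000e+00
4.58159767e-02,2.52575981e+00,1.56251554e-01,0.00000000e+00
5.15067808e-02,1.73807050e+00,1.53637355e-01,0.00000000e+00
5.79044398e-02,1.19634372e+00,1.50838114e-01,0.00000000e+00
6.50967523e-02,8.23741093e-01,1.47854479e-01,0.00000000e+00
7.31824222e-02,5.67432278e-01,1.44689740e-01,0.00000000e+00
8.22724134e-02,3.91093259e-01,1.41350034e-01,0.00000000e+00
9.24914728e-02,2.69748736e-01,1.37844447e-01,0.00000000e+00
1.03979842e-01,1.86226110e-01,1.34185006e-01,0.00000000e+00
1.16895182e-01,1.28717491e-01,1.30386526e-01,0.00000000e+00
1.31414736e-01,8.91035052e-02,1.26466314e-01,0.00000000e+00
1.47737765e-01,6.18008472e-02,1.22443732e-01,0.00000000e+00
1.66088278e-01,4.29699389e-02,1.18339637e-01,0.00000000e+00
1.86718109e-01,2.99701575e-02,1.14175726e-01,0.00000000e+00
2.09910372e-01,2.09852822e-02,1.09973847e-01,0.00000000e+00
2.35983347e-01,1.47659686e-02,1.05755301e-01,0.00000000e+00
2.65294846e-01,1.04526859e-02,1.01540215e-01,0.00000000e+00
2.98247129e-01,7.45397303e-03,9.73470165e-02,0.00000000e+00
3.35292415e-01,5.36272993e-03,9.31920548e-02,0.00000000e+00
3.76939098e-01,3.89865990e-03,8.90893906e-02,0.00000000e+00
4.23758716e-01,2.86869129e-03,8.50507497e-02,0.00000000e+00
4.76393801e-01,2.13976170e-03,8.10856318e-02,0.00000000e+00
5.35566692e-01,1.62010203e-03,7.72015411e-02,0.00000000e+00
6.02089449e-01,1.24636485e-03,7.34042998e-02,0.00000000e+00
6.76875001e-01,9.74771374e-04,6.96984015e-02,0.00000000e+00
7.60949669e-01,7.75021724e-04,6.60873638e-02,0.00000000e+00
8.55467254e-01,6.26105269e-04,6.25740467e-02,0.00000000e+00
9.61724871e-01,5.13417718e-04,5.91609137e-02,0.00000000e+00
1.08118075e+00,4.26776860e-04,5.58502207e-02,1.07867997e-06
1.21547425e+00,3.59056395e-04,5.26441334e-02,2.97975181e-05
1.36644835e+00,3.05244932e-04,4.95447749e-02,1.31333857e-04
1.53617495e+00,2.61797494e-04,4.65542181e-02,3.37878394e-04
1.72698329e+00,2.26188297e-04,4.36744356e-02,6.68119567e-04
1.94149195e+00,1.96602056e-04,4.09072241e-02,1.12948288e-03
2.18264473e+00,1.71720673e-04,3.82541158e-02,1.72074855e-03
2.45375111e+00,1.50575616e-04,3.57162915e-02,2.43454960e-03
2.75853162e+00,1.32445574e-04,3.32945028e-02,3.25952351e-03
3.10116893e+00,1.16785330e-04,3.09890114e-02,4.18204392e-03
3.48636523e+00,1.03176180e-04,2.87995482e-02,5.18754115e-03
3.91940677e+00,9.12912491e-05,2.67252927e-02,6.26145868e-03
4.40623643e+00,8.08711041e-05,2.47648740e-02,7.38990774e-03
4.95353521e+00,7.17065158e-05,2.29163887e-02,8.56008274e-03
5.56881399e+00,6.36261799e-05,2.11774355e-02,9.76049455e-03
6.26051657e+00,5.64878999e-05,1.95451599e-02,1.09810702e-02
7.03813555e+00,5.01721903e-05,1.80163090e-02,1.22131585e-02
7.91234262e+00,4.45775792e-05,1.65872906e-02,1.34494725e-02
8.89513497e+00,3.96171150e-05,1.52542348e-02,1.46839925e-02
1.00000000e+01,3.52157278e-05,1.40130561e-02,1.59118465e-02
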