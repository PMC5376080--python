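energy_mev,pe,incoherent,pair
1.00000000e-02,1.50329614e+01,1.84545585e-01,0.00000000e+00
1.12421004e-02,1.03356822e+01,1.83706914e-01,0.00000000e+00
1.26384820e-02,7.10617106e+00,1.82775989e-01,0.00000000e+00
1.42083083e-02,4.88578808e+00,1.81744197e-01,0.00000000e+00
1.59731228e-02,3.35920707e+00,1.80602491e-01,0.00000000e+00
1.79571449e-02,2.30963335e+00,1.79341464e-01,0.00000000e+00
2.01876025e-02,1.58801513e+00,1.77951447e-01,0.00000000e+00
2.26951054e-02,1.09187549e+00,1.76422642e-01,0.00000000e+00
2.55140652e-02,7.50758939e-01,1.74745290e-01,0.00000000e+00
2.86831681e-02,5.16225479e-01,1.72909875e-01,0.00000000e+00
3.22459055e-02,3.54971325e-01,1.70907368e-01,0.00000000e+00
3.62511705e-02,2.44099221e-01,1.68729513e-01,0.00000000e+00
4.07539297e-02,1.67866665e-01,1.66369141e-01,0.00000000e+00
4.58159767e-02,1.15450225e-01,1.63820512e-01,0.00000000e+00
5.15067808e-02,7.94084668e-02,1.61079679e-01,0.00000000e+00
5.79044398e-02,5.46251633e-02,1.58144840e-01,0.00000000e+00
6.50967523e-02,3.75827328e-02,1.55016676e-01,0.00000000e+00
7.31824222e-02,2.58627067e-02,1.51698635e-01,0.00000000e+00
8.22724134e-02,1.78022884e-02,1.48197150e-01,0.00000000e+00
9.24914728e-02,1.22582286e-02,1.44521749e-01,0.00000000e+00
1.03979842e-01,8.44448366e-03,1.40685041e-01,0.00000000e+00
1.16895182e-01,5.82060104e-03,1.36702560e-01,0.00000000e+00
1.31414736e-01,4.01498107e-03,1.32592450e-01,0.00000000e+00
1.47737765e-01,2.77211751e-03,1.28375011e-01,0.00000000e+00
1.66088278e-01,1.91632354e-03,1.24072109e-01,0.00000000e+00
1.86718109e-01,1.32679246e-03,1.19706496e-01,0.00000000e+00
2.09910372e-01,9.20450874e-04,1.15301074e-01,0.00000000e+00
2.35983347e-01,6.40169742e-04,1.10878178e-01,0.00000000e+00
2.65294846e-01,4.46658946e-04,1.06458910e-01,0.00000000e+00
2.98247129e-01,3.12894444e-04,1.02062589e-01,0.00000000e+00
3.35292415e-01,2.20286651e-04,9.77063573e-02,0.00000000e+00
3.76939098e-01,1.56045970e-04,9.34049565e-02,0.00000000e+00
4.23758716e-01,1.11371410e-04,8.91706804e-02,0.00000000e+00
4.76393801e-01,8.02051124e-05,8.50134888e-02,0.00000000e+00
5.35566692e-01,5.83759526e-05,8.09412494e-02,0.00000000e+00
6.02089449e-01,4.30106715e-05,7.69600666e-02,0.00000000e+00
6.76875001e-01,3.21289307e-05,7.30746514e-02,0.00000000e+00
7.60949669e-01,2.43648388e-05,6.92886920e-02,0.00000000e+00
8.55467254e-01,1.87754334e-05,6.56051868e-02,0.00000000e+00
9.61724871e-01,1.47089547e-05,6.20267187e-02,0.00000000e+00
1.08118075e+00,1.17142329e-05,5.85556530e-02,4.52372859e-07
1.21547425e+00,9.47834801e-06,5.51942601e-02,1.24963741e-05
1.36644835e+00,7.78373155e-06,5.19447660e-02,5.50783122e-05
1.53617495e+00,6.47863994e-06,4.88093440e-02,1.41698205e-04
1.72698329e+00,5.45682444e-06,4.57900625e-02,2.80193539e-04
1.94149195e+00,4.64352742e-06,4.28888049e-02,4.73678396e-04
2.18264473e+00,3.98583097e-06,4.01071778e-02,7.21641229e-04
2.45375111e+00,3.44600048e-06,3.74464190e-02,1.02099250e-03
2.75853162e+00,2.99688966e-06,3.49073168e-02,1.36696704e-03
3.10116893e+00,2.61876482e-06,3.24901455e-02,1.75385028e-03
3.48636523e+00,2.29710683e-06,3.01946229e-02,2.17553202e-03
3.91940677e+00,2.02108686e-06,2.80198887e-02,2.62590763e-03
4.40623643e+00,1.78250679e-06,2.59645055e-02,3.09915246e-03
4.95353521e+00,1.57506036e-06,2.40264781e-02,3.58989617e-03
5.56881399e+00,1.39381605e-06,2.22032885e-02,4.09332049e-03
6.26051657e+00,1.23485330e-06,2.04919441e-02,4.60520104e-03
7.03813555e+00,1.09500519e-06,1.88890343e-02,5.12190973e-03
7.91234262e+00,9.71675042e-07,1.73907930e-02,5.64039058e-03
8.89513497e+00,8.62704546e-07,1.59931630e-02,6.15811903e-03
1.00000000e+01,7.66278004e-07,1.46918605e-02,6.67305195e-03
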