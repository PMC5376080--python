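energy_mev,pe,incoherent,pair
1.00000000e-02,8.92230716e+01,1.87434272e-01,0.00000000e+00
1.12421004e-02,6.13444340e+01,1.86582474e-01,0.00000000e+00
1.26384820e-02,4.21770356e+01,1.85636977e-01,0.00000000e+00
1.42083083e-02,2.89988441e+01,1.84589034e-01,0.00000000e+00
1.59731228e-02,1.99383938e+01,1.83429458e-01,0.00000000e+00
1.79571449e-02,1.37090046e+01,1.82148692e-01,0.00000000e+00
2.01876025e-02,9.42605096e+00,1.80736917e-01,0.00000000e+00
2.26951054e-02,6.48133005e+00,1.79184182e-01,0.00000000e+00
2.55140652e-02,4.45668627e+00,1.77480574e-01,0.00000000e+00
2.86831681e-02,3.06462643e+00,1.75616429e-01,0.00000000e+00
3.22459055e-02,2.10749098e+00,1.73582577e-01,0.00000000e+00
3.62511705e-02,1.44938334e+00,1.71370632e-01,0.00000000e+00
4.07539297e-02,9.96870546e-01,1.68973313e-01,0.00000000e+00
4.58159767e-02,6.85714511e-01,1.66384790e-01,0.00000000e+00
5.15067808e-02,4.71749387e-01,1.63601055e-01,0.00000000e+00
5.79044398e-02,3.24609558e-01,1.60620278e-01,0.00000000e+00
6.50967523e-02,2.23417464e-01,1.57443148e-01,0.00000000e+00
7.31824222e-02,1.53818859e-01,1.54073170e-01,0.00000000e+00
8.22724134e-02,1.05944485e-01,1.50516876e-01,0.00000000e+00
9.24914728e-02,7.30086621e-02,1.46783944e-01,0.00000000e+00
1.03979842e-01,5.03457804e-02,1.42887181e-01,0.00000000e+00
1.16895182e-01,3.47478627e-02,1.38842362e-01,0.00000000e+00
1.31414736e-01,2.40091181e-02,1.34667916e-01,0.00000000e+00
1.47737765e-01,1.66128084e-02,1.30384462e-01,0.00000000e+00
1.66088278e-01,1.15159584e-02,1.26014207e-01,0.00000000e+00
1.86718109e-01,8.00133652e-03,1.21580258e-01,0.00000000e+00
2.09910372e-01,5.57568560e-03,1.17105879e-01,0.00000000e+00
2.35983347e-01,3.89975221e-03,1.12613752e-01,0.00000000e+00
2.65294846e-01,2.74017826e-03,1.08125308e-01,0.00000000e+00
2.98247129e-01,1.93642376e-03,1.03660172e-01,0.00000000e+00
3.35292415e-01,1.37802410e-03,9.92357524e-02,0.00000000e+00
3.76939098e-01,9.88952584e-04,9.48670220e-02,0.00000000e+00
4.23758716e-01,7.16868198e-04,9.05664668e-02,0.00000000e+00
4.76393801e-01,5.25722259e-04,8.63442028e-02,0.00000000e+00
5.35566692e-01,3.90674406e-04,8.22082208e-02,0.00000000e+00
6.02089449e-01,2.94596463e-04,7.81647205e-02,0.00000000e+00
6.76875001e-01,2.25668072e-04,7.42184871e-02,0.00000000e+00
7.60949669e-01,1.75723030e-04,7.03732661e-02,0.00000000e+00
8.55467254e-01,1.39111807e-04,6.66321032e-02,0.00000000e+00
9.61724871e-01,1.11919022e-04,6.29976213e-02,0.00000000e+00
1.08118075e+00,9.14250115e-05,5.94722231e-02,7.65756399e-07
1.21547425e+00,7.57352605e-05,5.60582144e-02,2.11532992e-05
1.36644835e+00,6.35252916e-05,5.27578561e-02,9.32340860e-05
1.53617495e+00,5.38649671e-05,4.95733554e-02,2.39860338e-04
1.72698329e+00,4.60974252e-05,4.65068132e-02,4.74299002e-04
1.94149195e+00,3.97556068e-05,4.35601423e-02,8.01821454e-04
2.18264473e+00,3.45046542e-05,4.07349744e-02,1.22156177e-03
2.45375111e+00,3.01021196e-05,3.80325669e-02,1.72829012e-03
2.75853162e+00,2.63704400e-05,3.54537202e-02,2.31394023e-03
3.10116893e+00,2.31778638e-05,3.29987130e-02,2.96883875e-03
3.48636523e+00,2.04252043e-05,3.06672585e-02,3.68264262e-03
3.91940677e+00,1.80366151e-05,2.84584833e-02,4.44501815e-03
4.40623643e+00,1.59531420e-05,2.63709273e-02,5.24610570e-03
4.95353521e+00,1.41281969e-05,2.44025640e-02,6.07681455e-03
5.56881399e+00,1.25243628e-05,2.25508360e-02,6.92898855e-03
6.26051657e+00,1.11111231e-05,2.08127039e-02,7.79547689e-03
7.03813555e+00,9.86323492e-06,1.91847039e-02,8.67013808e-03
7.91234262e+00,8.75955200e-06,1.76630107e-02,9.54779911e-03
8.89513497e+00,7.78216349e-06,1.62435035e-02,1.04241865e-02
1.00000000e+01,6.91575556e-06,1.49218318e-02,1.12958418e-02
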