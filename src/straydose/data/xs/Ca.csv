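energy_mev,pe,incoherent,pair
1.00000000e-02,1.08132482e+02,1.92474810e-01,0.00000000e+00
1.12421004e-02,7.43454789e+01,1.91600105e-01,0.00000000e+00
1.26384820e-02,5.11158946e+01,1.90629182e-01,0.00000000e+00
1.42083083e-02,3.51448154e+01,1.89553057e-01,0.00000000e+00
1.59731228e-02,2.41641547e+01,1.88362297e-01,0.00000000e+00
1.79571449e-02,1.66145457e+01,1.87047088e-01,0.00000000e+00
2.01876025e-02,1.14238837e+01,1.85597348e-01,0.00000000e+00
2.26951054e-02,7.85506870e+00,1.84002856e-01,0.00000000e+00
2.55140652e-02,5.40132513e+00,1.82253434e-01,0.00000000e+00
2.86831681e-02,3.71423102e+00,1.80339158e-01,0.00000000e+00
3.22459055e-02,2.55423659e+00,1.78250611e-01,0.00000000e+00
3.62511705e-02,1.75664445e+00,1.75979182e-01,0.00000000e+00
4.07539297e-02,1.20822022e+00,1.73517393e-01,0.00000000e+00
4.58159767e-02,8.31111666e-01,1.70859260e-01,0.00000000e+00
5.15067808e-02,5.71792728e-01,1.68000664e-01,0.00000000e+00
5.79044398e-02,3.93462290e-01,1.64939726e-01,0.00000000e+00
6.50967523e-02,2.70818100e-01,1.61677156e-01,0.00000000e+00
7.31824222e-02,1.86463728e-01,1.58216551e-01,0.00000000e+00
8.22724134e-02,1.28438242e-01,1.54564621e-01,0.00000000e+00
9.24914728e-02,8.85177995e-02,1.50731302e-01,0.00000000e+00
1.03979842e-01,6.10479456e-02,1.46729745e-01,0.00000000e+00
1.16895182e-01,4.21407801e-02,1.42576152e-01,0.00000000e+00
1.31414736e-01,2.91229888e-02,1.38289446e-01,0.00000000e+00
1.47737765e-01,2.01563472e-02,1.33890799e-01,0.00000000e+00
1.66088278e-01,1.39768032e-02,1.29403018e-01,0.00000000e+00
1.86718109e-01,9.71508742e-03,1.24849831e-01,0.00000000e+00
2.09910372e-01,6.77337599e-03,1.20255125e-01,0.00000000e+00
2.35983347e-01,4.74049001e-03,1.15642194e-01,0.00000000e+00
2.65294846e-01,3.33359141e-03,1.11033046e-01,0.00000000e+00
2.98247129e-01,2.35809530e-03,1.06447832e-01,0.00000000e+00
3.35292415e-01,1.68010703e-03,1.01904430e-01,0.00000000e+00
3.76939098e-01,1.20747041e-03,9.74182141e-02,0.00000000e+00
4.23758716e-01,8.76736582e-04,9.30020071e-02,0.00000000e+00
4.76393801e-01,6.44203508e-04,8.86661967e-02,0.00000000e+00
5.35566692e-01,4.79754360e-04,8.44189886e-02,0.00000000e+00
6.02089449e-01,3.62620268e-04,8.02667494e-02,0.00000000e+00
6.76875001e-01,2.78466255e-04,7.62143927e-02,0.00000000e+00
7.60949669e-01,2.17386974e-04,7.22657648e-02,0.00000000e+00
8.55467254e-01,1.72528051e-04,6.84239935e-02,0.00000000e+00
9.61724871e-01,1.39137611e-04,6.46917721e-02,0.00000000e+00
1.08118075e+00,1.13913645e-04,6.10715678e-02,8.25666815e-07
1.21547425e+00,9.45548263e-05,5.75657486e-02,2.28082680e-05
1.36644835e+00,7.94512612e-05,5.41766360e-02,1.00528433e-04
1.53617495e+00,6.74714890e-05,5.09064968e-02,2.58626270e-04
1.72698329e+00,5.78157043e-05,4.77574882e-02,5.11406691e-04
1.94149195e+00,4.99145421e-05,4.47315745e-02,8.64553488e-04
2.18264473e+00,4.33592233e-05,4.18304314e-02,1.31713299e-03
2.45375111e+00,3.78532894e-05,3.90553500e-02,1.86350620e-03
2.75853162e+00,3.31792085e-05,3.64071521e-02,2.49497577e-03
3.10116893e+00,2.91752269e-05,3.38861242e-02,3.20111153e-03
3.48636523e+00,2.57192877e-05,3.14919715e-02,3.97076121e-03
3.91940677e+00,2.27178244e-05,2.92237972e-02,4.79278264e-03
4.40623643e+00,2.00979250e-05,2.70801021e-02,5.65654480e-03
4.95353521e+00,1.78018260e-05,2.50588050e-02,6.55224575e-03
5.56881399e+00,1.57830223e-05,2.31572798e-02,7.47109121e-03
6.26051657e+00,1.40034998e-05,2.13724054e-02,8.40537092e-03
7.03813555e+00,1.24317496e-05,1.97006246e-02,9.34846291e-03
7.91234262e+00,1.10413285e-05,1.81380096e-02,1.02947894e-02
8.89513497e+00,9.80980503e-06,1.66803287e-02,1.12397427e-02
1.00000000e+01,8.71797475e-06,1.53231141e-02,1.21795935e-02
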