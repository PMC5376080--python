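energy_mev,pe,incoherent,pair
1.00000000e-02,2.05463663e+01,1.90430087e-01,0.00000000e+00
1.12421004e-02,1.41263539e+01,1.89564674e-01,0.00000000e+00
1.26384820e-02,9.71241365e+00,1.88604065e-01,0.00000000e+00
1.42083083e-02,6.67769977e+00,1.87539373e-01,0.00000000e+00
1.59731228e-02,4.59124016e+00,1.86361262e-01,0.00000000e+00
1.79571449e-02,3.15673070e+00,1.85060026e-01,0.00000000e+00
2.01876025e-02,2.17045483e+00,1.83625686e-01,0.00000000e+00
2.26951054e-02,1.49235222e+00,1.82048133e-01,0.00000000e+00
2.55140652e-02,1.02612779e+00,1.80317296e-01,0.00000000e+00
2.86831681e-02,7.05576148e-01,1.78423356e-01,0.00000000e+00
3.22459055e-02,4.85179314e-01,1.76356996e-01,0.00000000e+00
3.62511705e-02,3.33642436e-01,1.74109697e-01,0.00000000e+00
4.07539297e-02,2.29449418e-01,1.71674061e-01,0.00000000e+00
4.58159767e-02,1.57807312e-01,1.69044166e-01,0.00000000e+00
5.15067808e-02,1.08545511e-01,1.66215937e-01,0.00000000e+00
5.79044398e-02,7.46713920e-02,1.63187517e-01,0.00000000e+00
6.50967523e-02,5.13772789e-02,1.59959606e-01,0.00000000e+00
7.31824222e-02,3.53577121e-02,1.56535765e-01,0.00000000e+00
8.22724134e-02,2.43400482e-02,1.52922630e-01,0.00000000e+00
9.24914728e-02,1.67617368e-02,1.49130034e-01,0.00000000e+00
1.03979842e-01,1.15484398e-02,1.45170987e-01,0.00000000e+00
1.16895182e-01,7.96148194e-03,1.41061518e-01,0.00000000e+00
1.31414736e-01,5.49296900e-03,1.36820352e-01,0.00000000e+00
1.47737765e-01,3.79367856e-03,1.32468434e-01,0.00000000e+00
1.66088278e-01,2.62348243e-03,1.28028328e-01,0.00000000e+00
1.86718109e-01,1.81726066e-03,1.23523510e-01,0.00000000e+00
2.09910372e-01,1.26146614e-03,1.18977615e-01,0.00000000e+00
2.35983347e-01,8.78011913e-04,1.14413689e-01,0.00000000e+00
2.65294846e-01,6.13193001e-04,1.09853506e-01,0.00000000e+00
2.98247129e-01,4.30069669e-04,1.05317002e-01,0.00000000e+00
3.35292415e-01,3.03230481e-04,1.00821866e-01,0.00000000e+00
3.76939098e-01,2.15191591e-04,9.63833084e-02,0.00000000e+00
4.23758716e-01,1.53920982e-04,9.20140162e-02,0.00000000e+00
4.76393801e-01,1.11136171e-04,8.77242666e-02,0.00000000e+00
5.35566692e-01,8.11336927e-05,8.35221780e-02,0.00000000e+00
6.02089449e-01,5.99842227e-05,7.94140494e-02,0.00000000e+00
6.76875001e-01,4.49790897e-05,7.54047421e-02,0.00000000e+00
7.60949669e-01,3.42496436e-05,7.14980619e-02,0.00000000e+00
8.55467254e-01,2.65054732e-05,6.76971029e-02,0.00000000e+00
9.61724871e-01,2.08543470e-05,6.40045301e-02,0.00000000e+00
1.08118075e+00,1.66783491e-05,6.04227845e-02,5.05697205e-07
1.21547425e+00,1.35486575e-05,5.69542087e-02,1.39694089e-05
1.36644835e+00,1.11668979e-05,5.36010998e-02,6.15707773e-05
1.53617495e+00,9.32477390e-06,5.03657004e-02,1.58401161e-04
1.72698329e+00,7.87626878e-06,4.72501447e-02,3.13221907e-04
1.94149195e+00,6.71849479e-06,4.42563763e-02,5.29514175e-04
2.18264473e+00,5.77849236e-06,4.13860530e-02,8.06706118e-04
2.45375111e+00,5.00412375e-06,3.86404521e-02,1.14134402e-03
2.75853162e+00,4.35778510e-06,3.60203870e-02,1.52810099e-03
3.10116893e+00,3.81205915e-06,3.35261407e-02,1.96058885e-03
3.48636523e+00,3.34670496e-06,3.11574220e-02,2.43197717e-03
3.91940677e+00,2.94656914e-06,2.89133432e-02,2.93544169e-03
4.40623643e+00,2.60013284e-06,2.67924213e-02,3.46447120e-03
4.95353521e+00,2.29849762e-06,2.47925970e-02,4.01306229e-03
5.56881399e+00,2.03467481e-06,2.29112724e-02,4.57582874e-03
6.26051657e+00,1.80308494e-06,2.11453593e-02,5.14804823e-03
7.03813555e+00,1.59920302e-06,1.94913384e-02,5.72566498e-03
7.91234262e+00,1.41930511e-06,1.79453236e-02,6.30526278e-03
8.89513497e+00,1.26028577e-06,1.65031280e-02,6.88401950e-03
1.00000000e+01,1.11952502e-06,1.51603317e-02,7.45965116e-03
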