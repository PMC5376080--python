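energy_mev,pe,incoherent,pair
1.00000000e-02,7.24474110e+00,1.52642000e-01,0.00000000e+00
1.12421004e-02,7.24474110e+00,1.51948315e-01,0.00000000e+00
1.26384820e-02,7.24474110e+00,1.51178325e-01,0.00000000e+00
1.42083083e-02,7.24474110e+00,1.50324906e-01,0.00000000e+00
1.59731228e-02,7.24474110e+00,1.49380574e-01,0.00000000e+00
1.79571449e-02,7.24474110e+00,1.48337549e-01,0.00000000e+00
2.01876025e-02,7.24474110e+00,1.47187833e-01,0.00000000e+00
2.26951054e-02,7.24474110e+00,1.45923323e-01,0.00000000e+00
2.55140652e-02,7.24474110e+00,1.44535945e-01,0.00000000e+00
2.86831681e-02,7.24474110e+00,1.43017830e-01,0.00000000e+00
3.22459055e-02,7.24474110e+00,1.41361510e-01,0.00000000e+00
3.62511705e-02,7.24474110e+00,1.39560154e-01,0.00000000e+00
4.07539297e-02,7.24474110e+00,1.37607835e-01,0.00000000e+00
4.58159767e-02,7.24474110e+00,1.35499804e-01,0.00000000e+00
5.15067808e-02,7.24474110e+00,1.33232796e-01,0.00000000e+00
5.79044398e-02,7.24474110e+00,1.30805322e-01,0.00000000e+00
6.50967523e-02,7.24474110e+00,1.28217943e-01,0.00000000e+00
7.31824222e-02,7.24474110e+00,1.25473514e-01,0.00000000e+00
8.22724134e-02,7.24474110e+00,1.22577353e-01,0.00000000e+00
9.24914728e-02,6.83254871e+00,1.19537342e-01,0.00000000e+00
1.03979842e-01,4.74007680e+00,1.16363911e-01,0.00000000e+00
1.16895182e-01,3.29675195e+00,1.13069907e-01,0.00000000e+00
1.31414736e-01,2.30025079e+00,1.09670338e-01,0.00000000e+00
1.47737765e-01,1.61141366e+00,1.06181995e-01,0.00000000e+00
1.66088278e-01,1.13451388e+00,1.02622964e-01,0.00000000e+00
1.86718109e-01,8.03691645e-01,9.90120619e-02,0.00000000e+00
2.09910372e-01,5.73626330e-01,9.53682339e-02,0.00000000e+00
2.35983347e-01,4.13123000e-01,9.17099527e-02,0.00000000e+00
2.65294846e-01,3.00702424e-01,8.80546717e-02,0.00000000e+00
2.98247129e-01,2.21568692e-01,8.44183710e-02,0.00000000e+00
3.35292415e-01,1.65523977e-01,8.08152293e-02,0.00000000e+00
3.76939098e-01,1.25534539e-01,7.72574394e-02,0.00000000e+00
4.23758716e-01,9.67445119e-02,7.37551699e-02,0.00000000e+00
4.76393801e-01,7.57975780e-02,7.03166588e-02,0.00000000e+00
5.35566692e-01,6.03703630e-02,6.69484138e-02,0.00000000e+00
6.02089449e-01,4.88514140e-02,6.36554836e-02,0.00000000e+00
6.76875001e-01,4.01202970e-02,6.04417653e-02,0.00000000e+00
7.60949669e-01,3.33955489e-02,5.73103090e-02,0.00000000e+00
8.55467254e-01,2.81299876e-02,5.42635952e-02,0.00000000e+00
9.61724871e-01,2.39386001e-02,5.13037599e-02,0.00000000e+00
1.08118075e+00,2.05488414e-02,4.84327597e-02,2.58799703e-06
1.21547425e+00,1.77663579e-02,4.56524724e-02,7.14909802e-05
1.36644835e+00,1.54513243e-02,4.29647393e-02,3.15099604e-04
1.53617495e+00,1.35020905e-02,4.03713580e-02,8.10646629e-04
1.72698329e+00,1.18438620e-02,3.78740391e-02,1.60296984e-03
1.94149195e+00,1.04208506e-02,3.54743406e-02,2.70988469e-03
2.18264473e+00,9.19081760e-03,3.31735913e-02,4.12846466e-03
2.45375111e+00,8.12126900e-03,3.09728151e-02,5.84103471e-03
2.75853162e+00,7.18679204e-03,2.88726639e-02,7.82033355e-03
3.10116893e+00,6.36718200e-03,2.68733646e-02,1.00336685e-02
3.48636523e+00,5.64611672e-03,2.49746837e-02,1.24460836e-02
3.91940677e+00,5.01021200e-03,2.31759098e-02,1.50226545e-02
4.40623643e+00,4.44834244e-03,2.14758541e-02,1.77300588e-02
4.95353521e+00,3.95114817e-03,1.98728659e-02,2.05375731e-02
5.56881399e+00,3.51067216e-03,1.83648628e-02,2.34176323e-02
6.26051657e+00,3.12009004e-03,1.69493696e-02,2.63460692e-02
7.03813555e+00,2.77350573e-03,1.56235652e-02,2.93021275e-02
7.91234262e+00,2.46579441e-03,1.43843345e-02,3.22683242e-02
8.89513497e+00,2.19247988e-03,1.32283218e-02,3.52302166e-02
1.00000000e+01,1.94963712e-03,1.21519838e-02,3.81761158e-02
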