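energy_mev,pe,incoherent,pair
1.00000000e-02,5.31340739e-01,1.71194085e-01,0.00000000e+00
1.12421004e-02,3.65312237e-01,1.70416090e-01,0.00000000e+00
1.26384820e-02,2.51163311e-01,1.69552515e-01,0.00000000e+00
1.42083083e-02,1.72682889e-01,1.68595371e-01,0.00000000e+00
1.59731228e-02,1.18725463e-01,1.67536266e-01,0.00000000e+00
1.79571449e-02,8.16282206e-02,1.66366472e-01,0.00000000e+00
2.01876025e-02,5.61227872e-02,1.65077019e-01,0.00000000e+00
2.26951054e-02,3.85870248e-02,1.63658821e-01,0.00000000e+00
2.55140652e-02,2.65306231e-02,1.62102821e-01,0.00000000e+00
2.86831681e-02,1.82414307e-02,1.60400195e-01,0.00000000e+00
3.22459055e-02,1.25423002e-02,1.58542565e-01,0.00000000e+00
3.62511705e-02,8.62391254e-03,1.56522274e-01,0.00000000e+00
4.07539297e-02,5.92983970e-03,1.54332669e-01,0.00000000e+00
4.58159767e-02,4.07752266e-03,1.51968429e-01,0.00000000e+00
5.15067808e-02,2.80394171e-03,1.49425890e-01,0.00000000e+00
5.79044398e-02,1.92826345e-03,1.46703381e-01,0.00000000e+00
6.50967523e-02,1.32615966e-03,1.43801532e-01,0.00000000e+00
7.31824222e-02,9.12150932e-04,1.40723545e-01,0.00000000e+00
8.22724134e-02,6.27467414e-04,1.37475385e-01,0.00000000e+00
9.24914728e-02,4.31702824e-04,1.34065892e-01,0.00000000e+00
1.03979842e-01,2.97076337e-04,1.30506763e-01,0.00000000e+00
1.16895182e-01,2.04487495e-04,1.26812406e-01,0.00000000e+00
1.31414736e-01,1.40803860e-04,1.22999654e-01,0.00000000e+00
1.47737765e-01,9.69961924e-05,1.19087338e-01,0.00000000e+00
1.66088278e-01,6.68563474e-05,1.15095743e-01,0.00000000e+00
1.86718109e-01,4.61157848e-05,1.11045972e-01,0.00000000e+00
2.09910372e-01,3.18395228e-05,1.06959274e-01,0.00000000e+00
2.35983347e-01,2.20094614e-05,1.02856366e-01,0.00000000e+00
2.65294846e-01,1.52379049e-05,9.87568228e-02,0.00000000e+00
2.98247129e-01,1.05705979e-05,9.46785667e-02,0.00000000e+00
3.35292415e-01,7.35130632e-06,9.06374997e-02,0.00000000e+00
3.76939098e-01,5.12871011e-06,8.66472966e-02,0.00000000e+00
4.23758716e-01,3.59238885e-06,8.27193618e-02,0.00000000e+00
4.76393801e-01,2.52880792e-06,7.88629346e-02,0.00000000e+00
5.35566692e-01,1.79105656e-06,7.50853135e-02,0.00000000e+00
6.02089449e-01,1.27804063e-06,7.13921612e-02,0.00000000e+00
6.76875001e-01,9.20175951e-07,6.77878480e-02,0.00000000e+00
7.60949669e-01,6.69550957e-07,6.42757950e-02,0.00000000e+00
8.55467254e-01,4.93162369e-07,6.08587841e-02,0.00000000e+00
9.61724871e-01,3.68263663e-07,5.75392109e-02,0.00000000e+00
1.08118075e+00,2.79166271e-07,5.43192697e-02,1.74851915e-07
1.21547425e+00,2.15039640e-07,5.12010668e-02,4.83011944e-06
1.36644835e+00,1.68398112e-07,4.81866671e-02,2.12889615e-05
1.53617495e+00,1.34060081e-07,4.52780865e-02,5.47694273e-05
1.72698329e+00,1.08431902e-07,4.24772439e-02,1.08300876e-04
1.94149195e+00,8.90151362e-08,3.97858865e-02,1.83086967e-04
2.18264473e+00,7.40673867e-08,3.72055045e-02,2.78929976e-04
2.45375111e+00,6.23687801e-08,3.47372462e-02,3.94635733e-04
2.75853162e+00,5.30611133e-08,3.23818429e-02,5.28362390e-04
3.10116893e+00,4.55369960e-08,3.01395491e-02,6.77901146e-04
3.48636523e+00,3.93633954e-08,2.80101029e-02,8.40890282e-04
3.91940677e+00,3.42288593e-08,2.59927063e-02,1.01497021e-03
4.40623643e+00,2.99070423e-08,2.40860260e-02,1.19788960e-03
4.95353521e+00,2.62314614e-08,2.22882110e-02,1.38757268e-03
5.56881399e+00,2.30779912e-08,2.05969254e-02,1.58215709e-03
6.26051657e+00,2.03526955e-08,1.90093933e-02,1.78001002e-03
7.03813555e+00,1.79833443e-08,1.75224508e-02,1.97972913e-03
7.91234262e+00,1.59134756e-08,1.61326043e-02,2.18013321e-03
8.89513497e+00,1.40982198e-08,1.48360899e-02,2.38024648e-03
1.00000000e+01,1.25013463e-08,1.36289341e-02,2.57927922e-03
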