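energy_mev,pe,incoherent,pair
1.00000000e-02,5.61649622e+00,1.92862190e-01,0.00000000e+00
1.12421004e-02,3.86152340e+00,1.91985724e-01,0.00000000e+00
1.26384820e-02,2.65493174e+00,1.91012847e-01,0.00000000e+00
1.42083083e-02,1.82536606e+00,1.89934557e-01,0.00000000e+00
1.59731228e-02,1.25501546e+00,1.88741400e-01,0.00000000e+00
1.79571449e-02,8.62881979e-01,1.87423544e-01,0.00000000e+00
2.01876025e-02,5.93277518e-01,1.85970886e-01,0.00000000e+00
2.26951054e-02,4.07915094e-01,1.84373185e-01,0.00000000e+00
2.55140652e-02,2.80471434e-01,1.82620242e-01,0.00000000e+00
2.86831681e-02,1.92848613e-01,1.80702113e-01,0.00000000e+00
3.22459055e-02,1.32603832e-01,1.78609363e-01,0.00000000e+00
3.62511705e-02,9.11823386e-02,1.76333362e-01,0.00000000e+00
4.07539297e-02,6.27025072e-02,1.73866619e-01,0.00000000e+00
4.58159767e-02,4.31205548e-02,1.71203135e-01,0.00000000e+00
5.15067808e-02,2.96562634e-02,1.68338786e-01,0.00000000e+00
5.79044398e-02,2.03981482e-02,1.65271688e-01,0.00000000e+00
6.50967523e-02,1.40320018e-02,1.62002551e-01,0.00000000e+00
7.31824222e-02,9.65426145e-03,1.58534982e-01,0.00000000e+00
8.22724134e-02,6.64369373e-03,1.54875701e-01,0.00000000e+00
9.24914728e-02,4.57317503e-03,1.51034667e-01,0.00000000e+00
1.03979842e-01,3.14903811e-03,1.47025057e-01,0.00000000e+00
1.16895182e-01,2.16937128e-03,1.42863104e-01,0.00000000e+00
1.31414736e-01,1.49534792e-03,1.38567771e-01,0.00000000e+00
1.47737765e-01,1.03151478e-03,1.34160272e-01,0.00000000e+00
1.66088278e-01,7.12239580e-04,1.29663458e-01,0.00000000e+00
1.86718109e-01,4.92393319e-04,1.25101107e-01,0.00000000e+00
2.09910372e-01,3.40944091e-04,1.20497153e-01,0.00000000e+00
2.35983347e-01,2.36552592e-04,1.15874939e-01,0.00000000e+00
2.65294846e-01,1.64543870e-04,1.11256514e-01,0.00000000e+00
2.98247129e-01,1.14825286e-04,1.06662072e-01,0.00000000e+00
3.35292415e-01,8.04550096e-05,1.02109525e-01,0.00000000e+00
3.76939098e-01,5.66577903e-05,9.76142805e-02,0.00000000e+00
4.23758716e-01,4.01482366e-05,9.31891853e-02,0.00000000e+00
4.76393801e-01,2.86655256e-05,8.88446486e-02,0.00000000e+00
5.35566692e-01,2.06534747e-05,8.45888925e-02,0.00000000e+00
6.02089449e-01,1.50405593e-05,8.04282963e-02,0.00000000e+00
6.76875001e-01,1.10886468e-05,7.63677837e-02,0.00000000e+00
7.60949669e-01,8.28897811e-06,7.24112088e-02,0.00000000e+00
8.55467254e-01,6.29063497e-06,6.85617054e-02,0.00000000e+00
9.61724871e-01,4.85134374e-06,6.48219724e-02,0.00000000e+00
1.08118075e+00,3.80363813e-06,6.11944820e-02,3.54569389e-07
1.21547425e+00,3.03158286e-06,5.76816069e-02,9.79464536e-06
1.36644835e+00,2.45475961e-06,5.42856733e-02,4.31703253e-05
1.53617495e+00,2.01724734e-06,5.10089525e-02,1.11062909e-04
1.72698329e+00,1.68003723e-06,4.78536061e-02,2.19615412e-04
1.94149195e+00,1.41581009e-06,4.48216025e-02,3.71268648e-04
2.18264473e+00,1.20533884e-06,4.19146204e-02,5.65621665e-04
2.45375111e+00,1.03500905e-06,3.91339538e-02,8.00252891e-04
2.75853162e+00,8.95108783e-07,3.64804261e-02,1.07142738e-03
3.10116893e+00,7.78648025e-07,3.39543242e-02,1.37466607e-03
3.48636523e+00,6.80542717e-07,3.15553531e-02,1.70517980e-03
3.91940677e+00,5.97049929e-07,2.92826138e-02,2.05818374e-03
4.40623643e+00,5.25376141e-07,2.71346042e-02,2.42911256e-03
4.95353521e+00,4.63404896e-07,2.51092390e-02,2.81375699e-03
5.56881399e+00,4.09506877e-07,2.32038867e-02,3.20834045e-03
6.26051657e+00,3.62406930e-07,2.14154200e-02,3.60955191e-03
7.03813555e+00,3.21090523e-07,1.97402746e-02,4.01454766e-03
7.91234262e+00,2.84737532e-07,1.81745146e-02,4.42093242e-03
8.89513497e+00,2.52675041e-07,1.67138999e-02,4.82672746e-03
1.00000000e+01,2.24343394e-07,1.53539538e-02,5.23033136e-03
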