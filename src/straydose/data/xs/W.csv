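energy_mev,pe,incoherent,pair
1.00000000e-02,1.01036219e+01,1.55253591e-01,0.00000000e+00
1.12421004e-02,1.01036219e+01,1.54548038e-01,0.00000000e+00
1.26384820e-02,1.01036219e+01,1.53764874e-01,0.00000000e+00
1.42083083e-02,1.01036219e+01,1.52896853e-01,0.00000000e+00
1.59731228e-02,1.01036219e+01,1.51936365e-01,0.00000000e+00
1.79571449e-02,1.01036219e+01,1.50875494e-01,0.00000000e+00
2.01876025e-02,1.01036219e+01,1.49706108e-01,0.00000000e+00
2.26951054e-02,1.01036219e+01,1.48419962e-01,0.00000000e+00
2.55140652e-02,1.01036219e+01,1.47008848e-01,0.00000000e+00
2.86831681e-02,1.01036219e+01,1.45464759e-01,0.00000000e+00
3.22459055e-02,1.01036219e+01,1.43780100e-01,0.00000000e+00
3.62511705e-02,1.01036219e+01,1.41947925e-01,0.00000000e+00
4.07539297e-02,1.01036219e+01,1.39962203e-01,0.00000000e+00
4.58159767e-02,1.01036219e+01,1.37818105e-01,0.00000000e+00
5.15067808e-02,1.01036219e+01,1.35512311e-01,0.00000000e+00
5.79044398e-02,1.01036219e+01,1.33043304e-01,0.00000000e+00
6.50967523e-02,1.01036219e+01,1.30411657e-01,0.00000000e+00
7.31824222e-02,1.01036219e+01,1.27620272e-01,0.00000000e+00
8.22724134e-02,7.19149960e+00,1.24674560e-01,0.00000000e+00
9.24914728e-02,4.97658754e+00,1.21582538e-01,0.00000000e+00
1.03979842e-01,3.45021756e+00,1.18354811e-01,0.00000000e+00
1.16895182e-01,2.39763081e+00,1.15004449e-01,0.00000000e+00
1.31414736e-01,1.67113188e+00,1.11546716e-01,0.00000000e+00
1.47737765e-01,1.16913784e+00,1.07998690e-01,0.00000000e+00
1.66088278e-01,8.21773524e-01,1.04378767e-01,0.00000000e+00
1.86718109e-01,5.80967435e-01,1.00706085e-01,0.00000000e+00
2.09910372e-01,4.13642005e-01,9.69999135e-02,0.00000000e+00
2.35983347e-01,2.97031373e-01,9.32790419e-02,0.00000000e+00
2.65294846e-01,2.15461901e-01,8.95612217e-02,0.00000000e+00
2.98247129e-01,1.58138412e-01,8.58627067e-02,0.00000000e+00
3.35292415e-01,1.17621906e-01,8.21979179e-02,0.00000000e+00
3.76939098e-01,8.87827224e-02,7.85792569e-02,0.00000000e+00
4.23758716e-01,6.80806017e-02,7.50170661e-02,0.00000000e+00
4.76393801e-01,5.30695287e-02,7.15197246e-02,0.00000000e+00
5.35566692e-01,4.20571328e-02,6.80938514e-02,0.00000000e+00
6.02089449e-01,3.38703726e-02,6.47445817e-02,0.00000000e+00
6.76875001e-01,2.76943070e-02,6.14758790e-02,0.00000000e+00
7.60949669e-01,2.29611309e-02,5.82908458e-02,0.00000000e+00
8.55467254e-01,1.92737813e-02,5.51920050e-02,0.00000000e+00
9.61724871e-01,1.63533230e-02,5.21815291e-02,0.00000000e+00
1.08118075e+00,1.40026934e-02,4.92614082e-02,2.37856242e-06
1.21547425e+00,1.20817033e-02,4.64335523e-02,6.57055461e-05
1.36644835e+00,1.04897856e-02,4.36998341e-02,2.89600052e-04
1.53617495e+00,9.15407592e-03,4.10620819e-02,7.45044751e-04
1.72698329e+00,8.02116793e-03,3.85220358e-02,1.47324891e-03
1.94149195e+00,7.05139869e-03,3.60812803e-02,2.49058627e-03
2.18264473e+00,6.21487958e-03,3.37411669e-02,3.79436713e-03
2.45375111e+00,5.48873150e-03,3.15027370e-02,5.36834682e-03
2.75853162e+00,4.85515194e-03,2.93666537e-02,7.18747017e-03
3.10116893e+00,4.30005771e-03,2.73331479e-02,9.22169018e-03
3.48636523e+00,3.81212640e-03,2.54019820e-02,1.14388797e-02
3.91940677e+00,3.38211491e-03,2.35724324e-02,1.38069406e-02
4.40623643e+00,3.00237085e-03,2.18432900e-02,1.62952472e-02
4.95353521e+00,2.66647886e-03,2.02128759e-02,1.88755624e-02
5.56881399e+00,2.36900159e-03,1.86790720e-02,2.15225518e-02
6.26051657e+00,2.10528753e-03,1.72393607e-02,2.42140038e-02
7.03813555e+00,1.87132631e-03,1.58908728e-02,2.69308420e-02
7.91234262e+00,1.66363816e-03,1.46304398e-02,2.96569982e-02
8.89513497e+00,1.47918793e-03,1.34546485e-02,3.23791982e-02
1.00000000e+01,1.31531716e-03,1.23598953e-02,3.50866995e-02
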