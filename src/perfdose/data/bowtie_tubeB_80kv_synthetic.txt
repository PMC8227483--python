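# Synthetic Al-equivalent bowtie profile, tube B (additional to inherent filtration; see scripts/make_spectra.py)
# fan_angle_rad thickness_mm_Al
-0.272050 7.549557
-0.265249 7.048245
-0.258447 6.572476
-0.251646 6.121260
-0.244845 5.693636
-0.238044 5.288665
-0.231243 4.905437
-0.224441 4.543065
-0.217640 4.200690
-0.210839 3.877477
-0.204038 3.572617
-0.197236 3.285327
-0.190435 3.014850
-0.183634 2.760453
-0.176833 2.521431
-0.170031 2.297103
-0.163230 2.086814
-0.156429 1.889936
-0.149628 1.705865
-0.142826 1.534023
-0.136025 1.373859
-0.129224 1.224845
-0.122423 1.086482
-0.115621 0.958293
-0.108820 0.839831
-0.102019 0.730670
-0.095218 0.630414
-0.088416 0.538689
-0.081615 0.455150
-0.074814 0.379475
-0.068013 0.311369
-0.061211 0.250562
-0.054410 0.196811
-0.047609 0.149897
-0.040808 0.109628
-0.034006 0.075836
-0.027205 0.048381
-0.020404 0.027147
-0.013603 0.012044
-0.006801 0.003008
0.000000 0.000000
0.006801 0.003008
0.013602 0.012044
0.020404 0.027147
0.027205 0.048381
0.034006 0.075836
0.040807 0.109628
0.047609 0.149897
0.054410 0.196811
0.061211 0.250562
0.068012 0.311369
0.074814 0.379475
0.081615 0.455150
0.088416 0.538689
0.095218 0.630414
0.102019 0.730670
0.108820 0.839831
0.115621 0.958293
0.122422 1.086482
0.129224 1.224845
0.136025 1.373859
0.142826 1.534023
0.149627 1.705865
0.156429 1.889936
0.163230 2.086814
0.170031 2.297103
0.176833 2.521431
0.183634 2.760453
0.190435 3.014850
0.197236 3.285327
0.204037 3.572617
0.210839 3.877477
0.217640 4.200690
0.224441 4.543065
0.231243 4.905437
0.238044 5.288665
0.244845 5.693636
0.251646 6.121260
0.258447 6.572476
0.265249 7.048245
0.272050 7.549557
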