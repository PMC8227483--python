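# Synthetic Al-equivalent bowtie profile, tube A (additional to inherent filtration; see scripts/make_spectra.py)
# fan_angle_rad thickness_mm_Al
-0.397750 17.671501
-0.387806 16.340806
-0.377862 15.089601
-0.367919 13.914363
-0.357975 12.811660
-0.348031 11.778152
-0.338087 10.810591
-0.328144 9.905818
-0.318200 9.060769
-0.308256 8.272470
-0.298312 7.538037
-0.288369 6.854680
-0.278425 6.219700
-0.268481 5.630487
-0.258537 5.084526
-0.248594 4.579391
-0.238650 4.112749
-0.228706 3.682358
-0.218762 3.286067
-0.208819 2.921817
-0.198875 2.587641
-0.188931 2.281663
-0.178987 2.002098
-0.169044 1.747254
-0.159100 1.515528
-0.149156 1.305412
-0.139213 1.115486
-0.129269 0.944423
-0.119325 0.790989
-0.109381 0.654039
-0.099438 0.532521
-0.089494 0.425474
-0.079550 0.332028
-0.069606 0.251406
-0.059663 0.182922
-0.049719 0.125981
-0.039775 0.080079
-0.029831 0.044804
-0.019888 0.019837
-0.009944 0.004948
0.000000 0.000000
0.009944 0.004948
0.019888 0.019837
0.029831 0.044804
0.039775 0.080079
0.049719 0.125981
0.059663 0.182922
0.069606 0.251406
0.079550 0.332028
0.089494 0.425474
0.099437 0.532521
0.109381 0.654039
0.119325 0.790989
0.129269 0.944423
0.139213 1.115486
0.149156 1.305412
0.159100 1.515528
0.169044 1.747254
0.178988 2.002098
0.188931 2.281663
0.198875 2.587641
0.208819 2.921817
0.218763 3.286067
0.228706 3.682358
0.238650 4.112749
0.248594 4.579391
0.258537 5.084526
0.268481 5.630487
0.278425 6.219700
0.288369 6.854680
0.298312 7.538037
0.308256 8.272470
0.318200 9.060769
0.328144 9.905818
0.338087 10.810591
0.348031 11.778152
0.357975 12.811660
0.367919 13.914363
0.377862 15.089601
0.387806 16.340806
0.397750 17.671501
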