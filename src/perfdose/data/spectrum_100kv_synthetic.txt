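# Synthetic 100 kV tungsten spectrum (see scripts/make_spectra.py)
# energy_keV relative_fluence
1.0 0.00000000e+00
2.0 0.00000000e+00
3.0 0.00000000e+00
4.0 1.27275593e-306
5.0 8.34912675e-158
6.0 5.09538319e-92
7.0 1.39000322e-58
8.0 9.07521642e-40
9.0 1.97142282e-28
10.0 3.63828552e-21
11.0 2.52423932e-16
12.0 5.88427783e-13
13.0 1.52217897e-10
14.0 9.00665129e-09
15.0 1.92214930e-07
16.0 1.94716780e-06
17.0 1.17734317e-05
18.0 4.85762591e-05
19.0 1.50282305e-04
20.0 3.73040913e-04
21.0 7.48805229e-04
22.0 1.33041849e-03
23.0 2.14404807e-03
24.0 3.19350240e-03
25.0 4.46095216e-03
26.0 5.91146158e-03
27.0 7.49923171e-03
28.0 9.17382605e-03
29.0 1.08853329e-02
30.0 1.25880490e-02
31.0 1.40442075e-02
32.0 1.54206101e-02
33.0 1.66999795e-02
34.0 1.77400417e-02
35.0 1.86457151e-02
36.0 1.94432115e-02
37.0 2.01335674e-02
38.0 2.07195316e-02
39.0 2.12051236e-02
40.0 2.15952621e-02
41.0 2.17107700e-02
42.0 2.17627726e-02
43.0 2.17564038e-02
44.0 2.16966096e-02
45.0 2.15881110e-02
46.0 2.14353785e-02
47.0 2.12426196e-02
48.0 2.10137721e-02
49.0 2.07525057e-02
50.0 2.04622264e-02
51.0 2.00457614e-02
52.0 1.96185739e-02
53.0 1.91823085e-02
54.0 1.87384556e-02
55.0 1.82883643e-02
56.0 1.78332548e-02
57.0 1.73742293e-02
58.0 4.21055450e-02
59.0 6.27714065e-02
60.0 1.59831217e-02
61.0 1.54646167e-02
62.0 1.49526028e-02
63.0 1.44471443e-02
64.0 1.39482846e-02
65.0 1.34560488e-02
66.0 1.29704462e-02
67.0 1.89929586e-02
68.0 1.20191073e-02
69.0 1.48040685e-02
70.0 1.10940864e-02
71.0 1.06413454e-02
72.0 1.01950483e-02
73.0 9.75513548e-03
74.0 9.32154165e-03
75.0 8.89419711e-03
76.0 8.47302825e-03
77.0 8.05795818e-03
78.0 7.64890730e-03
79.0 7.24579379e-03
80.0 6.84853402e-03
81.0 6.44713921e-03
82.0 6.05294936e-03
83.0 5.66577381e-03
84.0 5.28542839e-03
85.0 4.91173515e-03
86.0 4.54452208e-03
87.0 4.18362293e-03
88.0 3.82887695e-03
89.0 3.48012867e-03
90.0 3.13722771e-03
91.0 2.80002859e-03
92.0 2.46839049e-03
93.0 2.14217713e-03
94.0 1.82125658e-03
95.0 1.50550106e-03
96.0 1.19478683e-03
97.0 8.88993997e-04
98.0 5.88006398e-04
99.0 2.91711446e-04
100.0 0.00000000e+00
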