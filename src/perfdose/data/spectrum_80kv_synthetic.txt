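# Synthetic 80 kV tungsten spectrum (see scripts/make_spectra.py)
# energy_keV relative_fluence
1.0 0.00000000e+00
2.0 0.00000000e+00
3.0 0.00000000e+00
4.0 2.08422895e-306
5.0 1.36344193e-157
6.0 8.29733550e-92
7.0 2.25690694e-58
8.0 1.46912786e-39
9.0 3.18166661e-28
10.0 5.85342750e-21
11.0 4.04806563e-16
12.0 9.40540163e-13
13.0 2.42481831e-10
14.0 1.42977193e-08
15.0 3.04046132e-07
16.0 3.06875348e-06
17.0 1.84851705e-05
18.0 7.59730983e-05
19.0 2.34104951e-04
20.0 5.78729557e-04
21.0 1.15678254e-03
22.0 2.04634850e-03
23.0 3.28304310e-03
24.0 4.86742891e-03
25.0 6.76685587e-03
26.0 8.92308123e-03
27.0 1.12623162e-02
28.0 1.37050077e-02
29.0 1.61737780e-02
30.0 1.85989455e-02
31.0 2.06301393e-02
32.0 2.25160298e-02
33.0 2.42324279e-02
34.0 2.55756374e-02
35.0 2.67015293e-02
36.0 2.76502230e-02
37.0 2.84253992e-02
38.0 2.90332376e-02
39.0 2.94817164e-02
40.0 2.97800316e-02
41.0 2.96855949e-02
42.0 2.94935984e-02
43.0 2.92127144e-02
44.0 2.88512267e-02
45.0 2.84169806e-02
46.0 2.79173537e-02
47.0 2.73592430e-02
48.0 2.67490639e-02
49.0 2.60927585e-02
50.0 2.53958101e-02
51.0 2.45404436e-02
52.0 2.36723931e-02
53.0 2.27942188e-02
54.0 2.19082276e-02
55.0 2.10164952e-02
56.0 2.01208867e-02
57.0 1.92230752e-02
58.0 2.28773301e-02
59.0 2.57979038e-02
60.0 1.65306353e-02
61.0 1.55842566e-02
62.0 1.46508776e-02
63.0 1.37305250e-02
64.0 1.28231941e-02
65.0 1.19288535e-02
66.0 1.10474481e-02
67.0 1.13538109e-02
68.0 9.32312301e-03
69.0 9.06745542e-03
70.0 7.64941500e-03
71.0 6.83123122e-03
72.0 6.02530700e-03
73.0 5.23149140e-03
74.0 4.44962674e-03
75.0 3.67954976e-03
76.0 2.92109269e-03
77.0 2.17408421e-03
78.0 1.43835023e-03
79.0 7.13714648e-04
80.0 0.00000000e+00
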