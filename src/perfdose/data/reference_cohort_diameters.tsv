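# Maximum effective diameter (mm) of each reference-cohort case, used for the
# <=32 cm / >32 cm protocol grouping.
case	effective_diameter_mm
1	313
2	331
3	320
4	272
5	276
6	292
7	245
8	256
9	297
10	251
11	322
12	316
13	342
14	312
15	313
16	329
17	332
18	304
19	322
20	354
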