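index	abbreviation	name	n_fibers
1	L-ATR	left anterior thalamic radiation	268
2	R-ATR	right anterior thalamic radiation	289
3	CC-FNR	corpus callosum, frontal	852
4	CC-OCC	corpus callosum, occipital	335
5	CC-PAR	corpus callosum, parietal	255
6	CC-POCG	corpus callosum, post-central gyrus	114
7	CC-PRCG	corpus callosum, pre-central gyrus	143
8	CC-TEM	corpus callosum, temporal	178
9	L-CGC	left cingulum	365
10	R-CGC	right cingulum	326
11	L-CST	left corticospinal tract	195
12	R-CST	right corticospinal tract	274
13	L-IFO	left inferior fronto-occipital fasciculus	377
14	R-IFO	right inferior fronto-occipital fasciculus	309
15	L-ILF	left inferior longitudinal fasciculus	353
16	R-ILF	right inferior longitudinal fasciculus	340
17	L-PHC	left parahippocampal cingulum	101
18	R-PHC	right parahippocampal cingulum	155
19	L-SLF	left superior longitudinal fasciculus	297
20	L-UNC	left uncinate fasciculus	183
21	R-UNC	right uncinate fasciculus	150
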