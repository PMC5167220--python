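group	n	age_mean	age_sd	n_male	n_female	mmse_mean	mmse_sd
control	33	59.4	9.6	14	19	29.1	0.9
bvFTD	20	60.7	10.7	8	12	24.1	4.7
EOAD	23	59.0	5.0	10	13	23.4	4.2
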