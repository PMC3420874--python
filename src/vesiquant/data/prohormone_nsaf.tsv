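protein	mean_nsaf_x1000	sd_x1000
CHGA	98.5	16.0
CHGB	56.3	2.0
PENK	1.5	0.5
NPY	7.4	2.2
PC1_3	4.42	0.8
PC2	13.8	1.5
PROSAAS	15.7	3.9
SCG5_7B2	4.3	0.9
CPE	26.7	3.2
PAM	3.3	1.5
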