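genotype	rate_yel068c	printed_fold_yel068c	rate_yel072w	printed_fold_yel072w	printed_ratio
Wild type	2.27e-9	1	1.97e-8	8.7	8.7
siz1Δ	3.13e-10	0.1	6.35e-8	28	203
siz2Δ	2.66e-9	1.2	3.71e-8	16.3	14
siz1Δ siz2Δ	7.14e-9	3.1	1.86e-7	82	26
mms21-11	1.06e-7	46.7	1.19e-5	5242	112
mms21-11 siz1Δ	3.46e-7	152	1.23e-5	5419	36
mms21-11 siz2Δ	3.22e-7	142	3.47e-5	15286	108
mms21-CH	2.08e-8	9.2	4.26e-6	1877	205
mms21-CH siz1Δ	4.6e-8	20.3	1.7e-5	7489	369
mms21-CH siz2Δ	2.2e-7	97	3.3e-5	14537	150
esc2Δ	2.1e-8	9.3	2.7e-6	1189	128
esc2Δ siz1Δ	3.7e-8	16.3	2.0e-6	881	54
esc2Δ siz2Δ	1.9e-8	8.4	1.7e-6	749	89
mms21-11 esc2Δ	2.86e-7	126	1.36e-5	5991	48
slx5Δ	1.48e-9	0.7	4.8e-7	211	324
slx5Δ siz1Δ	2.2e-8	9.7	6.7e-7	295	30
slx5Δ siz2Δ	9.5e-8	42	4.5e-6	1982	47
slx5Δ siz1Δ siz2Δ	9.9e-8	44	8.4e-6	3700	86
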