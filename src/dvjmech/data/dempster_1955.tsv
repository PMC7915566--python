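# Body segment inertial parameters after the classical cadaver fractions.
# Columns as in deleva_1996_male.tsv.
segment	mass_fraction	com_fraction	gyration_fraction	count
foot	0.0145	0.5000	0.4750	2
shank	0.0465	0.4330	0.3020	2
thigh	0.1000	0.4330	0.3230	2
hat	0.6780	0.5000	0.4000	1
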