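# PHR calibration ranges (log10 peak-height ratios) for RICA1b5-type
# L/R genotypes, from published calibration on individuals of known
# ploidy at genotype 120/136, applied unchanged to the analogous
# genotypes 122/137 and 123/137.  Closed intervals; class means where
# published.
locus	genotype	class	phr_min	phr_max	mean
Rica1b5	120/136	LLR	-0.54	-0.29	-0.39
Rica1b5	120/136	LR	-0.23	0.00
Rica1b5	120/136	LRR	0.09	0.25	0.17
Rica1b5	122/137	LLR	-0.54	-0.29	-0.39
Rica1b5	122/137	LR	-0.23	0.00
Rica1b5	122/137	LRR	0.09	0.25	0.17
Rica1b5	123/137	LLR	-0.54	-0.29	-0.39
Rica1b5	123/137	LR	-0.23	0.00
Rica1b5	123/137	LRR	0.09	0.25	0.17
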