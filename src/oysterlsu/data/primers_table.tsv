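# Study primers for the LSU rRNA splicing test (expected_length and
# annealing_temp_c are informational only; lengths are the published product
# sizes on the C. virginica (Cv) / A. irradians (Ai) templates).
# Note: the 3'-portion product is reported as 494 bp in the primer table and
# gel figure but 434 bp in the running text; the table/figure value is used
# here and the conflict is recorded rather than resolved.
region	name	sequence	role	expected_length	annealing_temp_c
5_prime_portion	mt168-F	GGATTCTGTTTGTCCGCAGCATT	forward	233	50
5_prime_portion	mt169-R	CACCATATAGCTATCTTTAGTTGA	reverse	233	50
3_prime_portion	mt89-F	CAGTACCTGCCCAGTGCGACAA	forward	494	58
3_prime_portion	16SBR	CCGGTCTGAACTCAGATCACGT	reverse	494	58
spanning	dCv-Ai-LSU-f	CTTTWGCAKMATGGCYTTWTGAG	forward	~773 (Cv) / 748 (Ai)	55
spanning	dCv-Ai-LSU-r	CACGGGGTCTTCTTGTCTWWCTTT	reverse	~773 (Cv) / 748 (Ai)	55
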