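# Synthetic allele -> 34-mer pseudo-sequence fixture (not NetMHCpan data).
# Generated with phlagraph.synth.gen_pseudo_table(8, seed=42).
HLA-A*01:01	CSQKKVCQFCMYRSRSMDTLMIEWSPKTMKLFCN
HLA-B*01:01	VCVTGPESRICYKVQSSEILLAMERQWRIYKHWI
HLA-C*01:01	CLSELDQLHFNQWKETPRCHSTKTTIVGFQPDTE
HLA-A*02:01	TASSSQLRGSNLMNADFDKQQLVNCSNPNNCNSH
HLA-B*02:01	PAHKYFGKYVAFTCVGWGKQDNMSYQKKKTHEHA
HLA-C*02:01	DCSRQLREWMWELQLKEIFHQPPIYCHDHYIWLQ
HLA-A*03:01	LGSYGSGRSKRGCCKWDLRFRHTNMELVASLRQK
HLA-B*03:01	HPDNCPPCSKSAELEHQDQDENSEGWYNKHPNGA
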