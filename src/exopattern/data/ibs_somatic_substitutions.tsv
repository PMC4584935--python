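# Substitution counts among inferred shared (identity-by-state) somatic SNVs
# from a familial colorectal-adenocarcinoma exome study (two tumor samples
# against three related controls and a positive somatic catalog).
# Rows: reference allele; columns: alternate allele.
ref	A	C	T	G
A	0	38	20	149
C	43	0	158	63
T	32	169	0	38
G	220	63	47	0
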