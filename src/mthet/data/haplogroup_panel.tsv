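# Macro-haplogroup marker panel for pair-concordance checking.
# Positions follow standard phylotree-style macro-haplogroup motifs;
# alt alleles are the transition partner of the bundled synthetic
# reference base (a real-data analysis should supply a real panel).
# H is the root label (reference-like backbone, no markers).
haplogroup	position	alt
H		
V	4580	G
U	11467	T
U	12308	T
U	12372	G
K	11467	T
K	12308	T
K	12372	G
K	1189	T
K	10550	T
K	14798	C
J	4216	G
J	10398	G
J	12612	G
J	13708	G
J	16069	T
T	4216	G
T	4917	C
T	13368	T
T	15607	T
W	1243	A
W	5460	T
W	8251	C
W	8994	A
X	6221	T
X	6371	T
X	14470	C
I	4529	G
I	8251	C
I	10034	A
I	10238	C
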