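# AGGRESCAN intrinsic aggregation-propensity values (a3v), one per amino acid.
# Conchillo-Sole et al. (2007) BMC Bioinformatics 8:65, Table 1.
aa	a3v
I	1.822
F	1.754
V	1.594
L	1.380
Y	1.159
W	1.037
M	0.910
C	0.604
A	-0.036
T	-0.159
S	-0.294
P	-0.334
G	-0.535
N	-0.850
K	-0.931
H	-1.033
Q	-1.231
R	-1.240
E	-1.412
D	-1.836
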