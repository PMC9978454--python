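context	alt	rate
ACA	A	2.000000e-09
ACA	G	2.000000e-09
ACA	T	8.000000e-09
ACC	A	2.000000e-09
ACC	G	2.000000e-09
ACC	T	8.000000e-09
ACG	A	2.000000e-09
ACG	G	2.000000e-09
ACG	T	8.000000e-08
ACT	A	2.000000e-09
ACT	G	2.000000e-09
ACT	T	8.000000e-09
ATA	A	2.000000e-09
ATA	C	8.000000e-09
ATA	G	2.000000e-09
ATC	A	2.000000e-09
ATC	C	8.000000e-09
ATC	G	2.000000e-09
ATG	A	2.000000e-09
ATG	C	8.000000e-09
ATG	G	2.000000e-09
ATT	A	2.000000e-09
ATT	C	8.000000e-09
ATT	G	2.000000e-09
CCA	A	2.000000e-09
CCA	G	2.000000e-09
CCA	T	8.000000e-09
CCC	A	2.000000e-09
CCC	G	2.000000e-09
CCC	T	8.000000e-09
CCG	A	2.000000e-09
CCG	G	2.000000e-09
CCG	T	8.000000e-08
CCT	A	2.000000e-09
CCT	G	2.000000e-09
CCT	T	8.000000e-09
CTA	A	2.000000e-09
CTA	C	8.000000e-09
CTA	G	2.000000e-09
CTC	A	2.000000e-09
CTC	C	8.000000e-09
CTC	G	2.000000e-09
CTG	A	2.000000e-09
CTG	C	8.000000e-09
CTG	G	2.000000e-09
CTT	A	2.000000e-09
CTT	C	8.000000e-09
CTT	G	2.000000e-09
GCA	A	2.000000e-09
GCA	G	2.000000e-09
GCA	T	8.000000e-09
GCC	A	2.000000e-09
GCC	G	2.000000e-09
GCC	T	8.000000e-09
GCG	A	2.000000e-09
GCG	G	2.000000e-09
GCG	T	8.000000e-08
GCT	A	2.000000e-09
GCT	G	2.000000e-09
GCT	T	8.000000e-09
GTA	A	2.000000e-09
GTA	C	8.000000e-09
GTA	G	2.000000e-09
GTC	A	2.000000e-09
GTC	C	8.000000e-09
GTC	G	2.000000e-09
GTG	A	2.000000e-09
GTG	C	8.000000e-09
GTG	G	2.000000e-09
GTT	A	2.000000e-09
GTT	C	8.000000e-09
GTT	G	2.000000e-09
TCA	A	2.000000e-09
TCA	G	2.000000e-09
TCA	T	8.000000e-09
TCC	A	2.000000e-09
TCC	G	2.000000e-09
TCC	T	8.000000e-09
TCG	A	2.000000e-09
TCG	G	2.000000e-09
TCG	T	8.000000e-08
TCT	A	2.000000e-09
TCT	G	2.000000e-09
TCT	T	8.000000e-09
TTA	A	2.000000e-09
TTA	C	8.000000e-09
TTA	G	2.000000e-09
TTC	A	2.000000e-09
TTC	C	8.000000e-09
TTC	G	2.000000e-09
TTG	A	2.000000e-09
TTG	C	8.000000e-09
TTG	G	2.000000e-09
TTT	A	2.000000e-09
TTT	C	8.000000e-09
TTT	G	2.000000e-09
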