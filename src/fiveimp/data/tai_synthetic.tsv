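codon	weight
TTT	0.5000
TTC	0.5614
TTA	0.2750
TTG	0.3932
CTT	0.4000
CTC	0.5455
CTA	0.2636
CTG	1.0000
ATT	0.4636
ATC	0.5727
ATA	0.2705
ATG	0.6000
GTT	0.3500
GTC	0.4295
GTA	0.2614
GTG	0.7386
TCT	0.4455
TCC	0.5023
TCA	0.3773
TCG	0.2000
CCT	0.4977
CCC	0.5500
CCA	0.4841
CCG	0.2568
ACT	0.3977
ACC	0.5295
ACA	0.4432
ACG	0.2386
GCT	0.5182
GCC	0.7295
GCA	0.4591
GCG	0.2682
TAT	0.3773
TAC	0.4477
CAT	0.3477
CAC	0.4432
CAA	0.3795
CAG	0.8773
AAT	0.4864
AAC	0.5341
AAA	0.6545
AAG	0.8250
GAT	0.5955
GAC	0.6705
GAA	0.7591
GAG	1.0000
TGT	0.3409
TGC	0.3864
TGG	0.4000
CGT	0.2023
CGC	0.3364
CGA	0.2409
CGG	0.3591
AGT	0.3750
AGC	0.5432
AGA	0.3773
AGG	0.3727
GGT	0.3455
GGC	0.6045
GGA	0.4750
GGG	0.4750
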