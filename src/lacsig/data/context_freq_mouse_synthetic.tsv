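# synthetic genome-like (mouse) trinucleotide frequencies
context	frequency
ACA	0.04395826453051876
ACC	0.024928540705120295
ACG	0.0015142174997826747
ACT	0.03682401219748685
CCA	0.024098033779408043
CCC	0.020718566600936347
CCG	0.0012314293593237088
CCT	0.02780868254617024
GCA	0.029580854381612422
GCC	0.017501127303373196
GCG	0.0010331921486293441
GCT	0.027169725752109884
TCA	0.03897988899503654
TCC	0.024677597871469715
TCG	0.001723947552407284
TCT	0.042779928186033364
ATA	0.05243652176838692
ATC	0.038624140842662184
ATG	0.03908905441419633
ATT	0.056890814335934646
CTA	0.041269981360926
CTC	0.027699549477393528
CTG	0.029556699041721257
CTT	0.03564048343205532
GTA	0.0366177730758082
GTC	0.028216727236969226
GTG	0.025506752147273038
GTT	0.03636163026864717
TTA	0.05452335440930859
TTC	0.03911409985141379
TTG	0.03654297098563806
TTT	0.057381437942247246
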