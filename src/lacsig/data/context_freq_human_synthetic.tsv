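# synthetic genome-like (human) trinucleotide frequencies
context	frequency
ACA	0.036615725597045005
ACC	0.02303361322215212
ACG	0.0013767605423389204
ACT	0.04139804144574004
CCA	0.026441895103981844
CCC	0.019397514992231784
CCG	0.0010453328306156016
CCT	0.029505847358668565
GCA	0.02868389322947724
GCC	0.019901183571677472
GCG	0.000850797097876287
GCT	0.029278280772422824
TCA	0.03418588993697711
TCC	0.026394543073495865
TCG	0.001266789389112109
TCT	0.033967647000240894
ATA	0.05563587769798103
ATC	0.044485638884008055
ATG	0.037957982422533544
ATT	0.05096031126282958
CTA	0.03872191472652149
CTC	0.029021547675271823
CTG	0.02752740575406445
CTT	0.038996689266779856
GTA	0.034846483511626274
GTC	0.028213649663029475
GTG	0.028179171872943946
GTT	0.043423089063176615
TTA	0.06323004908347425
TTC	0.04121394408072555
TTG	0.0342024287884471
TTT	0.05004006108253328
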