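gene	status
GOLGB1	printed
TMIGD1	printed
CHMP4C	printed
SLC4A4	printed
MLL3	printed
TMEM140	printed
ARFRP1	printed
TNNI1	printed
UNRESOLVED_9	unresolved
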