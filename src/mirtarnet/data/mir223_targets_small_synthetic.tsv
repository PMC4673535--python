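gene	status
SLC4A4	printed
SMALL_TARGET_01	synthetic
SMALL_TARGET_02	synthetic
SMALL_TARGET_03	synthetic
SMALL_TARGET_04	synthetic
SMALL_TARGET_05	synthetic
SMALL_TARGET_06	synthetic
SMALL_TARGET_07	synthetic
SMALL_TARGET_08	synthetic
SMALL_TARGET_09	synthetic
SMALL_TARGET_10	synthetic
SMALL_TARGET_11	synthetic
SMALL_TARGET_12	synthetic
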