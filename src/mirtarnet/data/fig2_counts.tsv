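tissue	n_up	n_down	n_probes
small	24	326	24000
large	166	225	24000
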