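species	n_copies
sp01	2
sp02	1
sp03	2
sp04	1
sp05	1
sp06	1
sp07	1
sp08	1
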