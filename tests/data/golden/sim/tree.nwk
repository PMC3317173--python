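(((sp06|g1,(sp08|g1,sp05|g1)),(sp02|g1,(sp03|g2,sp03|g3))),((sp04|g1,sp07|g1),(sp01|g2,sp01|g3)));
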