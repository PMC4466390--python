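residue,pka
His-5,6.11
His-6,5.83
His29,5.98
His72,4.90
His27,6.49
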