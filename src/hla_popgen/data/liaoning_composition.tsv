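population	count
Han	20465
Manchu	1118
Mongol	126
Hui	101
Korean	64
Xibe	31
Others	13
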