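G0070
G0116
G0162
G0208
G0254
G0300
G0346
G0392
G0438
G0484
G0530
G0576
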