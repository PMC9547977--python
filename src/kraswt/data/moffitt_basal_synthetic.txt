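G0781
G0827
G0873
G0919
G0965
G1011
G1057
G1103
G1149
G1195
G1241
G1287
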