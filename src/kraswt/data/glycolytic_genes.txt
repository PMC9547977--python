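GAPDH
ALDOA
PKM
ENO1
TPI1
PGK1
GPI
PGAM1
PFKP
PFKFB3
ENO2
PPP2R5D
PFKM
PFKFB4
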