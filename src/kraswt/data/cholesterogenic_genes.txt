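FDPS
FDFT1
DHCR24
EBP
IDI1
MVD
HMGCS1
SQLE
NSDHL
DHCR7
HMGCR
LSS
SC5D
MVK
HSD1787
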