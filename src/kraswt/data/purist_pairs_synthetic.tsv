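gene_high_basal	gene_low_basal	weight
G0781	G0070	2.0
G0827	G0116	2.0
G0873	G0162	2.0
G0919	G0208	2.0
G0965	G0254	2.0
G1011	G0300	2.0
G1057	G0346	2.0
G1103	G0392	2.0
#intercept	-8.0
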