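squamous	synthetic squamous module	G0781	G0827	G0873	G0919	G0965	G1011	G1057	G1103	G1149	G1195	G1241	G1287
progenitor	synthetic progenitor module	G0070	G0116	G0162	G0208	G0254	G0300	G0346	G0392	G0438	G0484	G0530	G0576
adex	synthetic ADEX module	G1860	G1867	G1874	G1881	G1888	G1895	G1902	G1909	G1916	G1923	G1930	G1937	G1944
immunogenic	synthetic immunogenic module	G0100	G0107	G0114	G0121	G0128	G0135	G0142	G0149	G0156	G0163	G0170	G0177	G0184
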