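classical	synthetic classical module	G0070	G0116	G0162	G0208	G0254	G0300	G0346	G0392	G0438	G0484	G0530	G0576
quasi_mesenchymal	synthetic QM module	G0781	G0827	G0873	G0919	G0965	G1011	G1057	G1103	G1149	G1195	G1241	G1287
exocrine_like	synthetic exocrine module	G1860	G1867	G1874	G1881	G1888	G1895	G1902	G1909	G1916	G1923	G1930	G1937	G1944
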