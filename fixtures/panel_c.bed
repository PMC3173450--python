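panelC	0	300	ref_1	0	+	0	300	0	2	100,100	0,200
panelC	0	300	ref_2	0	+	0	300	0	2	100,100	0,200
panelC	0	300	paired_shift	0	+	0	300	0	2	80,80	0,220
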