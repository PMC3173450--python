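panelA	0	500	spliced	0	+	0	500	0	3	100,100,100	0,200,400
panelA	0	500	retains_both	0	+	0	500	0	1	500	0
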