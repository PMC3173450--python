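panelB	0	700	ref	0	+	0	700	0	4	100,100,100,100	0,200,400,600
panelB	0	700	retain_i1	0	+	0	700	0	3	300,100,100	0,400,600
panelB	0	700	retain_i2	0	+	0	700	0	3	100,300,100	0,200,600
panelB	0	700	retain_both	0	+	0	700	0	2	500,100	0,600
panelB	0	700	alt_donor_480	0	+	0	700	0	4	100,100,80,100	0,200,400,600
panelB	0	700	alt_donor_520	0	+	0	700	0	4	100,100,120,100	0,200,400,600
panelB	0	700	alt_acceptor_640	0	+	0	700	0	4	100,100,100,60	0,200,400,640
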