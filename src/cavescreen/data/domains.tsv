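gene	domain_name	aa_start	aa_end
ghrb	GHBP	254	519
mki67	Herpes_BLLF1	477	718
mki67	PTZ00449	515	742
mki67	PHA03247	203	676
mki67	retinal	253	659
mlf1	Mlf1IP	81	210
plg	PAN_AP_HGF	32	105
plg	PAN_AP	28	105
plg	PAN_1	31	105
wdr1	WD40 domain	54	390
wdr1	WD40 repeat	20	514
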