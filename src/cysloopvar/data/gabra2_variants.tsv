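gene	protein_id	hgvs_c	hgvs_p	significance	source
GABRA2	P47869	.	p.Met263Thr	pathogenic	manual
GABRA2	P47869	c.839C>T	p.Pro280Leu	pathogenic	manual
GABRA2	P47869	.	p.Val284Ala	pathogenic	manual
GABRA2	P47869	.	p.Leu291Val	pathogenic	manual
GABRA2	P47869	.	p.Thr292Lys	pathogenic	manual
GABRA2	P47869	.	p.Phe325Leu	pathogenic	manual
GABRA2	P47869	.	p.Asn335His	pathogenic	manual
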