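query_hgvs_p	gene	family	hgvs_c	hgvs_p	equivalent_ref_pos	rsid	source
p.Met263Thr	CHRNA2	nACh	NM_000742.3(CHRNA2):c.836T>A	p.Ile279Asn	262	rs104894063	clinvar;humsavar
p.Met263Thr	GABRA1	GABA-A	NM_000806.5(GABRA1):c.788T>A	p.Met263Lys	263	rs796052491	clinvar
p.Met263Thr	GABRA1	GABA-A	NM_000806.5(GABRA1):c.789G>A	p.Met263Ile	263	rs1060499553	clinvar
p.Met263Thr	GABRA1	GABA-A	NM_000806.5(GABRA1):c.788T>C	p.Met263Thr	263	.	manual
p.Met263Thr	GABRB3	GABA-A	NM_000814.5(GABRB3):c.766C>G	p.Leu256Val	263	rs1555401942	clinvar
p.Met263Thr	GABRB3	GABA-A	NM_000814.5(GABRB3):c.767T>A	p.Leu256Gln	263	.	humsavar
p.Pro280Leu	GABRG2	GABA-A	NM_198903.2(GABRG2):c.905C>T	p.Pro302Leu	280	.	manual
p.Pro280Leu	GLRA1	Gly	NM_001146040.1(GLRA1):c.832C>A	p.Pro278Thr	280	rs121918413	clinvar;humsavar
p.Val284Ala	CHRNA2	nACh	NM_000742.3(CHRNA2):c.889A>T	p.Ile297Phe	283	rs1554514507	clinvar
p.Val284Ala	GABRB2	GABA-A	NM_021911.2(GABRB2):c.830T>C	p.Leu277Ser	285	rs1554094145	clinvar
p.Val284Ala	GABRG2	GABA-A	NM_000816.3(GABRG2):c.919T>G	p.Leu307Val	285	rs796052509	clinvar
p.Leu291Val	CHRNB1	nACh	NM_000747.2(CHRNB1):c.853C>A	p.Leu285Met	291	rs137852811	clinvar;humsavar
p.Leu291Val	GLRB	Gly	NM_000824.4:c.920_921delinsGA	p.Leu307Arg	291	.	humsavar
p.Leu291Val	GABRA1	GABA-A	NM_000806.5(GABRA1):c.868G>A	p.Val290Met	290	rs796052494	clinvar
p.Leu291Val	GABRB2	GABA-A	NM_021911.2(GABRB2):c.845T>C	p.Val282Ala	290	rs886039374	clinvar
p.Leu291Val	GLRA1	Gly	NM_001146040.1(GLRA1):c.862G>A	p.Val288Met	290	rs121918416	clinvar
p.Thr292Lys	GLRA1	Gly	NM_000171.3(GLRA1):c.869C>T	p.Thr290Ile	292	rs1064795411	clinvar
p.Thr292Lys	CHRNA4	nACh	NM_000744.6(CHRNA4):c.851C>T	p.Ser284Leu	292	rs28931591	clinvar
p.Phe325Leu	CHRNB2	nACh	NM_000748.2(CHRNB2):c.923T>C	p.Val308Ala	324	rs281865070	clinvar
p.Phe325Leu	GABRA1	GABA-A	NM_000806.5(GABRA1):c.973T>C	p.Phe325Leu	325	rs1064794681	clinvar
p.Phe325Leu	GABRB2	GABA-A	NM_021911.2(GABRB2):c.946G>A	p.Val316Ile	324	rs1554093884	clinvar
p.Phe325Leu	GABRB2	GABA-A	NM_021911.2(GABRB2):c.950_951delTCinsCA	p.Phe317Ser	325	rs1554093882	clinvar
p.Phe325Leu	CHRNA1	nACh	NM_001039523.2(CHRNA1):c.988G>A	p.Val330Ile	324	rs137852804	clinvar
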