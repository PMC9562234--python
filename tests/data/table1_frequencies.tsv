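locus_id	chrom	position	G_magnirostris	G_fortis	G_fuliginosa
ERV-GE.cPa583.28	CamParChr2	13933293	1,00	0,66	0,05
ERV-S.cPa248.357	CamParChr2	126790181	0,93	0,69	0,00
ERV-AB1.cPa529.231	CamParChr2	14989140	0,93	0,69	0,05
ERV-AB1.cPa142.60	CamParChr1A	41006454	0,93	0,66	0,05
ERV-AB1.cPa452.570	CamParChr2	15047613	0,87	0,41	0,00
ERV-AB1.cPa452.1150	CamParChr3	107769927	1,00	0,53	0,16
ERV-S.cPa248.238	CamParChr1A	33361744	0,80	0,50	0,00
ERV-GE.cPa273.207	CamParChr3	60476691	0,87	0,59	0,11
ERV-AB1.cPa255.18	CamParChr2	15008875	0,73	0,47	0,00
ERV-AB1.cPa529.201	CamParChr1A	31065165	0,73	0,53	0,00
ERV-AB1.cPa16.47	CamParChr2	127077908	0,00	0,13	0,42
ERV-GE.cPa227.49	CamParChr2	22491398	0,00	0,09	0,58
ERV-AB2.cPa199.745	CamParChr3	39727190	0,07	0,31	0,74
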