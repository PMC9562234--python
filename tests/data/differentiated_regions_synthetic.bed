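CamParChr1A	30965000	31165000	region_01
CamParChr1A	33261000	33461000	region_02
CamParChr1A	40906000	41106000	region_03
CamParChr2	13833000	14033000	region_04
CamParChr2	14889000	15147000	region_05
CamParChr2	22391000	22591000	region_06
CamParChr2	126690000	126890000	region_07
CamParChr2	126977000	127177000	region_08
CamParChr3	39627000	39827000	region_09
CamParChr3	60376000	60576000	region_10
CamParChr3	107669000	107869000	region_11
CamParChr1A	5000000	5200000	region_12
CamParChr1A	12000000	12250000	region_13
CamParChr1A	58000000	58180000	region_14
CamParChr2	3500000	3700000	region_15
CamParChr2	40000000	40220000	region_16
CamParChr2	71500000	71700000	region_17
CamParChr2	99000000	99240000	region_18
CamParChr3	8200000	8400000	region_19
CamParChr3	25000000	25200000	region_20
CamParChr3	88000000	88150000	region_21
CamParChr4	6000000	6200000	region_22
CamParChr4	30500000	30700000	region_23
CamParChr4	55000000	55160000	region_24
CamParChr5	9800000	10000000	region_25
CamParChr5	27000000	27210000	region_26
CamParChr9	4400000	4600000	region_27
CamParChr9	15800000	16000000	region_28
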