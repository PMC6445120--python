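chrom	hfth1_length	hfth1_gaps	hfth1_telomere	gddh13_length	gddh13_gaps	gddh13_telomere
Chr01	32944118	12	Single	32625452	85	Single
Chr02	38449405	8	Both	37577729	87	None
Chr03	37138690	4	Single	37524076	80	None
Chr04	31012745	7	Both	32301874	64	Single
Chr05	47891858	13	Single	47952461	107	None
Chr06	35567198	5	Both	37137259	88	Single
Chr07	35934761	5	Both	36691129	75	None
Chr08	31511015	7	Single	31609270	66	Single
Chr09	34800404	9	Single	37604908	79	Single
Chr10	43815736	13	Both	41762413	82	Single
Chr11	42456296	14	Single	43059885	90	None
Chr12	32285079	8	Single	33050054	74	None
Chr13	44866511	12	Single	44339518	118	Single
Chr14	31515206	5	Both	32513452	61	Single
Chr15	56644392	15	None	54945402	128	Single
Chr16	41670059	14	None	41389449	92	None
Chr17	33998825	7	Both	34748701	75	Single
mtDNA	396939	0	NA	396947	0	NA
cpDNA	160068	0	NA	160068	0	NA
Unanchored	7992922	326	None	52728359	839	None
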