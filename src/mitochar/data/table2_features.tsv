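gene	direction	location	size	anticodon	start_codon	stop_codon
cox1	F	1–1559	1559	—	ATG	TAA
trnL2	F	1536–1601	66	TAA	—	—
cox2	F	1608–2315	708	—	ATG	TAA
trnK	F	2296–2365	70	TTT	—	—
trnD	F	2365–2428	64	GTC	—	—
atp8	F	2429–2587	159	—	ATG	TAA
atp6	F	2581–3254	674	—	ATG	TA
cox3	F	3255–4045	791	—	ATG	TA
trnG	F	4046–4110	65	TCC	—	—
nad3	F	4111–4461	351	—	ATT	TAA
trnA	F	4466–4529	64	TGC	—	—
trnR	F	4540–4605	66	TCG	—	—
trnN	F	4608–4674	67	GTT	—	—
trnS1	F	4678–4744	67	TCT	—	—
trnE	F	4745–4810	66	TTC	—	—
trnH	R	4815–4878	64	TAC	—	—
trnF	R	4881–4945	65	GAA	—	—
nad5	R	4953–6680	1728	—	ATG	TAA
nad4	R	6700–8061	1362	—	ATG	TAA
nad4L	R	8055–8357	303	—	ATG	TAA
trnT	F	8367–8432	66	TGT	—	—
trnP	R	8433–8499	67	TGG	—	—
nad6	F	8502–9004	503	—	ATT	TA
cob	F	9005–10,159	1155	—	ATG	TAA
trnS2	F	10,140–10206	67	TGA	—	—
nad1	R	10,226–11164	939	—	ATA	TAA
trnL1	R	11,205–11,268	64	TAG	—	—
rrnL	R	11,269–12,267	999	—	—	—
trnV	R	12,608–12680	73	TAC	—	—
rrnS	R	12,681–13,502	822	—	—	—
CR	—	13,503–14,253	751	—	—	—
trnQ	R	14,254–14,322	69	TTG	—	—
trnI	F	14,515–14,581	67	GAT	—	—
trnM	F	14,629–14,698	70	CAT	—	—
nad2	F	14,699–15,706	1008	—	ATG	TAG
trnW	F	15,709–15,778	70	TCA	—	—
trnC	R	15,776–15,839	64	GCA	—	—
trnY	R	15,840–15,905	66	GTA	—	—
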