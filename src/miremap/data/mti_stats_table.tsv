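mirna	direction	n_curated	n_de_targets
miR-429-3p	up	438	39
miR-200a-3p	up	394	25
miR-200b-3p	up	410	25
miR-200c-3p	up	382	26
miR-182-5p	up	379	18
miR-326-3p	up	175	16
miR-199a-5p	up	249	24
miR-673-3p	up	0	0
miR-337-3p	up	36	2
miR-337-5p	up	0	0
miR-540-3p	up	0	0
miR-431-5p	up	178	5
miR-127-3p	up	39	1
miR-127-5p	up	1	0
miR-434-3p	up	7	0
miR-434-5p	up	23	2
miR-136-3p	up	0	0
miR-136-5p	up	501	24
miR-379-5p	up	138	6
miR-379-3p	up	0	0
miR-411-3p	up	26	2
miR-411-5p	up	140	15
miR-299a-5p	up	18	1
miR-329-3p	up	329	5
miR-494-3p	up	427	26
miR-1193-3p	up	0	0
miR-543-3p	up	480	36
miR-495-3p	up	644	40
miR-376c-3p	up	337	18
miR-376b-3p	up	227	10
miR-376b-5p	up	0	0
miR-376a-3p	up	11	1
miR-300-3p	up	40	6
miR-381-3p	up	606	45
miR-382-5p	up	296	20
miR-382-3p	up	1	0
miR-134-5p	up	203	14
miR-485-5p	up	140	9
miR-485-3p	up	0	0
miR-154-3p	up	0	0
miR-154-5p	up	226	11
miR-496a-3p	up	218	13
miR-541-5p	up	298	20
miR-409-5p	up	0	0
miR-409-3p	up	29	2
miR-369-3p	up	0	0
miR-369-5p	up	0	0
miR-410-3p	up	524	29
miR-455-3p	down	3	0
miR-455-5p	down	0	0
miR-31-3p	down	0	0
miR-31-5p	down	334	36
miR-93-5p	down	705	83
miR-339-3p	down	0	0
miR-335-5p	down	223	19
miR-486b-5p	down	28	2
miR-144-3p	down	709	72
miR-451a	down	108	31
miR-345-5p	down	18	5
miR-17-5p	down	992	115
miR-19a-3p	down	602	62
miR-484	down	0	0
miR-802-5p	down	0	0
miR-145a-5p	down	262	26
miR-322-5p	down	817	80
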