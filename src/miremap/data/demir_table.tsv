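mirna	direction	locus	seq_fc	array_fc
miR-429-3p	up	chr4:156053905-156053987:-	2.01	3.56E+00
miR-200a-3p	up	chr4:156054896-156054985:-	2.50	2.25E+00
miR-200b-3p	up	chr4:156055681-156055750:-	3.53	4.25E+00
miR-200c-3p	up	chr6:124718322-124718390:-	1.86	2.88E+00
miR-182-5p	up	chr6:30165918-30165992:-	2.12	2.41E+00
miR-326-3p	up	chr7:99552269-99552363:+	2.07	1.83E+00
miR-199a-5p	up	chr9:21496495-21496564:-	3.39	1.10E+01
miR-673-3p	up	chr12: 109571990-109572080:+	34.09	3.55E+04
miR-337-3p	up	chr12: 109585789-109585885:+	22.14	9.67E+00
miR-337-5p	up	chr12: 109585789-109585885:+	59.88	2.20E+01
miR-540-3p	up	chr12: 109586080-109586146:+	26.89	1.04E+04
miR-431-5p	up	chr12: 109590447-109590537:+	34.02	5.96E+05
miR-127-3p	up	chr12: 109592846-109592915:+	61.60	1.59E+01
miR-127-5p	up	chr12: 109592846-109592915:+	38.92	3.07E+01
miR-434-3p	up	chr12: 109594506-109594599:+	68.55	2.98E+01
miR-434-5p	up	chr12: 109594506-109594599:+	49.12	2.35E+01
miR-136-3p	up	chr12:109595327-109595388:+	55.82	1.29E+01
miR-136-5p	up	chr12:109595327-109595388:+	42.94	2.49E+00
miR-379-5p	up	chr12:109709060-109709125:+	46.48	1.74E+01
miR-379-3p	up	chr12:109709060-109709125:+	62.39	7.18E+00
miR-411-3p	up	chr12:109710175-109710256:+	64.08	1.16E+01
miR-411-5p	up	chr12:109710175-109710256:+	56.88	2.51E+01
miR-299a-5p	up	chr12:109710638-109710700:+	34.89	6.81E+02
miR-329-3p	up	chr12:109713481-109713577:+	19.84	1.05E+04
miR-494-3p	up	chr12:109715318-109715402:+	16.36	1.35E+03
miR-1193-3p	up	chr12:109715671-109715791:+	33.38	1.07E+01
miR-543-3p	up	chr12:109717258-109717333:+	28.07	5.30E+00
miR-495-3p	up	chr12:109718754-109718816:+	31.35	2.03E+01
miR-376c-3p	up	chr12:109722718-109722803:+	43.62	1.85E+01
miR-376b-3p	up	chr12:109723458-109723539:+	64.47	4.21E+01
miR-376b-5p	up	chr12:109723458-109723539:+	56.26	2.81E+01
miR-376a-3p	up	chr12:109723781-109723848:+	12.12	2.07E+04
miR-300-3p	up	chr12:109724313-109724391:+	48.31	2.87E+03
miR-381-3p	up	chr12:109726822-109726896:+	59.30	2.33E+03
miR-382-5p	up	chr12:109733771-109733846:+	26.07	4.62E+00
miR-382-3p	up	chr12:109733771-109733846:+	16.26	4.37E+03
miR-134-5p	up	chr12:109734139-109734209:+	41.55	3.29E+01
miR-485-5p	up	chr12:109734902-109734974:+	10.71	1.18E+05
miR-485-3p	up	chr12:109734902-109734974:+	63.49	9.91E+01
miR-154-3p	up	chr12:109738433-109738498:+	63.36	8.38E+01
miR-154-5p	up	chr12:109738433-109738498:+	57.20	4.12E+03
miR-496a-3p	up	chr12:109739119-109739197:+	48.48	5.39E+03
miR-541-5p	up	chr12:109742409-109742498:+	48.98	4.90E+01
miR-409-5p	up	chr12:109743158-109743236:+	16.22	7.26E+03
miR-409-3p	up	chr12:109743158-109743236:+	58.62	2.91E+01
miR-369-3p	up	chr12:109743418-109743496:+	19.52	1.03E+04
miR-369-5p	up	chr12:109743418-109743496:+	7.92	2.19E+03
miR-410-3p	up	chr12:109743715-109743795:+	51.74	9.52E+00
miR-455-3p	down	chr4:63256851-63256932:+	0.64	4.35E-01
miR-455-5p	down	chr4:63256851-63256932:+	0.66	3.85E-01
miR-31-3p	down	chr4:88910557-88910662:-	0.40	9.54E-02
miR-31-5p	down	chr4:88910557-88910662:-	0.25	8.27E-02
miR-93-5p	down	chr5:138165523-138165610:-	0.58	9.70E-04
miR-339-3p	down	chr5:139369650-139369745:-	0.57	2.59E-01
miR-335-5p	down	chr6:30741299-30741396:+	0.41	3.99E-01
miR-486b-5p	down	chr8: 23142573-23142662:-	0.50	3.09E-01
miR-144-3p	down	chr11:78073005-78073070:+	0.46	1.83E-01
miR-451a	down	chr11:78073170-78073241:+	0.35	7.81E-03
miR-345-5p	down	chr12:108836973-108837068:+	0.52	3.19E-01
miR-17-5p	down	chr14:115043671-115043754:+	0.55	2.16E-07
miR-19a-3p	down	chr14:115044000-115044081:+	0.35	4.21E-01
miR-484	down	chr16:14159626-14159692:+	0.59	6.05E-01
miR-802-5p	down	chr16:93369720-93369816:+	0.17	7.01E-02
miR-145a-5p	down	chr18:61647825-61647894:-	0.56	1.95E-01
miR-322-5p	down	chrX:53054255-53054349:-	0.61	4.79E-01
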