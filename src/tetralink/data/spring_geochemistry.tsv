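spring_id	lat	lon	ph	temp	conductivity	salinity	sulfide	fe2	no2	no3	nh4	cl	so4
E1	N 44°43′39.0″	W 110°42′56.3″	3.12	71.0	3500	2.0	5.9	11.2	34.3	470.7	71.9	8.06	1.10
E2	N 44°43′43.1″	W 110°42′45.2″	2.28	83.0	2600	2.4	4.4	10.7	30.0	1208.6	286.0	0.03	5.19
E3	N 44°43′45.4″	W 110°42′44.9″	2.81	58.3	2600	2.0	12.6	2.3	69.3	594.3	51.7	7.92	1.44
E4	N 44°43′56.8″	W 110°42′35.1″	4.27	79.5	3750	2.1	8.9	0.8	109.3	499.3	11.4	9.79	0.98
E5	N 44°43′59.8″	W 110°42′35.2″	2.55	82.0	3600	2.3	16.8	15.6	35.7	505.7	207.6	6.09	3.39
E6	N 44°43′59.2″	W 110°42′34.4″	2.93	75.0	3600	2.3	12.5	2.2	37.9	682.1	202.6	7.10	2.34
E7	N 44°43′58.9″	W 110°42′33.2″	2.61	22.5	3700	2.3	BD	6.8	35.0	912.9	87.8	10.60	3.86
E8	N 44°43′58.0″	W 110°42′34.4″	3.30	70.0	3300	2.1	14.9	4.0	37.1	311.4	103.7	8.07	1.78
E9	N 44°43′40.4″	W 110°42′36.9″	4.45	64.8	3750	2.5	1.1	11.0	27.1	352.1	143.9	8.27	2.46
E10	N 44°43′35.8″	W 110°42′32.9″	7.17	82.4	6000	4.0	1.4	BD	102.9	355.0	18.2	11.15	0.39
E11	N 44°43′35.8″	W 110°42′32.9″	7.46	60.2	3100	3.0	BD	BD	339.3	946.4	13.8	11.75	0.43
E12	N 44°18′17.8″	W 110°31′19.9″	8.49	47.7	1750	1.1	0.1	0.2	870.0	1980.0	8.6	3.79	1.61
E13	N 44°18′18.8″	W 110°31′19.3″	7.32	83.8	2700	1.9	0.6	BD	187.9	205.7	25.8	4.22	1.82
E14	N 44°18′18.8″	W 110°31′19.3″	3.49	64.8	3200	2.0	11.2	16.6	35.2	264.1	88.6	7.51	3.48
E15	N 44°18′14.1″	W 110°31′16.7″	9.30	69.0	3800	2.8	0.4	9.3	863.6	448.6	3.9	6.41	2.62
E17	N 44°18′15.7″	W 110°31′23.7″	9.10	86.7	4600	3.5	18.7	BD	118.6	138.6	5.9	5.27	1.99
E18	N 44°18′15.8″	W 110°31′23.0″	9.45	54.5	3350	2.4	34.1	5.2	116.4	386.4	1.6	6.26	2.48
E19	N 44°18′15.7″	W 110°31′22.2″	9.57	38.0	2650	1.9	2.2	0.1	204.3	516.4	4.1	5.61	2.13
E22	N 44°18′17.2″	W 110°31′23.9″	8.88	67.0	4000	3.1	2.3	0.2	644.3	636.4	4.9	3.31	2.35
E23	N 44°31′54.6″	W 110°52′33.3″	6.69	55.0	1500	0.9	0.1	BD	276.4	432.9	8.2	4.29	1.10
E24	N 44°31′54.6″	W 110°52′33.3″	8.50	52.4	2600	1.8	2.5	BD	155.0	343.6	1.1	3.43	0.20
E26	N 44°31′54.6″	W 110°52′33.3″	5.80	48.0	1000	0.5	4.7	16.4	167.9	282.1	91.0	3.28	0.33
E29	N 44°31′54.6″	W 110°52′33.3″	4.10	81.5	320	0.1	1.9	4.4	122.1	1782.1	111.0	3.89	0.80
E31	N 44°43′35.8″	W 110°42′32.9″	3.01	39.2	2375	1.5	3.8	19.8	67.9	427.1	94.1	6.66	1.95
E32	N 44°43′45.4″	W 110°42′44.9″	2.75	43.1	3175	2.2	BD	8.5	56.4	272.9	46.5	7.23	1.09
E36	N 44°45′06.9″	W 110°43′42.8″	2.06	32.7	2300	2.6	BD	30.1	268.6	BD	26.7	0.37	0.50
E39	N 44°45′06.9″	W 110°43′42.8″	4.95	16.3	590	0.5	1.6	5.3	497.9	21.4	2.4	0.24	0.19
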