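spring_id	GTGT-0	GDGT-0	GDGT-1	GDGT-2	GDGT-3	GDGT-4	GDGT-4p	GDGT-5	GDGT-5p	CREN	CREN-ISO	GDGT-6	GDGT-7	GDGT-8	Ring index	total_igdgt	archaeol
E1	0.2	2.0	3.8	10.0	17.1	37.9	1.9	15.5	0.7	2.9	0.9	6.4	0.5	0.3	3.8	1542.7	1.0
E2	0.0	3.0	0.1	4.3	9.7	57.6	9.4	10.1	0.0	0.0	0.0	5.8	0.0	0.0	3.9	1.6	0.0
E3	0.2	1.7	1.4	6.5	15.7	59.8	0.6	9.5	0.1	0.4	0.0	3.2	0.7	0.2	3.8	1633.6	20.4
E4	0.1	1.1	2.2	6.1	18.4	52.9	2.3	12.2	0.5	0.2	0.0	3.9	0.2	0.1	3.8	495.5	0.0
E5	0.5	4.5	4.6	16.2	18.0	30.2	6.8	9.2	3.1	0.2	0.0	5.7	0.6	0.5	3.4	3282.4	0.0
E6	0.7	1.5	2.8	6.8	5.1	66.9	5.7	3.6	1.5	1.3	0.0	3.7	0.2	0.2	3.8	7786.3	4.1
E7	0.1	2.6	3.2	11.4	23.6	42.9	0.7	7.9	0.1	0.8	0.0	6.2	0.3	0.2	3.6	1494.9	6.2
E8	0.3	3.5	5.4	14.3	23.6	35.0	1.8	9.5	0.6	0.4	0.0	4.8	0.5	0.4	3.4	2587.5	0.3
E9	0.2	4.8	2.6	13.8	17.1	45.0	1.2	10.0	0.2	0.5	0.0	4.6	0.0	0.0	3.5	233.2	12.1
E10	0.0	11.9	13.4	19.1	23.4	19.9	0.3	0.5	0.0	10.8	0.3	0.2	0.0	0.0	2.6	192.2	0.0
E11	0.5	13.8	8.9	21.3	13.2	12.7	0.3	1.0	0.2	26.9	0.6	0.7	0.0	0.0	2.9	748.4	9.6
E12	0.1	17.3	27.1	25.1	19.7	7.1	0.1	0.5	0.0	2.3	0.2	0.3	0.0	0.0	1.8	34837.8	73.3
E14	0.2	2.5	2.0	5.6	13.4	39.3	2.1	23.2	0.2	0.5	0.1	10.9	0.0	0.0	4.0	8280.2	111.8
E15	0.1	12.4	10.6	40.2	17.1	9.6	0.5	0.9	0.0	7.6	0.7	0.2	0.0	0.0	2.3	890.7	3.6
E17	0.2	9.3	13.1	26.8	28.0	20.2	0.3	0.0	0.0	1.8	0.2	0.0	0.0	0.0	2.4	1056.9	7.4
E18	0.0	5.1	8.6	22.8	37.2	24.9	0.0	0.3	0.0	1.0	0.1	0.1	0.0	0.0	2.7	850.1	1.0
E19	0.1	4.9	9.8	21.4	35.4	26.8	0.1	0.4	0.0	1.1	0.1	0.1	0.0	0.0	2.7	25532.4	29.4
E22	0.4	6.8	11.8	19.9	30.2	28.0	0.2	0.4	0.0	2.1	0.2	0.1	0.0	0.0	2.7	39486.4	61.0
E24	0.1	2.7	2.9	6.1	17.2	67.5	0.0	0.6	0.0	2.5	0.2	0.1	0.0	0.0	3.5	17832.9	3.1
E26	0.8	40.2	10.3	10.7	10.9	24.7	0.3	0.7	0.1	0.8	0.3	0.1	0.0	0.0	1.7	5309.2	226.1
E29	0.1	1.8	2.5	4.2	12.9	40.6	1.7	22.7	0.3	0.5	0.0	12.7	0.0	0.0	4.1	741.8	3.0
E31	0.2	3.4	3.6	9.9	17.4	53.1	0.6	6.6	0.1	1.0	0.0	4.0	0.1	0.1	3.5	333.0	14.7
E32	0.2	11.5	10.1	21.9	18.5	34.5	0.3	2.0	0.0	0.6	0.0	0.4	0.0	0.0	2.6	524.3	20.4
E36	0.2	5.7	3.2	8.6	14.8	47.0	1.0	10.2	0.2	0.8	1.5	6.6	0.1	0.1	3.6	445.5	2.1
E39	0.0	4.3	8.8	24.9	40.3	20.4	0.1	0.3	0.0	0.7	0.1	0.0	0.0	0.0	2.7	3439.5	0.0
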