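spring_id	GTGT-0	GDGT-0	GDGT-1	GDGT-2	GDGT-3	GDGT-4	GDGT-4p	GDGT-5	GDGT-5p	CREN	CREN-ISO	GDGT-6	GDGT-7	GDGT-8	Ring index	total_igdgt	archaeol
E1	0.2	1.3	2.6	9.6	21.6	48.2	0.4	10.8	0.0	0.5	0.1	4.7	0.1	0.1	3.7	15162.6	135.6
E2	0.0	1.1	1.5	3.7	10.4	55.6	0.8	19.8	0.0	0.0	0.0	7.2	0.0	0.0	4.1	10.5	0.1
E3	0.3	2.6	1.6	8.7	8.2	58.6	0.6	13.4	0.1	0.6	0.0	5.3	0.1	0.1	3.8	1601.4	22.7
E4	0.1	0.6	1.0	3.0	9.7	75.7	0.3	6.8	0.1	0.6	0.0	2.2	0.0	0.0	3.9	5792.0	18.9
E5	0.1	1.6	2.8	7.5	16.5	48.4	0.8	14.9	0.1	0.3	0.0	6.7	0.1	0.1	3.8	56527.7	452.1
E6	0.2	1.2	2.0	5.8	13.9	44.0	1.8	21.4	0.4	0.3	0.0	8.8	0.1	0.1	4.0	104666.1	851.2
E7	0.3	2.4	3.2	6.6	7.8	54.9	0.6	11.9	0.2	0.6	0.2	10.7	0.2	0.3	3.9	1507.2	34.4
E8	0.2	1.6	2.6	7.7	16.8	54.9	0.3	10.5	0.1	0.4	0.0	4.5	0.2	0.2	3.7	18178.5	148.1
E9	0.5	4.4	2.0	10.5	12.2	42.8	1.1	13.6	0.3	0.4	0.0	12.3	0.0	0.0	3.8	122.5	4.9
E10	0.5	12.1	12.1	16.2	25.3	27.2	0.2	3.6	0.0	1.3	0.1	1.4	0.0	0.0	2.6	118.3	2.2
E11	3.3	10.9	8.2	16.0	17.2	32.0	0.2	4.7	0.2	4.2	0.2	2.9	0.0	0.0	2.8	164.5	5.4
E12	0.5	15.9	22.2	22.2	17.7	13.2	0.3	2.7	0.0	2.7	0.3	2.3	0.0	0.0	2.2	6601.6	87.0
E14	0.5	2.3	2.0	5.2	12.0	40.7	1.6	22.0	0.2	0.5	0.1	12.7	0.0	0.0	4.1	2558.9	60.1
E15	0.7	14.5	10.6	24.6	15.4	19.3	0.4	4.0	0.0	8.2	1.0	1.3	0.0	0.0	2.6	169.2	10.6
E17	0.7	9.8	10.9	17.5	24.7	29.1	0.3	4.2	0.0	1.2	0.2	1.4	0.0	0.0	2.7	338.7	22.5
E18	0.2	6.3	10.2	23.0	37.3	22.1	0.0	0.3	0.0	0.6	0.0	0.1	0.0	0.0	2.6	850.7	4.7
E19	0.3	7.2	10.9	20.0	32.0	27.2	0.1	1.1	0.0	0.8	0.0	0.4	0.0	0.0	2.7	8151.8	76.6
E22	1.5	7.9	11.0	18.3	29.8	29.4	0.1	0.3	0.0	1.5	0.1	0.1	0.0	0.0	2.7	17062.9	392.9
E24	0.5	3.3	2.9	4.8	14.2	72.4	0.0	0.4	0.0	1.2	0.2	0.1	0.0	0.0	3.5	5808.2	111.6
E26	0.7	36.5	7.0	7.8	10.8	35.3	0.1	0.5	0.0	0.9	0.1	0.2	0.0	0.0	2.1	1912.6	50.8
E29	1.0	2.1	3.1	4.9	11.9	39.0	1.2	21.6	0.1	0.5	0.0	14.6	0.0	0.0	4.1	398.2	24.3
E31	0.2	2.0	3.3	8.2	17.1	53.4	0.4	8.5	0.1	0.5	0.1	6.0	0.1	0.1	3.7	482.8	5.5
E32	1.1	6.3	5.4	12.1	12.9	47.3	0.5	9.9	0.2	0.5	0.1	3.7	0.0	0.0	3.4	132.3	5.2
E36	0.3	3.4	2.3	6.4	13.2	53.0	0.5	11.0	0.1	0.6	0.1	9.0	0.1	0.1	3.8	642.6	12.2
E39	0.7	9.2	9.7	19.6	25.6	26.2	0.3	4.9	0.0	1.5	0.1	2.1	0.0	0.0	2.8	497.0	68.1
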