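Code	Diagnosis	Age	PSA	Race	Gleason
PC1	CANCER	61	11.6	MA	6
PC2	CANCER	71	5.1	MA	7
PC3	CANCER	61	100	B	9
PC4	CANCER	74	31	MA	7
PC5	CANCER	61	16.4	MA	6
PC6	CANCER	67	350	MA	9
PC7	CANCER	80	39.4	B	7
PC8	CANCER	68	1091	MA	9
PC9	CANCER	69	5.9	W	7
PC10	CANCER	64	9.1	W	6
PC11	CANCER	64	1.1	W	6
PC12	CANCER	76	195	W	10
PC13	CANCER	74	1.5	MA	6
PC14	CANCER	66	34	MA	9
PC15	CANCER	76	315	MA	6
PC16	CANCER	62	17.05	MA	7
PC17	CANCER	63	24.05	MA	7
PC18	CANCER	71	2.9	W	9
PC19	CANCER	74	184	W	10
PC20	CANCER	77	738	B	8
BPH1	BENIGN	72	3.6	MA	NA
BPH2	BENIGN	64	2.8	MA	NA
BPH3	BENIGN	70	5.4	W	NA
BPH4	BENIGN	61	2.9	MA	NA
BPH5	BENIGN	75	3.7	MA	NA
BPH6	BENIGN	58	19.5	W	NA
BPH7	BENIGN	70	48.4	MA	NA
BPH8	BENIGN	68	5.7	MA	NA
BPH9	BENIGN	69	7.1	MA	NA
BPH10	BENIGN	56	5.03	MA	NA
BPH11	BENIGN	53	1.24	W	NA
BPH12	BENIGN	63	4.7	W	NA
BPH13	BENIGN	86	10.6	B	NA
BPH14	BENIGN	56	9.6	MA	NA
BPH15	BENIGN	75	7.3	B	NA
BPH16	BENIGN	61	4.5	B	NA
BPH17	BENIGN	81	25.8	B	NA
BPH18	BENIGN	64	6.6	B	NA
BPH19	BENIGN	74	2.6	B	NA
BPH20	BENIGN	57	3.64	MA	NA
BPH21	BENIGN	69	3.3	MA	NA
BPH22	BENIGN	70	1.2	W	NA
BPH23	BENIGN	75	0.83	W	NA
BPH24	BENIGN	65	27	B	NA
BPH25	BENIGN	68	5.8	MA	NA
BPH26	BENIGN	62	1.4	W	NA
BPH27	BENIGN	78	0.1	B	NA
BPH28	BENIGN	66	3.6	W	NA
BPH29	BENIGN	68	0.75	B	NA
BPH30	BENIGN	70	9.1	MA	NA
BPH31	BENIGN	77	37.1	MA	NA
BPH32	BENIGN	67	6.43	MA	NA
DC1	NFM	44	0.7	MA	NA
DC2	NFM	74	7.8	MA	NA
DC3	NFM	62	3.7	MA	NA
DC4	NFM	52	NA	MA	NA
DC5	NFM	34	NA	B	NA
DC6	NFM	63	6.3	MA	NA
DC7	NFM	67	5.9	MA	NA
DC8	NFM	65	3.4	MA	NA
DC9	NFM	59	18.9	MA	NA
DC10	NFM	69	0.4	MA	NA
DC11	NFM	61	8	MA	NA
DC12	NFM	76	7	B	NA
DC13	NFM	56	0.9	MA	NA
DC14	NFM	35	NA	B	NA
DC15	NFM	58	6.5	MA	NA
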