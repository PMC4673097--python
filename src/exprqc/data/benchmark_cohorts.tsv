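cohort_id	group	n_female	n_male
C01	lung	89	107
C02	lung	220	223
C03	lung	36	14
C04	lung	17	38
C05	lung	23	67
C06	lung	47	82
C07	lung	109	95
C08	lung	23	59
C09	lung	14	3
C10	lung	16	56
C11	colorectal	12	10
C12	colorectal	48	42
C13	colorectal	22	15
C14	colorectal	28	34
C15	colorectal	106	120
C16	colorectal	81	96
C17	colorectal	29	26
C18	other	32	68
C19	other	25	68
C20	other	6	24
C21	other	24	30
C22	other	9	14
C23	non_cancer	11	48
C24	non_cancer	38	40
C25	non_cancer	7	10
C26	non_cancer	28	22
C27	non_cancer	28	12
C28	non_cancer	27	12
C29	non_cancer	80	45
C30	breast	200	0
C31	breast	286	0
C32	breast	280	0
C33	breast	114	0
C34	breast	247	0
C35	breast	139	0
C36	breast	47	0
C37	breast	60	0
C38	ovarian	133	0
C39	ovarian	80	0
C40	ovarian	28	0
C41	ovarian	185	0
C42	prostate	0	153
C43	prostate	0	79
C44	prostate	0	19
C45	prostate	0	148
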