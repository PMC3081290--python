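drug	label	daily_dose_mg	unit	cmax	cmean	ctrough	inr
rivaroxaban	5 OD	5	ug/l	60.98	24.280	4.27
rivaroxaban	5 BD	10	ug/l	75.97	42.83	16.36
rivaroxaban	10 OD	10	ug/l	121.97	48.56	8.54
rivaroxaban	10 BD	20	ug/l	151.9	85.66	32.73
rivaroxaban	20 OD	20	ug/l	195.15	77.69	13.66
rivaroxaban	20 BD	40	ug/l	243.10	137.06	52.37
rivaroxaban	53 OD	53	ug/l	387.86	154.42	27.15
rivaroxaban	53 BD	106	ug/l	483.17	272.42	104.08
warfarin	INR 1.5		INR				1.5
warfarin	INR 2.0		INR				2.0
warfarin	INR 2.5		INR				2.5
warfarin	INR 3.0		INR				3.0
warfarin	INR 3.5		INR				3.5
warfarin	INR 4.0		INR				4.0
ximelagatran	24 BD	48	uM	0.21	0.12	0.04
ximelagatran	60 BD	120	uM	0.52	0.31	0.12
DX-9065a	IV 100		ug/l	100	100	100
DX-9065a	IV 200		ug/l	200	200	200
enoxaparin	20 OD	20	mg/l	1.79	0.76	0.19
enoxaparin	40 OD	40	mg/l	3.69	1.57	0.40
enoxaparin	30 BD	60	mg/l	2.74	1.95	0.95
enoxaparin	105 OD (1.5 mg/kg)	105	mg/l	12.8	5.47	1.40
enoxaparin	70 BD (1 mg/kg)	140	mg/l	10.79	7.67	3.74
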