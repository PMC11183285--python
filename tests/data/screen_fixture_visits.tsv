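subject_id	visit	scan_present	diagnosis
S1	bl	1	AD
S1	m06	1	AD
S1	m12	1	AD
S1	m18	1	AD
S1	m24	1	AD
S1	m36	1	AD
S2	bl	1	MCI
S2	m06	1	MCI
S2	m12	1	MCI
S2	m18	1	MCI
S2	m24	1	MCI
S2	m36	1	MCI
S3	bl	1	MCI
S3	m06	1	AD
S3	m12	1	AD
S3	m18	1	AD
S3	m24	1	AD
S3	m36	1	AD
S4	bl	1	MCI
S4	m06	1	MCI
S4	m12	1	CN
S4	m18	1	CN
S4	m24	1	CN
S4	m36	1	CN
S5	bl	1	MCI
S5	m06	1	MCI
S5	m12	1	MCI
S5	m18	1	MCI
S5	m24	0	MCI
S5	m36	1	MCI
S6	bl	1	MCI
S6	m06	1	MCI
S6	m12	0	MCI
S6	m18	0	MCI
S6	m24	0	MCI
S6	m36	1	AD
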