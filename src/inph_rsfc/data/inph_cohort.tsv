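subject_id	group	mmse	fab	gs_gait	gs_cognition	gs_urinary	tap_test
iNPH1	iNPH	17	10	3	3	0	positive
iNPH2	iNPH	25	11	2	1	1	positive
iNPH3	iNPH	22	10	2	2	0	positive
iNPH4	iNPH	16	9	3	3	3	positive
iNPH5	iNPH	19	6	3	2	2	positive
iNPH6	iNPH	28	13	2	2	2	positive
iNPH7	iNPH	25	6	2	2	0	positive
iNPH8	iNPH	29	13	1	2	0	negative
iNPH9	iNPH	25	17	1	1	0	negative
iNPH10	iNPH	25	16	2	2	4	positive
iNPH11	iNPH	20	12	2	3	2	positive
HC1	HC			0	0	0
HC2	HC			0	0	0
HC3	HC			0	0	0
HC4	HC			0	0	0
HC5	HC			0	0	0
HC6	HC			0	0	0
HC7	HC			0	0	0
HC8	HC			0	0	0
HC9	HC			0	0	0
HC10	HC			0	0	0
HC11	HC			0	0	0
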