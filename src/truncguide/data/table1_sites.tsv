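target_id	seq20_pam	seq17_pam	indel_293T_20nt	indel_293T_17nt	indel_iPSC_20nt	indel_iPSC_17nt	indel_iMSC_20nt	indel_iMSC_17nt
sgGFP42-On	GCCGTCCAGCTCGACCAGGAtGG	GTCCAGCTCGACCAGGAtGG	98.20	98.90	75.50	71.10	80.60	60.87
sgGFP42-Off1	TATGTCCAGCTGGACCAGGAgGG	GTCCAGCTGGACCAGGAgGG	26.55	33.53	21.40	26.64	18.94	26.79
sgGFP42-Off2	GAGCTCCAGCTCAACCAGGAtGG	CTCCAGCTCAACCAGGAtGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off4	GGGCTCCAGCTCAACCAGGAtGG	CTCCAGCTCAACCAGGAtGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off5	GTGGTCCAGCTCGCCCAGGTcGG	GTCCAGCTCGCCCAGGTcGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off6	CCTGGCCAGCTAGACCAGGAtGG	GGCCAGCTAGACCAGGAtGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off7	GCTGGACAGCTCTACCAGGAtGG	GGACAGCTCTACCAGGAtGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off9	GGCGCACAGCTCGACCTGGAgGG	GCACAGCTCGACCTGGAgGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off10	GCCTCCCAGCTCCACCAGGCaGG	TCCCAGCTCCACCAGGCaGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off12	GCCATCCAGGAGGACCAGGAtGG	ATCCAGGAGGACCAGGAtGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off13	GCCCTCCATCCCCACCAGGAgGG	CTCCATCCCCACCAGGAgGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off14	GCCGTCCAGCTCTCCCAGGTgGG	GTCCAGCTCTCCCAGGTgGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off15	GCAGTCCAGCTCTAGGAGGAaGG	GTCCAGCTCTAGGAGGAaGG	ND	ND	ND	ND	ND	ND
sgGFP42-Off16	GCCGTGCAGCTCTAGCAGGGaGG	GTGCAGCTCTAGCAGGGaGG	ND	ND	ND	ND	ND	ND
sgGFP101-On	GGCGAGGGCGATGCCACCTAaGG	GAGGGCGATGCCACCTAaGG	99.50	99.43	69.23	44.40	79.63	53.83
sgGFP101-Off1	GAGCAGGGGGATGCCACCTAgGG	CAGGGGGATGCCACCTAgGG	ND	ND	ND	ND	ND	ND
sgGFP101-Off2	GATGAGGGAGAGGCCACCTAgGG	GAGGGAGAGGCCACCTAgGG	ND	ND	ND	ND	ND	ND
sgGFP101-Off3	GGGGAGGGAGATTCCACCTAcGG	GAGGGAGATTCCACCTAcGG	21.61	19.41	21.72	21.59	23.96	23.77
sgGFP101-Off5	GGTGAGGGTGATGCCACCCAgGG	GAGGGTGATGCCACCCAgGG	20.02	11.49	ND	ND	ND	ND
sgGFP101-Off6	AAAGAGGGCAATTCCACCTAcGG	GAGGGCAATTCCACCTAcGG	ND	ND	ND	ND	ND	ND
sgGFP101-Off7	AGGGAGGGCGGGGCCACCTAtGG	GAGGGCGGGGCCACCTAtGG	29.91	29.27	33.19	33.15	33.61	35
sgGFP261-On	GACGTAGCCTTCGGGCATGGcGG	GTAGCCTTCGGGCATGGcGG	99.73	99.80	50.47	59.80	75.77	61.07
sgGFP261-Off1	GCTGGAGCCTTCGGGCATGGcGG	GGAGCCTTCGGGCATGGcGG	ND	17.77	ND	ND	ND	ND
sgGFP261-Off3	GGAGAAGCTTTCGGGCATGGgGG	GAAGCTTTCGGGCATGGgGG	ND	ND	ND	ND	ND	ND
sgGFP261-Off4	GGTGTGGCCTTGGGGCATGGgGG	GTGGCCTTGGGGCATGGgGG	ND	ND	ND	ND	ND	ND
sgGFP261-Off5	GGTGTAGGCCTCGGGCATGGcGG	GTAGGCCTCGGGCATGGcGG	ND	ND	ND	ND	ND	ND
sgGFP261-Off6	ACAGAAGCCTTCAGGCATGGaGG	GAAGCCTTCAGGCATGGaGG	ND	ND	ND	ND	ND	ND
sgGFP261-Off7	TTTGTAGTCTTCAGGCATGGgGG	GTAGTCTTCAGGCATGGgGG	11.92	22.15	ND	ND	ND	ND
sgGFP261-Off9	AACGTAGCCTCAGGGCATGGgGG	GTAGCCTCAGGGCATGGgGG	28.64	17.82	ND	ND	ND	ND
sgGFP261-Off10	CAGGTAGCCTTGGGCCATGGtGG	GTAGCCTTGGGCCATGGtGG	ND	ND	ND	ND	ND	ND
sgGFP261-Off11	CATGTAGCCTTCAGGCATGTgGG	GTAGCCTTCAGGCATGTgGG	ND	24.34	ND	ND	ND	ND
sgGFP379-On	GAAGGGCATCGACTTCAAGGaGG	GGGCATCGACTTCAAGGaGG	99.30	98.67	78.17	44.87	75.93	42
sgGFP379-Off3	ACGGGGCATCGATTTCAAGGaGG	GGGCATCGATTTCAAGGaGG	27.44	ND	23.92	ND	28.71	ND
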