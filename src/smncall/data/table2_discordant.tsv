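sample	haplotypes	mlpa_smn1_e7	mlpa_e7_flag	mlpa_smn1_e8	mlpa_e8_flag	mlpa_smn2_e7	mlpa_smn2_e8	qpcr_smn1_e7	qpcr_e7_flag	qpcr_smn1_e8	qpcr_e8_flag	casma_smn1	casma_smn2
RT01	SMN1*2 + SMN2*1	2	NLT	2	NLT	1	1	1	.	2	.	2	1
RT02	SMN1*1 + SMN1[c.-39A>G]*1 + SMN2*2	2	.	2	.	2	2	1	.	2	NLT	2	2
RT03	SMN1*2 + SMN2*1	2	.	2	.	1	1	1	.	2	.	2	1
RT04	SMN1*2 + SMN2*1	2	.	2	.	1	1	1	.	2	.	2	1
RT05	SMN1*2 + SMN2*1	2	.	2	.	1	1	1	NLT	2	.	2	1
RT06	SMN1*2 + SMN2*2	2	.	2	.	2	2	1	NLT	2	.	2	2
RT07	SMN1*3	3	.	3	.	0	0	2	NLT	2	.	3	0
RT08	SMN1*3 + SMN2*1	3	.	3	.	1	1	2	.	3	NUT	3	1
RT09	SMN1*3 + SMN2*1	3	.	3	.	1	1	2	.	2	.	3	1
RT10	SMN1*3 + SMN2*1	3	.	3	.	1	1	2	.	3	.	3	1
RT11	SMN1*3 + SMN2*1	3	.	3	.	1	1	2	.	3	.	3	1
RT12	SMN1*3 + SMN2*1	2	NLT	2	NLT	1	1	3	.	3	.	3	1
RT13	SMN1*3 + SMN2*1	2	NLT	2	NLT	1	1	3	NUT	3	.	3	1
RT14	SMN1*3 + SMN2*2	2	NLT	2	NLT	2	2	3	NUT	3	.	3	2
RT15	SMN1*3 + SMN2*2	2	NLT	2	NLT	2	2	3	.	2	.	3	2
RT16	SMN1*4 + SMN2*2	2	NLT	2	NLT	2	2	4	.	4	.	4	2
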