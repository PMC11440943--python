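sample	haplotypes	mlpa_smn1_e7	mlpa_smn1_e8	mlpa_smn2_e7	mlpa_smn2_e8	qpcr_smn1_e7	qpcr_smn1_e8	casma_smn1_e7	casma_smn1_e8	casma_smn2_e7	casma_smn2_e8
YZ01	SMN1*1 + SMN2*1	1	1	1	1	1	1	1	1	1	1
YZ02	SMN1*1 + SMN2*3	1	1	3	3	1	1	1	1	3	3
YZ03	SMN1*1 + SMN2*3	1	1	3	3	1	1	1	1	3	3
YZ04	SMN1*1 + SMN2*3	1	1	3	3	1	1	1	1	3	3
YZ05	SMN1*1 + SMN2*3	1	1	3	3	1	1	1	1	3	3
YZ06	SMN1*1 + SMN2*3	1	1	3	3	1	1	1	1	3	3
YZ07	SMN1*2 + SMN2*1	2	2	1	1	2	2	2	2	1	1
YZ08	SMN1*3	3	3	0	0	3	3	3	3	0	0
YZ09	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ10	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ11	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ12	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ13	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ14	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ15	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ16	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ17	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ18	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ19	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ20	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ21	SMN1*3 + SMN2*1	3	3	1	1	3	3	3	3	1	1
YZ22	SMN1*3 + SMN2*3	3	3	3	3	3	3	3	3	3	3
YZ23	SMN1*3 + SMN2*3	3	3	3	3	3	3	3	3	3	3
YZ24	SMN1*3 + SMN2*2	3	3	2	2	3	3	3	3	2	2
YZ25	SMN1*3 + SMN2*2	3	3	2	2	3	3	3	3	2	2
YZ26	SMN1*3 + SMN2*2	3	3	2	2	3	3	3	3	2	2
YZ27	SMN1*3 + SMN2*2	3	3	2	2	3	3	3	3	2	2
YZ28	SMN1*3 + SMN2*2	3	3	2	2	3	3	3	3	2	2
YZ29	SMN1*3 + SMN2*2	3	3	2	2	3	3	3	3	2	2
YZ30	SMN1*3 + SMN2*2	3	3	2	2	3	3	3	3	2	2
YZ31	SMN1*4 + SMN2*1	4	4	1	1	4	4	4	4	1	1
YZ32	SMN1*2 + SMN2*1 + SMN2[c.*3+100A>C;c.*3+215A>G;c.*239A>G]*1	2	3	2	1	2	3	2	3	2	1
YZ33	SMN1*2 + SMN2*1 + SMN2[c.*239A>G]*1	2	3	2	1	2	3	2	3	2	1
YZ34	SMN1*2 + SMN2*1 + SMN2[c.*239A>G]*1	2	3	2	1	2	3	2	3	2	1
YZ35	SMN1*2 + SMN2*1 + SMN2[c.*239A>G]*1	2	3	2	1	2	3	2	3	2	1
YZ36	SMN1*2 + SMN2*1 + SMN2[c.*239A>G]*1	2	3	2	1	2	3	2	3	2	1
YZ37	SMN1*2 + SMN2*1 + SMN2[c.*239A>G]*1	2	3	2	1	2	3	2	3	2	1
YZ38	SMN1*2 + SMN2*1 + SMN2[c.*239A>G]*1	2	3	2	1	2	3	2	3	2	1
YZ39	SMN1*3 + SMN2[c.*239A>G]*1	3	4	1	0	3	4	3	4	1	0
YZ40	SMN1*2 + SMN1[c.*239G>A]*1 + SMN2*1	3	2	1	2	3	2	3	2	1	2
YZ41	SMN1*1 + SMN1[c.*239G>A]*1 + SMN2*2	2	1	2	3	2	1	2	1	2	3
YZ42	SMN1*1 + SMN1[c.*239G>A]*1 + SMN2*2	2	1	2	3	2	1	2	1	2	3
YZ43	SMN1*1 + SMN1[c.*239G>A]*1 + SMN2*2	2	1	2	3	2	1	2	1	2	3
YZ44	SMN1*1 + SMN1[c.*237_*238del]*1 + SMN2*1	2	1	1	1	2	1	2	2	1	1
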