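smn1_e7	smn1_e8	smn2_e7	smn2_e8	n
1	1	1	1	4
1	1	2	2	10
1	1	3	3	9
2	1	1	1	1
2	1	1	2	1
2	1	2	2	2
2	1	2	3	5
2	2	0	0	64
2	2	1	0	3
2	2	1	1	455
2	2	1	2	1
2	2	2	1	4
2	2	2	2	716
2	2	3	2	1
2	2	3	3	33
2	3	1	0	8
2	3	2	1	18
2	3	2	2	1
3	2	1	2	1
3	3	0	0	2
3	3	1	0	1
3	3	1	1	35
3	3	2	1	1
3	3	2	2	19
3	3	3	3	2
3	4	1	0	1
4	4	1	1	1
4	4	2	2	1
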