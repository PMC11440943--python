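member	role	gene	fingerprint	copy_number
I-1	father	SMN1	150:T;812:G	1
I-1	father	SMN1	412:C;2710:A	1
I-1	father	SMN2	1260:A;1320:T;1700:G;1950:G;2300:A;905:C	1
I-2	mother	SMN1	.	1
I-2	mother	SMN2	1260:A;1320:T;1700:G;1950:G;2300:A;1105:T	1
I-2	mother	SMN2	1260:A;1320:T;1700:G;1950:G;2300:A;2680:G	1
II-2	child	SMN1	150:T;812:G	1
II-2	child	SMN1	412:C;2710:A	1
II-2	child	SMN2	1260:A;1320:T;1700:G;1950:G;2300:A;1105:T	1
II-2	child	SMN2	1260:A;1320:T;1700:G;1950:G;2300:A;2680:G	1
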