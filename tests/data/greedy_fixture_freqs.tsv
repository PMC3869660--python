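snp_id	a	b	c
s1	0.9	0.1	0.5
s2	0.8	0.2	0.2
s3	0.1	0.9	0.9
s4	0.5	0.5	0.0
s5	0.95	0.5	0.05
s6	0.3	0.7	0.5
s7	0.6	0.4	0.9
s8	0.2	0.2	0.8
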