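rank	snp_id	selected_for	in_value
1	s5	a:c	0.494631937214
2	s1	a:b	0.368064207168
3	s4	b:c	0.215761554339
4	s8	b:c	0.192744757022
5	s3	a:b	0.368064207168
6	s7	b:c	0.148399318834
7	s2	a:c	0.192744757022
8	s6	b:c	0.021005925702
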