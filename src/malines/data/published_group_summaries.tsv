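strain	diet	n_snv	n_insertion	n_deletion	ts_tv	coding_noncoding	genic_intergenic	at_bias	u_snv_e9	u_snv_ci_e9	u_ins_e10	u_ins_ci_e10	u_del_e10	u_del_ci_e10	generations	newly_analyzed
PS312	E. coli OP50	944	243	253	0.79	0.43	2.59	5.60	2.35	1.14	5.95	0.92	6.18	5.73	142	0
RSC011	N. sp. L76	484	66	123	1.03	0.34	2.72	3.30	1.88	0.65	2.57	2.43	4.78	4.42	100	1
RSC019	A. tumefaciens L27	431	56	77	1.30	0.41	1.99	4.66	1.69	0.55	2.19	2.09	3.01	3.01	100	1
RSC019	E. coli OP50	569	74	115	1.21	0.41	2.16	5.24	2.23	0.70	2.90	2.70	4.51	3.66	100	1
RSC019	H. alvei LRB17	466	41	89	0.96	0.39	1.93	5.24	1.74	0.69	1.53	1.87	3.32	2.86	100	1
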