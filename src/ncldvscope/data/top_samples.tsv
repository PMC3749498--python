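sample_id	depth_zone	total_bp	n_reads	gc_pct	avg_read_bp	n_orfs	avg_orf_aa
3_S	SRF	21533646	63994	37	336	65656	99
4_S	SRF	52953075	140754	38	376	149018	108
6_S	SRF	36129806	95255	48	379	98996	111
7_S	SRF	98750180	332049	38	297	335408	90
7_D	DCM	279389388	1117888	37	250	1013853	81
23_S	SRF	67695268	196190	39	345	201447	101
23_D	DCM	83539478	239447	38	349	246948	102
30_S	SRF	89180466	256028	37	348	268616	101
31_S	SRF	245463121	614743	39	399	660949	114
36_S	SRF	245945064	737506	39	333	757448	100
38_S	SRF	214253370	601110	39	356	631351	103
38_Z	OMZ	223188575	638843	45	349	659041	104
39_S	SRF	233273851	590664	43	395	629501	114
39_Z	OMZ	249558778	679589	46	367	708056	108
43_S	SRF	167515516	529506	37	316	545641	93
46_S	SRF	251310870	648425	41	388	689641	112
49_S	SRF	222417021	680573	43	327	696974	98
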