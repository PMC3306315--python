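# Known vascular genes among the upregulated entries of the etsrp-overexpression contrast.
# source: cluster = derived from the top two GO functional-annotation clusters;
#         manual_scan = identified by visual inspection of the upregulated list (15 rows).
unigene_id	gene_id	fold_change	p_value	source
Dr.118570	LOC561493	315.3	1.8E-196	cluster
Dr.133475	LOC100151130	254.8	3.62E-10	manual_scan
Dr.85502	mrc1	225.7	4.0E-20	cluster
Dr.47591	etv2	219.0	4.9E-237	cluster
Dr.84866	LOC100005159	159.4	9.6E-04	cluster
Dr.152900	LOC572378	110.1	4.90E-03	manual_scan
Dr.107226	sc:d0254	37.9	5.0E-10	cluster
Dr.78408	fli1a	37.6	3.0E-61	cluster
Dr.86352	zgc:113016	36.3	1.5E-09	cluster
Dr.36543	aqp8a	32.6	4.9E-237	cluster
Dr.83871	rasgrp3	32.6	2.6E-08	cluster
Dr.89996	egfl7	21.6	1.5E-10	manual_scan
Dr.79866	yrk	20.9	7.0E-151	cluster
Dr.103153	plxnd1	20.1	4.9E-237	cluster
Dr.118013	cdh5	19.1	3.5E-18	cluster
Dr.80968	fli1b	16.3	1.8E-07	cluster
Dr.77989	dusp5	14.8	1.2E-16	cluster
Dr.76027	ker18	12.5	2.1E-05	manual_scan
Dr.75812	tal1	12.4	6.9E-08	cluster
Dr.150623	f10	9.8	7.2E-04	manual_scan
Dr.89035	tmem88a	9.2	7.2E-16	cluster
Dr.75094	kdrl	7.8	1.6E-36	cluster
Dr.80363	clec14a	6.3	4.0E-06	cluster
Dr.151971	sox7	6.1	4.4E-02	cluster
Dr.74559	scarf1	5.6	1.4E-02	manual_scan
Dr.75958	robo4	5.4	3.7E-14	manual_scan
Dr.87001	cldn5b	5.1	1.6E-15	manual_scan
Dr.83306	mcam	4.7	4.0E-39	cluster
Dr.52827	zfpm2b	4.4	1.5E-05	cluster
Dr.5660	crip2	4.4	9.4E-11	cluster
Dr.107483	sb:cb911	4.3	3.1E-03	manual_scan
Dr.75385	LOC563577	4.2	3.1E-06	cluster
Dr.132454	smox	3.2	4.8E-55	manual_scan
Dr.599	ldb2a	3.2	3.7E-03	cluster
Dr.81683	rbpms2	3.1	1.2E-09	cluster
Dr.81298	flt4	3.0	2.1E-29	cluster
Dr.79626	ildr2	2.9	1.4E-21	manual_scan
Dr.132331	nrp1b	2.9	2.5E-15	manual_scan
Dr.78142	acvrl1	2.8	6.7E-19	manual_scan
Dr.135121	stab2	2.7	4.5E-10	cluster
Dr.76054	tpm4	2.6	1.9E-37	cluster
Dr.79413	jam2	2.6	1.5E-21	manual_scan
Dr.91385	kdr	2.5	2.5E-29	cluster
Dr.88777	pdlim4	2.5	2.3E-02	cluster
Dr.76395	C8orf4	2.4	1.0E-13	cluster
Dr.37960	fgfrl1b	2.4	2.1E-07	cluster
Dr.75409	gapdhs	2.3	2.7E-03	cluster
Dr.22604	amot	2.3	2.4E-08	manual_scan
Dr.80539	elovl1b	2.3	2.7E-09	cluster
Dr.82429	LOC563907	2.1	6.5E-03	cluster
Dr.104822	si:dkey-261h17.1	2.1	4.6E-107	cluster
Dr.78553	micall2	2.0	5.6E-18	cluster
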