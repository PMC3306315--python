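# Genes examined by whole-mount in situ hybridization from the etsrp-overexpression dataset.
# vascular_24hpf: expressed in vascular endothelial cells at 24 hpf (bold in the published table; 40 rows).
# positive_control: previously published vascular gene included as the WISH positive control (she).
# vascular_confirmed: newly confirmed vascular expression = vascular_24hpf AND NOT positive_control (39 rows).
unigene_id	gene_id	fold_change	p_value	vascular_24hpf	positive_control	vascular_confirmed
Dr.153782	lyg2	1899.9	4.5E-26	True	False	True
Dr.149118	cdc42GAP1	441.5	1.9E-21	True	False	True
Dr.118570	she	315.3	1.8E-196	True	True	False
Dr.40434	ms4a17a.11	300.4	3.5E-06	False	False	False
Dr.84343	spa17	225.9	1.1E-09	True	False	True
Dr.103328	klhl4	198.7	2.0E-05	True	False	True
Dr.110713	LOC100149611	165.4	3.8E-08	True	False	True
Dr.111220	gpr183	151.4	1.9E-04	True	False	True
Dr.78041	xirp2	95.0	7.6E-56	True	False	True
Dr.134501	rassf4	51.4	1.4E-02	True	False	True
Dr.91332	tmem119b	50.7	1.8E-42	True	False	True
Dr.89765	myl9	50.1	5.7E-113	True	False	True
Dr.115399	cntn4	38.4	1.4E-02	True	False	True
Dr.84022	myo1E	37.9	8.4E-03	True	False	True
Dr.75719	iclp2	32.2	1.3E-16	True	False	True
Dr.88587	rgl2	28.2	1.9E-36	True	False	True
Dr.76656	capn8	23.5	1.1E-05	True	False	True
Dr.11010	mhc1uea	21.8	2.4E-21	True	False	True
Dr.77849	dgki	17.4	4.4E-04	True	False	True
Dr.117215	ifit5	15.1	2.1E-03	True	False	True
Dr.134371	plscr2	10.6	1.5E-47	False	False	False
Dr.7340	slc16a9a	9.3	2.1E-23	False	False	False
Dr.89035	tmem88a	9.2	7.2E-16	True	False	True
Dr.100033	rasa4	7.8	2.3E-04	True	False	True
Dr.96217	samd10	7.2	1.2E-02	True	False	True
Dr.114623	cald1	6.8	1.6E-22	True	False	True
Dr.91020	sept5b	6.7	1.3E-05	True	False	True
Dr.119058	zgc:171494	6.4	2.8E-02	True	False	True
Dr.84654	ankdd1a	6.4	2.5E-09	True	False	True
Dr.91634	sh3bp4	6.0	2.0E-06	True	False	True
Dr.82145	myof	5.7	4.1E-32	True	False	True
Dr.84960	grtp1b	5.6	1.4E-02	True	False	True
Dr.85673	tagap	5.5	2.8E-03	True	False	True
Dr.124255	plc-l2	5.2	2.9E-05	False	False	False
Dr.80073	fhl3	5.1	5.4E-37	True	False	True
Dr.133138	irf9	4.9	9.4E-12	True	False	True
Dr.18530	FAM166B	4.4	1.8E-04	False	False	False
Dr.5660	crip2	4.4	9.4E-11	False	False	False
Dr.135601	zcchc4	4.0	4.4E-03	False	False	False
Dr.77065	hmha1	4.0	9.1E-12	True	False	True
Dr.47691	ankrd58	3.8	3.1E-06	True	False	True
Dr.92393	ccdc135	3.6	5.2E-05	True	False	True
Dr.83578	tmem151b	3.5	1.9E-03	True	False	True
Dr.81141	si:ch211-132b12.7	3.5	1.4E-02	False	False	False
Dr.78875	sept9b	3.3	1.3E-05	False	False	False
Dr.83297	aff3	2.4	1.5E-10	True	False	True
Dr.90997	tmem179	2.0	2.8E-09	False	False	False
Dr.34190	si:ch211-250g4.3	2.0	4.5E-04	True	False	True
Dr.107097	acsbg2	1.9	2.8E-64	True	False	True
Dr.77920	arhgap27	1.9	9.1E-07	True	False	True
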