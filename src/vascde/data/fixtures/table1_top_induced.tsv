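# Top annotated genes induced in the etsrp-overexpression condition (fold change of
# normalized pooled counts; Fisher's exact test p-value before adjustment).
unigene_id	gene_id	fold_change	p_value
Dr.24158	srgn	1920.8	7.7E-53
Dr.153782	LOC100151241	1899.9	4.5E-26
Dr.83594	crabp1a	917.4	5.1E-17
Dr.141228	LOC558783	452.8	1.1E-05
Dr.149118	LOC798186	441.5	1.9E-21
Dr.118570	LOC561493	315.3	1.8E-196
Dr.40434	ms4a17a.11	300.4	3.5E-06
Dr.133475	LOC100151130	254.8	3.6E-10
Dr.37870	ckmb	231.6	3.8E-07
Dr.92232	efcab2	231.5	8.4E-03
Dr.84343	zgc:153721	225.9	1.1E-09
Dr.85502	mrc1	225.7	4.0E-20
Dr.47591	etv2	219.0	4.9E-237
Dr.110840	LOC100006361	217.2	4.9E-03
Dr.103328	zgc:162298	198.7	2.0E-05
Dr.86665	nhlh2	180.6	2.1E-08
Dr.114377	zgc:173594	175.7	2.8E-03
Dr.110713	LOC100149611	165.4	3.8E-08
Dr.84866	LOC100005159	159.4	9.6E-04
Dr.111220	gpr183	151.4	1.9E-04
Dr.113631	LOC568486	136.1	2.5E-02
Dr.82184	LOC569386	123.4	6.2E-06
Dr.124732	LOC100148619	113.9	1.4E-02
Dr.152900	LOC572378	110.1	4.9E-03
Dr.142587	csf3r	104.9	6.5E-05
Dr.100658	LOC100004843	104.1	2.8E-03
Dr.149641	LOC558126	103.1	4.9E-03
Dr.151919	si:ch211-10e8.4	102.9	8.4E-03
Dr.81739	kcnh2	101.5	2.0E-09
Dr.78041	xirp2	95.0	7.6E-56
Dr.118849	zgc:63958	91.4	1.7E-03
Dr.102595	LOC568153	86.4	2.8E-03
Dr.115871	LOC569038	85.0	2.5E-02
Dr.83127	LOC100001838	79.5	1.4E-02
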