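# SYNTHETIC curation-chain fixture. The 38 retained cluster-derived genes are the 37
# published cluster-derived vascular gene ids plus one synthetic placeholder (one table row
# was lost in text extraction); the 18 'no_endo_evidence' and 12 'not_endothelial' excluded
# genes are synthetic placeholder ids (their published identities are only partially public).
# The 15 manual_scan rows are the published visually-identified vascular genes.
# Chain: union(top1, top2) = 68 -> minus 18 -> minus 12 -> 38 -> plus 15 manual -> 53.
gene_id	in_cluster_top1	in_cluster_top2	manual_scan	exclusion
Dr.118570	True	False	False	none
Dr.85502	True	False	False	none
Dr.47591	True	False	False	none
Dr.84866	True	False	False	none
Dr.107226	True	False	False	none
Dr.78408	True	False	False	none
Dr.86352	True	False	False	none
Dr.36543	True	False	False	none
Dr.83871	True	False	False	none
Dr.79866	True	False	False	none
Dr.103153	True	False	False	none
Dr.118013	True	False	False	none
Dr.80968	True	False	False	none
Dr.77989	True	False	False	none
Dr.75812	True	False	False	none
Dr.89035	True	False	False	none
Dr.75094	True	False	False	none
Dr.80363	True	False	False	none
Dr.151971	True	False	False	none
Dr.83306	True	False	False	none
Dr.52827	True	False	False	none
Dr.5660	True	False	False	none
Dr.75385	True	False	False	none
Dr.599	True	False	False	none
Dr.81683	True	False	False	none
Dr.81298	True	False	False	none
Dr.135121	True	False	False	none
Dr.76054	True	False	False	none
Dr.91385	True	False	False	none
Dr.88777	True	False	False	none
Dr.76395	True	False	False	none
Dr.37960	True	False	False	none
Dr.75409	True	False	False	none
Dr.80539	True	False	False	none
Dr.82429	True	True	False	none
Dr.104822	True	True	False	none
Dr.78553	True	True	False	none
SYN.RETAINED.01	True	True	False	none
SYN.MESO.01	True	True	False	no_endo_evidence
SYN.MESO.02	True	True	False	no_endo_evidence
SYN.MESO.03	False	True	False	no_endo_evidence
SYN.MESO.04	False	True	False	no_endo_evidence
SYN.MESO.05	False	True	False	no_endo_evidence
SYN.MESO.06	False	True	False	no_endo_evidence
SYN.MESO.07	False	True	False	no_endo_evidence
SYN.MESO.08	False	True	False	no_endo_evidence
SYN.MESO.09	False	True	False	no_endo_evidence
SYN.MESO.10	False	True	False	no_endo_evidence
SYN.MESO.11	False	True	False	no_endo_evidence
SYN.MESO.12	False	True	False	no_endo_evidence
SYN.MESO.13	False	True	False	no_endo_evidence
SYN.MESO.14	False	True	False	no_endo_evidence
SYN.MESO.15	False	True	False	no_endo_evidence
SYN.MESO.16	False	True	False	no_endo_evidence
SYN.MESO.17	False	True	False	no_endo_evidence
SYN.MESO.18	False	True	False	no_endo_evidence
SYN.NONENDO.01	False	True	False	not_endothelial
SYN.NONENDO.02	False	True	False	not_endothelial
SYN.NONENDO.03	False	True	False	not_endothelial
SYN.NONENDO.04	False	True	False	not_endothelial
SYN.NONENDO.05	False	True	False	not_endothelial
SYN.NONENDO.06	False	True	False	not_endothelial
SYN.NONENDO.07	False	True	False	not_endothelial
SYN.NONENDO.08	False	True	False	not_endothelial
SYN.NONENDO.09	False	True	False	not_endothelial
SYN.NONENDO.10	False	True	False	not_endothelial
SYN.NONENDO.11	False	True	False	not_endothelial
SYN.NONENDO.12	False	True	False	not_endothelial
Dr.133475	False	False	True	none
Dr.152900	False	False	True	none
Dr.89996	False	False	True	none
Dr.76027	False	False	True	none
Dr.150623	False	False	True	none
Dr.74559	False	False	True	none
Dr.75958	False	False	True	none
Dr.87001	False	False	True	none
Dr.107483	False	False	True	none
Dr.132454	False	False	True	none
Dr.79626	False	False	True	none
Dr.132331	False	False	True	none
Dr.78142	False	False	True	none
Dr.79413	False	False	True	none
Dr.22604	False	False	True	none
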