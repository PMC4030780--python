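gene	disease_hpo	known_human_disease_gene	identical_variant_reported_pathogenic	damaging_variant_class_in_known_domain	dosage_sensitive	model_organism_phenotype_overlap	functional_plausibility	expression_relevant
FGFR3	HP:0002652;HP:0003026	1	1	0	0	0	0	0
COL2A1	HP:0001627;HP:0001762;HP:0002652	1	0	1	0	0	0	0
OFD1	HP:0001274;HP:0000202;HP:0011297	1	0	0	1	0	0	0
PRKDC	HP:0002721;HP:0004313;HP:0000252;HP:0001999	1	0	0	0	0	1	0
FRAS1	HP:0000528;HP:0001159;HP:0000104	1	0	0	0	1	0	0
NF1	HP:0000957;HP:0001067;HP:0001328;HP:0001627	1	1	0	0	1	1	0
SMARCC2	.	0	0	0	0	0	1	1
RERE	.	0	0	0	0	1	0	0
DLC1	.	0	0	0	0	1	0	0
MACF1	.	0	0	0	0	1	0	0
GRIN2A	HP:0001250;HP:0002069;HP:0010818;HP:0001249	1	0	0	0	0	0	0
PARD3B	.	0	0	0	0	0	0	0
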