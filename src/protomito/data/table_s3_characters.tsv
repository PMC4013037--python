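# Phenetic matrix of 11 discrete characters of COX gene-cluster
# architecture, used to compare bacterial operons with the COX gene
# arrangement of protist mitochondria.
#
# INTERPRETIVE FIXTURE: the published legend states the matrix has 11
# independent characters but does not enumerate them; the characters below
# are reconstructed from the operon-architecture evidence discussed in the
# source (fusion states, syntenic diads, transcription order, COX4
# presence, COX3 helix count, phospholipid-binding category, Nrf-like
# attachment, assembly genes). The matrix is editable data, not code.
#
# Characters:
#  c01 COX2 fused with c-type cytochrome (0/1)
#  c02 COX1 fused with COX4 (0/1)
#  c03 COX1 fused with COX3 (0/1)
#  c04 isolated COX4 gene present (0/1)
#  c05 COX11-COX3 syntenic diad (0/1)
#  c06 COX1 adjacent to COX2 (0/1)
#  c07 reverse order of transcription of the core (0/1)
#  c08 COX3 transmembrane-helix count (0/5/7)
#  c09 COX3 phospholipid-binding category (weak/intermediate/strong)
#  c10 attachment to a Nrf-like gene cluster (0/1)
#  c11 assembly genes (ctaA/ctaB/ctaG) within the operon (0/1)
taxon	c01	c02	c03	c04	c05	c06	c07	c08	c09	c10	c11
protist mitochondria	1	1	1	0	0	1	1	5	intermediate	0	1
Methylobacterium extorquens PA1 (a-II)	1	1	0	0	0	1	0	5	intermediate	0	1
Tistrella mobilis (a-II)	1	1	0	0	0	1	0	5	intermediate	0	1
Roseobacter litoralis (b)	0	0	0	0	1	1	0	7	strong	0	1
exemplar a-I	1	0	0	1	0	1	0	7	weak	1	1
exemplar a-III	0	0	1	1	0	1	0	7	weak	0	1
exemplar a-IV	0	0	1	1	0	1	0	0	weak	0	1
beta-proteobacterial ab transition	0	0	0	1	0	1	0	7	intermediate	0	0
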