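# Exemplar COX gene clusters, one per operon type/subtype, transcribed from
# the published graphical operon diagrams. Gene order is the normalized
# (forward transcription) order; distances between genes are not encoded.
organism	cluster_id	gene_index	strand	product_label	protein_length	domain_labels
exemplar a-I	aI	0	+	regulator	210
exemplar a-I	aI	1	+	NrfD_like	320
exemplar a-I	aI	2	+	NrfD2	410
exemplar a-I	aI	3	+	COX2	430	cytochrome_c
exemplar a-I	aI	4	+	COX1	530
exemplar a-I	aI	5	+	COX3	270
exemplar a-I	aI	6	+	cytochrome_c	120
exemplar a-II	aII	0	+	COX2	290
exemplar a-II	aII	1	+	COX1	650	COX4_like
exemplar a-II	aII	2	+	COX3	165
exemplar a-II	aII	3	+	PQQ_dehydrogenase	600
exemplar a-II	aII	4	+	SURF1	250
exemplar a-III	aIII	0	+	COX2	300
exemplar a-III	aIII	1	+	COX1	540
exemplar a-III	aIII	2	+	COX3	270
exemplar a-III	aIII	3	+	COX3	265
exemplar a-III	aIII	4	+	ctaB/COX10	310
exemplar a-III	aIII	5	+	ctaG/COX11	200
exemplar a-IV	aIV	0	+	COX2	280
exemplar a-IV	aIV	1	+	COX1	820
exemplar a-IV	aIV	2	+	ctaB/COX10	300
exemplar b	b	0	+	ctaA/COX15	340
exemplar b	b	1	+	COX2	300
exemplar b	b	2	+	COX1	530
exemplar b	b	3	+	SCO	200
exemplar b	b	4	+	ctaG/COX11	200
exemplar b	b	5	+	COX3	270
exemplar b	b	6	+	cytochrome_c	110
exemplar ab transition	ab	0	+	COX2	300
exemplar ab transition	ab	1	+	COX1	540
exemplar ab transition	ab	2	+	COX3	270
exemplar ab transition	ab	3	+	ABC_transporter	420
exemplar ab transition	ab	4	+	regulator	220
exemplar incomplete	dead	0	+	COX2	300
exemplar incomplete	dead	1	+	COX1	530
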