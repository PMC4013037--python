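# Candidate progenitors for the bioenergetic evolution of mitochondria,
# with the full endowment used for loss/acquisition edit scoring: systems,
# COX operon types, ISP forms. Transcribed from the published
# possible-progenitors diagram and its discussion.
#
# Interpretive points, documented here and in docs/methods.md:
#  - the proto-mitochondrial target carries two COX operons (one of type a,
#    modelled as a-II, and one of type b) and the in-operon ISP1 form;
#  - pathway-B sources (Magnetospirillum / Roseobacter / Maricaulis) carry
#    an ISP that groups away from the mitochondrial homologues, encoded
#    here as the isolated-cluster form ISP2; their two losses are then
#    {cbb3 oxidase, ISP2} and their two acquisitions {COX operon a-II, ISP1};
#  - photosynthesis loss is not drawn in the source diagram and is left out
#    of this fixture ("no" throughout);
#  - pathway assignment is annotation only, it does not enter the scoring.
organism	taxon_group	systems	cox_operon_types	isp_forms	photosynthesis	n_met_markers	pathway
proto-mitochondrion	mitochondria	BC1,AA3,NMET	a-II,b	ISP1	no	NirBD	target
Beijerinckia indica	alpha-proteobacteria	BC1,AA3,BD,NMET	b	ISP1	no	NirBD	A
Magnetospirillum magneticum	alpha-proteobacteria	BC1,AA3,CBB3,NMET	b	ISP2	no	NirB	B
Roseobacter litoralis	alpha-proteobacteria	BC1,AA3,CBB3,NMET	b	ISP2	no	NirB	B
Maricaulis maris	alpha-proteobacteria	BC1,AA3,CBB3,NMET	b	ISP2	no		B
Methylocystis sp. SC2	alpha-proteobacteria	BC1,AA3,CBB3,BD,NMET	a-II,b	ISP1,ISP2	no	NirB	C
Methylobacterium extorquens PA1	alpha-proteobacteria	BC1,AA3,CBB3,BD,NMET	a-II,b	ISP1,ISP2	no	NiaD_related	C
Tistrella mobilis	alpha-proteobacteria	BC1,AA3,CBB3,BO,BD,NMET	a-II,b	ISP1	no	NirB	D
Rhodopseudomonas palustris BisA53	alpha-proteobacteria	BC1,AA3,CBB3,BD,NMET	a-II,b	ISP1,ISP2	no	NiaD_related	D
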