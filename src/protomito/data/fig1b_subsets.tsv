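# Attested subsets of the six quinol-to-oxygen bioenergetic systems
# (BC1 = cytochrome bc1 complex, AA3 = aa3-type cytochrome c oxidase,
# CBB3 = cbb3-type oxidase, BO = bo ubiquinol oxidase, BD = bd ubiquinol
# oxidase, NMET = bioenergy-linked N-metabolism), with representative
# organisms. Transcribed from the published subset diagram of pathways of
# mitochondrial bioenergetic evolution.
#
# The membership of the pathway-B subset (Magnetospirillum / Roseobacter /
# Maricaulis) is read from the figure, not stated in prose; it carries the
# four systems whose single-system loss yields the fungal/protist
# mitochondrial subset via the cbb3 branch.
# The "discounted" flag marks the Rickettsia subset: the route from it to
# mitochondria is drawn dashed in the source because the symbiotic event
# occurred only once.
organism	taxon_group	systems	cox_operon_types	isp_forms	photosynthesis	n_met_markers	discounted
Rhodopseudomonas palustris	alpha-proteobacteria	BC1,AA3,CBB3,BO,BD,NMET				NirB	no
Rhodopseudomonas palustris BisA53	alpha-proteobacteria	BC1,AA3,CBB3,BD,NMET				NiaD_related	no
Micavibrio aeruginosavorus	alpha-proteobacteria	BC1,AA3,BD,NMET					no
Beijerinckia indica	alpha-proteobacteria	BC1,AA3,BD,NMET				NirBD	no
Magnetospirillum magneticum	alpha-proteobacteria	BC1,AA3,CBB3,NMET				NirB	no
Roseobacter litoralis	alpha-proteobacteria	BC1,AA3,CBB3,NMET			yes	NirB	no
Maricaulis maris	alpha-proteobacteria	BC1,AA3,CBB3,NMET					no
Rickettsia felis	alpha-proteobacteria	BC1,AA3,BD					yes
Wolbachia	alpha-proteobacteria	BC1,AA3,BD					yes
fungal mitochondria	mitochondria	BC1,AA3,NMET				NirBD	no
heterokont mitochondria	mitochondria	BC1,AA3,NMET				NirBD	no
metazoan mitochondria	mitochondria	BC1,AA3					no
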