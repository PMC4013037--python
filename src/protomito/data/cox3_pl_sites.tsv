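# Phospholipid-binding site map for COX3, anchored on the mature beef
# reference (1-based positions on the ungapped reference sequence).
# pl_class: PE = phosphatidyl-ethanolamine, PG = phosphatidyl-glycerol.
# role: H_or_pi_bond = residue binding the phospholipid with an H or pi
# bond; E90_like = residue corresponding to E90 of beef COX3, which lies
# near a bound phospholipid modulating oxygen entry into the catalytic
# site. E90-like sites are reported separately and excluded from per-PL
# conserved counts.
#
# INTERPRETIVE FIXTURE: the published text does not enumerate the site
# positions (they derive from the bovine oxidase structure); this editable
# transcription pairs with the synthetic reference sequence shipped
# alongside (cox3_reference.synthetic.fasta) and preserves the published
# scoring rules (conserved = identical or positive substitution; binding
# is weak when fewer than 3 sites are conserved for each PL).
site_id	reference_position	pl_class	role
PE1	11	PE	H_or_pi_bond
PE2	15	PE	H_or_pi_bond
PE3	29	PE	H_or_pi_bond
PE4	156	PE	H_or_pi_bond
PE5	193	PE	H_or_pi_bond
PG1	34	PG	H_or_pi_bond
PG2	38	PG	H_or_pi_bond
PG3	91	PG	H_or_pi_bond
PG4	160	PG	H_or_pi_bond
PG5	197	PG	H_or_pi_bond
E90	90	other	E90_like
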