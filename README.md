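# protomito

Comparative bioenergetics of α-proteobacteria and the reconstruction of
proto-mitochondrial ancestry.

Mitochondria descend from an α-proteobacterial endosymbiont whose identity
is still contested, partly because sequence-based phylogenies of fast-
evolving mitochondrial genes are unstable. An alternative line of evidence
compares the *bioenergetic endowments* of living bacteria — which of the
six quinol-to-oxygen systems (the cytochrome *bc₁* complex, the *aa₃*-type
cytochrome *c* oxidase, the *cbb₃* oxidase, the *bo* and *bd* ubiquinol
oxidases, and bioenergy-linked N-metabolism) an organism encodes — together
with the fine architecture of its COX operons, COX3 phospholipid-binding
sites and Rieske iron–sulfur protein (ISP). `protomito` implements that
comparative pipeline as a tested, reusable Python package:

- **profiles / pathway_graph** — endowment data model, census and
  frequency reports; a parsimony graph whose edges are single-system
  losses between attested subsets, and loss/acquisition *edit scoring* of
  candidate ancestors against the proto-mitochondrial target (an
  acquisition via lateral gene transfer counts as costlier than a loss).
- **operon_classifier** — typing of COX gene clusters into a-I…a-IV, b,
  a–b transition or incomplete; fusion detection (COX1–COX4, COX1-3
  chimaera, COX2–cytochrome *c*, cytochrome *b*–*c₁*); Kyte–Doolittle
  hydropathy with a fixed 19-residue window for transmembrane segments;
  embedded/split COX3 detection in very long COX1 proteins and the deduced
  "minimal" protist COX operon.
- **similarity_scoring** — COX4-likeness: column-wise identity counting of
  a query segment against reference subunit-IV blocks, with the call fixed
  at ≥ 10 total identities.
- **cox3_pl** — phospholipid-binding strength of COX3: conservation of
  PE/PG-binding sites mapped onto the mature beef reference; binding is
  *weak* when fewer than 3 sites are conserved for each phospholipid.
- **isp_indels** — CIMit (Conserved Indel vs. Mitochondria) detection in
  ISP alignments, per-sequence indel-presence matrices, and ISP1/ISP2 form
  assignment.
- **phenetics_trees** — shared-character scores over an 11-character operon
  matrix, p-distances, an in-repo neighbour-joining implementation with
  Newick output, and monophyly checks.
- **synthetic_data** — seeded generators for every input class (clusters,
  membrane proteins, alignments with planted indels/conservation, random
  endowments) plus the packaged in-source fixtures.

## Worked example

Counting the fused assimilatory nitrite reductase NirBD — the N-metabolism
marker shared by some bacteria and fungi/heterokonts — in the packaged
census table:

```sh
$ protomito census --feature NirBD --taxon alpha-proteobacteria
feature	taxon_filter	count
NirBD	alpha-proteobacteria	10
  Beijerinckia indica
  Gluconobacter oxydans H24
  ...
```

Ten α-proteobacteria carry NirBD (acetic-acid bacteria plus *Beijerinckia*),
against 140 eukaryotes — the rarity that makes the marker phylogenetically
informative. Enumerating single-loss pathways from the six-system ancestral
subset into the fungal/protist mitochondrial subset:

```sh
$ protomito pathways --source "Rhodopseudomonas palustris" --target "fungal mitochondria"
2 pathway(s)
{AA3,BC1,BD,BO,CBB3,NMET} -> {AA3,BC1,BD,CBB3,NMET} -> {AA3,BC1,BD,NMET} -> {AA3,BC1,NMET}
{AA3,BC1,BD,BO,CBB3,NMET} -> {AA3,BC1,BD,CBB3,NMET} -> {AA3,BC1,CBB3,NMET} -> {AA3,BC1,NMET}
```

Exactly two attested subsets feed the mitochondrial endowment by one last
single-system loss: the *bd*-retaining subset of *Micavibrio*/*Beijerinckia*
and the *cbb₃*-retaining subset of *Magnetospirillum*/*Roseobacter*/
*Maricaulis*. Edit scoring of the candidate progenitors (`protomito`
library, see `pathway_graph.rank_candidate_ancestors`) then shows the
*Beijerinckia* route costs one loss (*bd* oxidase) plus one acquisition
(COX operon type a-II), while the second route costs two losses and two
acquisitions — the asymmetry that favours the methylotroph-proximal
pathway.

Other subcommands: `classify-operons`, `cox4-score`, `pl-strength`,
`cimit`, `phenetics`, `nj`, `simulate`, and `run-all` (all stages on the
packaged fixtures, with a reproducibility manifest).

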