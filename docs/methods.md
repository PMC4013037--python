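# Methods

## The model

`protomito` treats an organism's bioenergetics as a discrete *endowment*:
the subset of six quinol-to-oxygen systems it encodes (bc₁ complex,
aa₃-type cytochrome c oxidase, cbb₃ oxidase, bo and bd ubiquinol oxidases,
bioenergy-linked N-metabolism), plus its COX operon types, Rieske ISP
forms and photosynthetic capacity. Two complementary comparisons are
implemented.

**Single-loss parsimony.** Attested endowment subsets form a directed
acyclic graph whose edges remove exactly one system. Only subsets observed
in sequenced organisms (or organelles) are nodes — unattested intermediates
are never synthesized, so the graph encodes what extant genomes attest
rather than a combinatorial lattice. Pathways of mitochondrial evolution
are simple directed paths in this graph; operon-type and ISP changes do not
create edges because the subset diagram is drawn purely on the six systems.

**Edit scoring.** Candidate progenitors are compared with the
proto-mitochondrial target endowment (systems {bc₁, aa₃, N-metabolism},
COX operons of type a — modelled as a-II — and type b, ISP1) by
feature-class-wise set difference: losses are features the candidate has
and the target lacks, acquisitions the reverse. Ranking sorts by (total
acquisitions, total losses): an acquisition requires lateral gene
transfer, a rarer event than gene loss, so it weighs first. The weight
order is a configurable policy argument.

Interpretive choices in the packaged endowment fixtures, made where the
source diagrams are not itemised in prose:

- The pathway-B sources (*Magnetospirillum*, *Roseobacter*, *Maricaulis*)
  are encoded with the isolated-cluster ISP form (ISP2-like): their ISP
  carries a lineage-specific insert and groups away from the mitochondrial
  homologues, so reaching the target requires both losing that form and
  acquiring a mitochondria-compatible in-operon ISP1. Their two losses are
  then {cbb₃ oxidase, ISP2} and their two acquisitions {COX operon a-II,
  ISP1}.
- Photosynthesis loss is excluded from the candidate-progenitor fixture
  (it is not drawn in the source diagram), though the edit-scoring engine
  supports it as a fourth feature class for user data.
- The *Rickettsia* subset carries a `discounted` flag: the route from it
  to mitochondria is representable but marked implausible, because the
  symbiotic event happened once.

## Operon classification

The classifier is a rule cascade over a parsed gene cluster
(tab-separated: organism, cluster id, gene index, strand, product label
from a closed vocabulary, protein length, domain labels):

1. completeness — a cluster missing any core subunit (COX2, COX1, COX3;
   fusions count as carriers) is *incomplete*;
2. a-I — attached Nrf-like cluster (NrfD2 / NrfD-like present);
3. a-III — doublet of COX3 genes;
4. a-II — PQQ-dependent dehydrogenase / MxaF in the cluster, or a
   COX1–COX4 fusion;
5. a-IV — COX1-3 chimaera;
6. b — COX11–COX3 syntenic diad with a separate 7-helix COX3;
7. a–b transition — complete core with none of the above markers.

Conflicting evidence resolves by the fixed priority
a-I > a-III > a-II > a-IV > b > ab_transition (rarer, more specific
evidence first); all fired rules are retained on the call. Classification
reads set-level cluster content only, so it is deterministic and
order-independent for equal-content clusters. Gene adjacency means
consecutive gene indices in the provided cluster record; no
intergenic-distance inference is attempted.

**Fusion rules.** COX1–COX4: COX1 length in [630, 670] aa *and* the
C-terminal 120 residues contain a window whose identity count against the
reference subunit-IV blocks reaches the COX4-likeness call (below).
COX1-3: COX1 longer than 700 aa *and* the embedded-COX3 search succeeds;
when no sequence is supplied, length alone stands in and the evidence
string says so. COX2–cytochrome c and cytochrome b–c₁ are called from
domain labels plus minimum lengths (350 and 600 aa). The 630–670 window is
a stated constant of the reproduced analysis; the 700 aa long-COX1
threshold is a package choice (the fused COX1–COX4 proteins top out at
670 aa and the chimaeras are much longer) and a config key.

**Hydropathy.** Transmembrane segments are maximal runs of sliding-window
mean Kyte–Doolittle hydropathy ≥ 1.6 with a fixed 19-residue window,
discarding runs shorter than 10 window centres. Only the window width is
fixed by the method being reproduced; the threshold and minimum span
follow common practice and are config keys.

**Embedded / split COX3.** A long COX1 is scanned at fixed frame against
the packaged COX3 reference: a contiguous match at ≥ 0.8 identity with at
least 5 transmembrane segments in the matched span is *embedded*; failing
that, the 2-helix N-terminal block (reference positions 1–72) and the
5-helix C-terminal block are sought separately at ≥ 0.6 identity, and a
hit with ≥ 100 residues between the blocks is *split*. The two identity
cuts are deliberately different: a split architecture partially matches
the full-length probe (the C-terminal 5-helix block alone is 72% of the
reference), so the embedded call must demand more than any split
arrangement can reach. From chimaeric evidence the "minimal" protist
operon is emitted as the type-a core in the reverse order of transcription
with COX1 and COX3 merged (COX1-3, COX2).

## COX4-likeness score

A query segment pre-aligned to a fixed-coordinate reference block is
classed per column: identical to reference A, identical to reference B,
positive (BLOSUM62 score ≥ 0 — zero counts as positive here, a deliberate
reading of the source convention kept behind `positive_includes_zero`), or
other. The call depends only on the total identity count (columns
identical to at least one reference): COX4-like iff total ≥ 10. Positives
are reported but never enter the call. Gap columns contribute nothing.
The C-terminal scan slides the reference frame over the last 120 residues
and keeps the maximal-total window, ties breaking toward the most
C-terminal position. The packaged reference blocks are synthetic stand-ins
for the two solved subunit-IV structures (filenames and headers say so);
the scoring is purely coordinate-frame based, so users can substitute the
real blocks without code changes.

## COX3 phospholipid-binding strength

Binding-site positions (phosphatidyl-ethanolamine and
phosphatidyl-glycerol sites, plus the residue corresponding to E90 of beef
COX3) are 1-based on the mature beef reference and mapped into alignment
columns by walking the ungapped reference row. Each record is classed per
site as identical / positive / other / gap; *conserved* = identical or a
strictly positive BLOSUM62 score (a stricter convention than the ≥ 0 rule
of the COX4 score — the two modules carry separate flags because their
sources phrase the criterion differently). Categories: *weak* when every
PL class has < 3 conserved sites (the stated rule); *strong* when every
class has ≥ 5 (package heuristic); *intermediate* otherwise. E90-like
sites are reported separately and never enter the PL counts. The packaged
site map is an interpretive transcription — the source text never
enumerates the positions — and is editable data paired with the synthetic
reference sequence.

## CIMit detection

For each alignment column, each taxon group gets a consensus gap state
when at least `min_support` (default 0.8) of its members agree; a column
differs when the mitochondrial consensus and a bacterial group's consensus
are both determined and opposite. Maximal runs of consistently-directed
difference columns with a common carrier group form features, numbered
left to right; IN means mitochondria gapped / carriers residues, DEL the
reverse. Adjacent spans separated by one concordant column stay separate.
The mitochondrial *consensus* (not a single reference sequence) is the
default comparator; this is a flagged choice. Presence in the per-sequence
matrix requires the feature state over at least half the span. ISP forms:
ISP1 iff the gene sits in a petABC-like operon; an isolated sequence is
ISP2 when longer than the organism's in-operon form, otherwise flagged
ambiguous.

## Phenetics and trees

Shared-character scores count equal states over the 11-character operon
matrix; the packaged matrix is interpretive (the source states the
character count but not the characters) and documents its reconstruction
in the header. Distance trees use p-distances (mismatches over
pairwise-comparable columns, gap columns excluded per pair; an
incomparable pair gets the maximal distance 1.0 with a warning) and a
canonical neighbour-joining implementation: Q-matrix criterion,
deterministic tie-breaking by the lexicographically lowest label pair,
negative branch lengths clamped to zero with a flag. The original trees
came from profile-based web tools; this package reproduces their
*topological claims* only as properties on synthetic data, never as
replicas.

## Synthetic data and what passing tests show

Generators plant known structure: operon layouts per type, hydrophobic
stretches (I/L/V/F in spans, hydrophilic elsewhere, 10% per-residue
substitution noise), group-conditional gap blocks, site-conservation
classes against a reference row, and a shared-branch "mitochondrial" group
(ancestor mutated at rate 0.25, leaves at 0.03, other taxa radiating at
0.08 from the root). Problem sizes used by the test-suite and the
acceptance script: 200 generated clusters for classifier recovery, 200
alignments (12 sequences × 130 columns) for indel recovery, 40 random
additive matrices of up to 10 taxa for neighbour joining, and 100
replicates (12 × 300) for monophyly recovery — sizes chosen so the whole
pipeline exercises every rule while remaining a desk-scale computation.
Passing these tests shows the detectors recover what was planted under the
stated noise model; it does not show performance on real proteins, whose
conservation is position-heterogeneous and whose indels co-vary with
structure. Fixture-derived results (census counts, pathway counts, edit
totals, exemplar typing) are exact properties of the transcribed tables.

## Known limitations

- The classifier trusts the provided cluster boundaries; it performs no
  operon detection from genomes and no promoter/terminator modelling.
- COX4-likeness uses fixed-frame scanning, not gapped alignment; queries
  with internal indels relative to the reference block will under-count.
- The site map, character matrix and COX4 reference blocks are
  interpretive or synthetic stand-ins (each labelled as such); analyses of
  real data should replace them with transcriptions from the primary
  structural sources.
- p-distance + neighbour joining is a transparent baseline, not a
  substitute for model-based phylogenetics.
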