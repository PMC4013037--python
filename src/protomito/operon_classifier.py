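"""COX operon typing, subunit-fusion detection and COX3 architecture analysis.

Proteobacterial gene clusters coding the aa3-type cytochrome c oxidase fall
into three operon types — a (four subtypes a-I..a-IV), b and an a-b
transition form — distinguished by COX1 sequence variation (fusions with
COX3 or the small subunit IV) and the flanking gene content:

* a-I carries an attached Nrf-like cluster (NrfD2 + NrfD-like membrane
  subunits of an alternative complex III);
* a-II co-occurs with PQQ-dependent dehydrogenases (MxaF-related methanol
  dehydrogenase) and carries the COX1-COX4 fusion (COX1 of 630-670 aa with
  a COX4-like C-terminal extension);
* a-III carries a doublet of COX3 genes;
* a-IV keeps the ancestral COX1-3 chimaera (very long COX1 with an
  embedded COX3);
* b carries a separate 7-helix COX3 with the COX11-COX3 syntenic diad,
  the arrangement retained by mitochondrial genomes;
* the a-b transition form has the bare core with beta/gamma-style flanks.

A cluster lacking any core subunit (COX2/ctaC, COX1/ctaD, COX3/ctaE,
fusions counted as carriers) is *incomplete* ("dead"). Rule priority on
conflicting evidence is a-I > a-III > a-II > a-IV > b > ab_transition
(rarer, more specific evidence first); conflicts are retained on the call.

Transmembrane segments are detected from Kyte-Doolittle hydropathy with a
fixed 19-residue scanning window; the threshold (window mean >= 1.6) and
the minimum segment span (10 positions) follow common practice and are
config keys, only the window width is fixed by the method reproduced here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .core_io import GeneCluster, SequenceRecord, parse_fasta
from .similarity_scoring import load_reference_blocks, scan_cterm_for_cox4

logger = logging.getLogger(__name__)

OPERON_TYPES = ("a-I", "a-II", "a-III", "a-IV", "b", "ab_transition", "incomplete")
FUSION_KINDS = ("COX1_3", "COX1_COX4", "COX2_cytc", "cytb_cytc1")
CORE_SUBUNITS = ("COX2", "COX1", "COX3")


@dataclass
class ClassifierConfig:
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_span: int = 10
    cox1_cox4_length_window: tuple[int, int] = (630, 670)
    long_cox1_threshold: int = 700
    cox2_fusion_min_length: int = 350
    cytb_cytc1_min_length: int = 600
    cox4_cterm_window: int = 120
    seven_tm_min_length: int = 240   # length proxy when no sequence is given
    embedded_min_identity: float = 0.8
    split_min_identity: float = 0.6
    split_min_separation: int = 100
    split_boundary: int = 72         # end of the 2-TM block on the reference


DEFAULT_CONFIG = ClassifierConfig()


# ---------------------------------------------------------------------------
# Hydropathy / transmembrane segments


@dataclass(frozen=True)
class TMSegment:
    start: int   # 1-based window-centre positions, inclusive
    end: int
    peak: float  # maximal window-mean hydropathy within the segment

    def __post_init__(self) -> None:
        assert self.end >= self.start


def window_means(sequence: str, window: int = 19) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy; entry i is the mean of
    the window centred on 1-based position i + window//2 + 1."""
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence.upper()])
    return np.convolve(values, np.ones(window) / window, mode="valid")


def find_tm_segments(
    sequence: str | SequenceRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_span: int = 10,
) -> list[TMSegment]:
    """Maximal runs of window centres with mean hydropathy >= threshold,
    dropping runs shorter than ``min_span``. Sequences shorter than the
    window yield an empty list with a warning."""
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else sequence
    if len(seq) < window:
        warnings.warn(
            f"sequence of length {len(seq)} shorter than window {window}; "
            "no transmembrane segments reported"
        )
        return []
    means = window_means(seq, window)
    half = window // 2
    segments: list[TMSegment] = []
    i = 0
    n = len(means)
    while i < n:
        if means[i] >= threshold:
            j = i
            while j < n and means[j] >= threshold:
                j += 1
            if j - i >= min_span:
                segments.append(
                    TMSegment(i + half + 1, j - 1 + half + 1, float(means[i:j].max()))
                )
            i = j
        else:
            i += 1
    return segments


# ---------------------------------------------------------------------------
# Embedded / split COX3 detection


def load_cox3_reference() -> SequenceRecord:
    """The packaged synthetic stand-in for the mature beef COX3 reference."""
    path = Path(str(resources.files("protomito").joinpath(
        "data", "cox3_reference.synthetic.fasta")))
    return parse_fasta(path)[0]


def _identity_scan(query: str, probe: str) -> tuple[int, float]:
    """Best (0-based offset, identity fraction) of ``probe`` slid along
    ``query`` at fixed frame; ties break toward the most C-terminal offset."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    if len(q) < len(p):
        return 0, 0.0
    windows = np.lib.stride_tricks.sliding_window_view(q, len(p))
    frac = (windows == p).mean(axis=1)
    best = int(len(frac) - 1 - np.argmax(frac[::-1]))
    return best, float(frac[best])


@dataclass
class ArchitectureReport:
    """Outcome of searching a long COX1 for an embedded or split COX3."""

    query_id: str
    status: str  # embedded / split / absent
    span: tuple[int, int] | None = None          # 1-based, embedded block
    split_spans: tuple[tuple[int, int], tuple[int, int]] | None = None
    identity: float = 0.0
    tm_count: int = 0
    observed_gene_order: tuple[str, ...] | None = None


def detect_embedded_cox3(
    cox1: SequenceRecord,
    cox3_reference: SequenceRecord | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ArchitectureReport:
    """Search a long COX1 for COX3 sequence signatures.

    Reports *embedded* when a contiguous COX3-like block (7-helix
    architecture) is found, *split* when the initial 2-helix block and the
    5-helix block are separated by the body of COX1, *absent* otherwise.
    COX1 proteins of canonical length are absent by definition.
    """
    if cox3_reference is None:
        cox3_reference = load_cox3_reference()
    ref = cox3_reference.residues
    query = cox1.residues
    if len(query) <= config.long_cox1_threshold:
        return ArchitectureReport(cox1.id, "absent")
    off, frac = _identity_scan(query, ref)
    if frac >= config.embedded_min_identity:
        span = (off + 1, off + len(ref))
        tms = find_tm_segments(
            query[off:off + len(ref)], config.tm_window,
            config.tm_threshold, config.tm_min_span)
        if len(tms) >= 5:
            return ArchitectureReport(cox1.id, "embedded", span=span,
                                      identity=frac, tm_count=len(tms))
    n_probe = ref[: config.split_boundary]
    c_probe = ref[config.split_boundary:]
    n_off, n_frac = _identity_scan(query, n_probe)
    c_off, c_frac = _identity_scan(query, c_probe)
    if (
        n_frac >= config.split_min_identity
        and c_frac >= config.split_min_identity
        and c_off - (n_off + len(n_probe)) >= config.split_min_separation
    ):
        n_span = (n_off + 1, n_off + len(n_probe))
        c_span = (c_off + 1, c_off + len(c_probe))
        n_tms = find_tm_segments(query[n_off:n_off + len(n_probe)],
                                 config.tm_window, config.tm_threshold,
                                 config.tm_min_span)
        c_tms = find_tm_segments(query[c_off:c_off + len(c_probe)],
                                 config.tm_window, config.tm_threshold,
                                 config.tm_min_span)
        if len(n_tms) >= 1 and len(c_tms) >= 3:
            return ArchitectureReport(
                cox1.id, "split", split_spans=(n_span, c_span),
                identity=min(n_frac, c_frac), tm_count=len(n_tms) + len(c_tms))
    return ArchitectureReport(cox1.id, "absent", identity=frac)


# ---------------------------------------------------------------------------
# Fusion detection


@dataclass
class FusionCall:
    kind: str           # COX1_3 / COX1_COX4 / COX2_cytc / cytb_cytc1
    carrier: str        # product label of the carrier gene
    length: int
    evidence: str
    tm_count: int | None = None
    similarity_total: int | None = None

    def __post_init__(self) -> None:
        assert self.kind in FUSION_KINDS


def detect_subunit_fusions(
    cluster: GeneCluster,
    sequences: dict[str, SequenceRecord] | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
    cox3_reference: SequenceRecord | None = None,
) -> list[FusionCall]:
    """Detect fused oxidase subunits in one cluster.

    Sequence-requiring rules (the COX4-likeness scan behind COX1_COX4, the
    embedded-COX3 search behind COX1_3) are skipped with a log message when
    the relevant sequence is unavailable; domain-label rules (COX2_cytc,
    cytb_cytc1) always run.
    """
    calls: list[FusionCall] = []
    seqs = sequences or {}

    def seq_for(gene) -> SequenceRecord | None:
        key = f"{cluster.cluster_id}:{gene.gene_index}"
        return seqs.get(key) or seqs.get(gene.product_label)

    lo, hi = config.cox1_cox4_length_window
    for gene in cluster.genes_with("COX1"):
        if lo <= gene.protein_length <= hi:
            seq = seq_for(gene)
            if seq is None:
                logger.info(
                    "cluster %s: COX1 in the fusion length window but no "
                    "sequence; COX1_COX4 rule skipped", cluster.cluster_id)
            else:
                refs = load_reference_blocks()
                tm1 = {k: v.residues for k, v in refs.items() if "TM1" in k}
                report = scan_cterm_for_cox4(seq, tm1, config.cox4_cterm_window)
                if report.is_cox4_like:
                    calls.append(FusionCall(
                        "COX1_COX4", "COX1", gene.protein_length,
                        f"length {gene.protein_length} in [{lo},{hi}]; "
                        f"C-terminal COX4-likeness total {report.total} >= 10",
                        similarity_total=report.total))
        if gene.protein_length > config.long_cox1_threshold:
            seq = seq_for(gene)
            if seq is None:
                logger.info(
                    "cluster %s: long COX1 but no sequence; embedded-COX3 "
                    "confirmation skipped", cluster.cluster_id)
            else:
                report = detect_embedded_cox3(seq, cox3_reference, config)
                if report.status in {"embedded", "split"}:
                    calls.append(FusionCall(
                        "COX1_3", "COX1", gene.protein_length,
                        f"long COX1 ({gene.protein_length} aa) with "
                        f"{report.status} COX3 block, identity "
                        f"{report.identity:.2f}",
                        tm_count=report.tm_count))
    for gene in cluster.genes_with("COX2"):
        if ("cytochrome_c" in gene.domain_labels
                and gene.protein_length >= config.cox2_fusion_min_length):
            calls.append(FusionCall(
                "COX2_cytc", "COX2", gene.protein_length,
                f"COX2 of {gene.protein_length} aa with a c-type cytochrome domain"))
    for gene in cluster.genes:
        if ({"cytochrome_b", "cytochrome_c1"} <= set(gene.domain_labels)
                and gene.protein_length >= config.cytb_cytc1_min_length):
            calls.append(FusionCall(
                "cytb_cytc1", gene.product_label, gene.protein_length,
                "cytochrome b and cytochrome c1 domains on one gene"))
    return calls


# ---------------------------------------------------------------------------
# Operon classification


@dataclass
class OperonCall:
    organism: str
    cluster_id: str
    operon_type: str
    evidence: list[str]
    fusions: list[FusionCall] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.operon_type in OPERON_TYPES
        if self.operon_type != "incomplete":
            assert self.evidence, "non-incomplete call without evidence"


def _core_missing(cluster: GeneCluster, fusions: list[FusionCall],
                  long_cox1_fallback: bool) -> list[str]:
    kinds = {f.kind for f in fusions}
    missing = []
    if not cluster.genes_with("COX2"):
        missing.append("COX2")
    if not cluster.genes_with("COX1"):
        missing.append("COX1")
    cox3_covered = (
        bool(cluster.genes_with("COX3"))
        or "COX1_3" in kinds
        or long_cox1_fallback
    )
    if not cox3_covered:
        missing.append("COX3")
    return missing


def _has_cox11_cox3_diad(cluster: GeneCluster) -> bool:
    genes = cluster.genes
    for a, b in zip(genes, genes[1:]):
        if b.gene_index != a.gene_index + 1:
            continue
        if {a.product_label, b.product_label} == {"ctaG/COX11", "COX3"}:
            return True
    return False


def classify_cox_operon(
    cluster: GeneCluster,
    sequences: dict[str, SequenceRecord] | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
    cox3_reference: SequenceRecord | None = None,
) -> OperonCall:
    """Rule cascade assigning one of the seven operon-type labels.

    Deterministic and order-independent for equal-content clusters: every
    rule reads set-level cluster content, and conflicting evidence resolves
    by the fixed priority a-I > a-III > a-II > a-IV > b > ab_transition
    (conflicts are recorded on the call).
    """
    fusions = detect_subunit_fusions(cluster, sequences, config, cox3_reference)
    kinds = {f.kind for f in fusions}
    long_cox1 = [g for g in cluster.genes_with("COX1")
                 if g.protein_length > config.long_cox1_threshold]
    # without sequences a very long COX1 stands in for the chimaera call
    long_fallback = bool(long_cox1) and sequences is None

    missing = _core_missing(cluster, fusions, long_fallback)
    if missing:
        return OperonCall(cluster.organism, cluster.cluster_id, "incomplete",
                          [f"core subunit(s) missing: {','.join(missing)}"],
                          fusions)

    fired: list[tuple[str, str]] = []  # (type, evidence), in priority order
    products = set(cluster.products)
    if {"NrfD2", "NrfD_like"} & products:
        fired.append(("a-I", "attached Nrf-like cluster (NrfD2/NrfD-like present)"))
    if len(cluster.genes_with("COX3")) >= 2:
        fired.append(("a-III", "doublet of COX3 genes"))
    if {"PQQ_dehydrogenase", "MxaF"} & products:
        fired.append(("a-II", "PQQ-dependent dehydrogenase / MxaF in the cluster"))
    if "COX1_COX4" in kinds:
        if not any(t == "a-II" for t, _ in fired):
            fired.append(("a-II", "COX1-COX4 fusion"))
    if "COX1_3" in kinds:
        fired.append(("a-IV", "COX1-3 chimaera"))
    elif long_fallback:
        fired.append(("a-IV",
                      f"very long COX1 ({long_cox1[0].protein_length} aa; "
                      "length-only, no sequence provided)"))
    if _has_cox11_cox3_diad(cluster):
        seven_tm = False
        for gene in cluster.genes_with("COX3"):
            key = f"{cluster.cluster_id}:{gene.gene_index}"
            seq = (sequences or {}).get(key)
            if seq is not None:
                seven_tm = len(find_tm_segments(
                    seq, config.tm_window, config.tm_threshold,
                    config.tm_min_span)) >= 6
            else:
                seven_tm = gene.protein_length >= config.seven_tm_min_length
            if seven_tm:
                break
        if seven_tm:
            fired.append(("b", "COX11-COX3 diad with separate 7-helix COX3"))
    if not fired:
        fired.append(("ab_transition",
                      "complete core without a-type or type-b markers "
                      "(beta/gamma-style flanking content)"))

    priority = {"a-I": 0, "a-III": 1, "a-II": 2, "a-IV": 3, "b": 4,
                "ab_transition": 5}
    fired.sort(key=lambda t: priority[t[0]])
    chosen = fired[0][0]
    evidence = [ev for t, ev in fired if t == chosen]
    conflicts = [f"{t}: {ev}" for t, ev in fired if t != chosen]
    if conflicts:
        logger.info("cluster %s: conflicting evidence resolved to %s (%s)",
                    cluster.cluster_id, chosen, "; ".join(conflicts))
    return OperonCall(cluster.organism, cluster.cluster_id, chosen,
                      evidence, fusions, conflicts)


# ---------------------------------------------------------------------------
# The deduced "minimal" operon of protists

TYPE_A_CORE = ("COX2", "COX1", "COX3")


@dataclass
class MinimalOperon:
    genes: tuple[str, ...]            # chimaeric gene order as deduced
    expanded: tuple[str, ...]         # core equivalent with COX1-3 expanded
    reverse_transcription: bool


def deduce_minimal_operon(
    reports: list[ArchitectureReport],
) -> MinimalOperon | None:
    """From COX3-in-COX1 architecture reports of a taxon set, deduce the
    ancestral minimal operon: the type-a core, read in the reverse order of
    transcription, with COX1 and COX3 merged into the chimaera.

    Returns None when no report carries embedded or split evidence.
    """
    chimaeric = [r for r in reports if r.status in {"embedded", "split"}]
    if not chimaeric:
        return None
    orders = [r.observed_gene_order for r in chimaeric if r.observed_gene_order]
    if orders:
        # majority vote over observed mtDNA gene orders
        from collections import Counter
        genes = Counter(orders).most_common(1)[0][0]
    else:
        genes = ("COX1_3", "COX2")
    expanded = tuple(
        g2 for g in genes for g2 in (("COX3", "COX1") if g == "COX1_3" else (g,))
    )
    return MinimalOperon(genes, expanded,
                         reverse_transcription=expanded == TYPE_A_CORE[::-1])
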