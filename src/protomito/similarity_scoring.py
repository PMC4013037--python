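"""COX4-likeness scoring of query segments against reference subunit-IV blocks.

A query segment, pre-aligned to a fixed-coordinate reference block (the TM1
blocks of the two solved subunit-IV structures, or the TM2 block of the one
solved 2-TM structure), is scored column by column: identical to reference
A, identical to reference B, a positive substitution (BLOSUM62 score >= 0 —
the source counts zero as positive, kept behind ``positive_includes_zero``),
or other. The call is driven solely by the total identity count ("tot" =
columns identical to at least one reference): a segment is COX4-like when
tot >= 10. Positives are reported but never enter the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio.Align import substitution_matrices

from .core_io import GAP, SequenceRecord, parse_fasta

COX4_CALL_THRESHOLD = 10
DEFAULT_CTERM_WINDOW = 120

_BLOSUM62 = None


def blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def load_reference_blocks() -> dict[str, SequenceRecord]:
    """The packaged reference blocks (synthetic stand-ins for the two solved
    subunit-IV structures), keyed by record id."""
    path = Path(str(resources.files("protomito").joinpath(
        "data", "cox4_reference_blocks.synthetic.fasta")))
    return {r.id: r for r in parse_fasta(path)}


@dataclass
class SimilarityReport:
    query_id: str
    identities: dict[str, int]      # per-reference identity count
    positives: int
    total: int                      # columns identical to >= 1 reference
    is_cox4_like: bool
    span: tuple[int, int] | None = None  # 1-based aligned span on the query

    def __post_init__(self) -> None:
        assert self.is_cox4_like == (self.total >= COX4_CALL_THRESHOLD)


def _score(a: str, b: str) -> float:
    m = blosum62()
    try:
        return m[a, b]
    except KeyError:
        return -4.0  # X or other non-matrix letters


def cox4_similarity(
    query: str,
    references: dict[str, str],
    query_id: str = "query",
    positive_includes_zero: bool = True,
    span: tuple[int, int] | None = None,
) -> SimilarityReport:
    """Fixed-coordinate column-wise comparison of a query segment against
    one or more equal-length reference blocks.

    Gap columns in the query contribute nothing and are never identities.
    A query/reference length mismatch is a hard error.
    """
    if not references:
        raise ValueError("at least one reference block is required")
    for rid, ref in references.items():
        if len(ref) != len(query):
            raise ValueError(
                f"query length {len(query)} != reference {rid!r} length {len(ref)}"
            )
    identities = {rid: 0 for rid in references}
    positives = 0
    total = 0
    cut = 0.0 if positive_includes_zero else 1.0
    for i, q in enumerate(query.upper()):
        if q == GAP:
            continue
        col = {rid: ref[i].upper() for rid, ref in references.items()}
        hit = False
        for rid, r in col.items():
            if r != GAP and q == r:
                identities[rid] += 1
                hit = True
        if hit:
            total += 1
        elif any(r != GAP and _score(q, r) >= cut for r in col.values()):
            positives += 1
    return SimilarityReport(
        query_id, identities, positives, total,
        total >= COX4_CALL_THRESHOLD, span,
    )


def scan_cterm_for_cox4(
    protein: SequenceRecord,
    references: dict[str, str],
    cterm_window: int = DEFAULT_CTERM_WINDOW,
    positive_includes_zero: bool = True,
) -> SimilarityReport:
    """Slide the reference frame over the C-terminal region and return the
    maximal-total report; ties break toward the most C-terminal position."""
    block_len = len(next(iter(references.values())))
    seq = protein.residues
    if len(seq) <= block_len:
        raise ValueError(
            f"protein {protein.id} ({len(seq)} aa) not longer than the "
            f"reference block ({block_len} aa)"
        )
    start_min = max(0, len(seq) - cterm_window)
    best: SimilarityReport | None = None
    for start in range(start_min, len(seq) - block_len + 1):
        window = seq[start:start + block_len]
        rep = cox4_similarity(
            window, references, protein.id, positive_includes_zero,
            span=(start + 1, start + block_len),
        )
        if best is None or rep.total >= best.total:  # >= keeps the C-terminal tie
            best = rep
    assert best is not None
    return best
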