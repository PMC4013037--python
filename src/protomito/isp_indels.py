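"""Conserved-indel (CIMit) mining in Rieske ISP alignments.

A CIMit — Conserved Indel vs. Mitochondria — is a contiguous alignment span
where the gap state of one or more bacterial taxon groups differs from the
consensus gap state of the mitochondrial reference group: an *IN* feature
is an insert the carriers have and mitochondria lack (mitochondria gapped),
a *DEL* feature the reverse. "Conserved" is operationalised as >= a support
fraction (default 0.8) of group members agreeing on the gap state within
both the mitochondrial group and the carrier group; the published notion is
qualitative. Features are numbered left to right (CIMit1, CIMit2, ...).
Adjacent differing spans separated by a concordant column are kept separate.

The module also assigns ISP forms: ISP1 is the form coded inside the
petABC operon of the bc1 complex, ISP2 the longer paralogue found in
isolated gene clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GAP, AlignmentBlock


@dataclass(frozen=True)
class IndelFeature:
    label: str                      # CIMit1, CIMit2, ...
    kind: str                       # IN / DEL (relative to mitochondria)
    start: int                      # 1-based alignment columns, inclusive
    end: int
    carrier_groups: frozenset[str]
    support: float                  # min within-group agreement over the span

    def __post_init__(self) -> None:
        assert self.kind in {"IN", "DEL"}
        assert self.end >= self.start
        assert 0 < self.support <= 1

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def _gap_matrix(alignment: AlignmentBlock) -> np.ndarray:
    return np.array([[c == GAP for c in row] for row in alignment.rows])


def detect_indels(
    alignment: AlignmentBlock,
    mitochondrial_group: str = "mitochondria",
    min_support: float = 0.8,
    min_span: int = 1,
) -> list[IndelFeature]:
    """Detect group-conserved indels relative to the mitochondrial consensus.

    A column differs for bacterial group g when both the mitochondrial
    group and g have a consensus gap state (agreement >= min_support) and
    the states are opposite. Maximal runs of columns with a consistent
    direction form features; the carrier set of a feature is the set of
    groups differing in *every* column of its span.
    """
    groups = alignment.groups()
    if mitochondrial_group not in groups:
        raise KeyError(
            f"alignment has no {mitochondrial_group!r} group; "
            f"groups present: {sorted(groups)}"
        )
    bact_groups = [g for g in groups if g != mitochondrial_group]
    if not bact_groups:
        raise KeyError("alignment needs at least one non-mitochondrial group")

    gaps = _gap_matrix(alignment)
    idx = {rid: i for i, rid in enumerate(alignment.ids)}

    def consensus(group: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rows = gaps[[idx[r] for r in groups[group]]]
        gap_frac = rows.mean(axis=0)
        state = gap_frac >= 0.5
        support = np.where(state, gap_frac, 1 - gap_frac)
        determined = support >= min_support
        return state, support, determined

    mito_state, mito_support, mito_det = consensus(mitochondrial_group)
    per_group = {g: consensus(g) for g in bact_groups}

    ncol = alignment.length
    # per column: direction (+1 IN, -1 DEL, 0 none) and differing groups
    direction = np.zeros(ncol, dtype=int)
    differing: list[set[str]] = [set() for _ in range(ncol)]
    for g, (state, support, det) in per_group.items():
        diff = mito_det & det & (state != mito_state)
        for c in np.nonzero(diff)[0]:
            differing[c].add(g)
            direction[c] = 1 if mito_state[c] else -1  # mito gapped -> IN

    features: list[IndelFeature] = []
    c = 0
    while c < ncol:
        if direction[c] == 0:
            c += 1
            continue
        d = direction[c]
        j = c
        carriers = set(differing[c])
        while (j + 1 < ncol and direction[j + 1] == d
               and differing[j + 1] & carriers):
            carriers &= differing[j + 1]
            j += 1
        if j - c + 1 >= min_span and carriers:
            cols = slice(c, j + 1)
            support = min(
                float(min(per_group[g][1][cols].min() for g in carriers)),
                float(mito_support[cols].min()),
            )
            features.append(IndelFeature(
                label=f"CIMit{len(features) + 1}",
                kind="IN" if d > 0 else "DEL",
                start=c + 1, end=j + 1,
                carrier_groups=frozenset(carriers),
                support=support,
            ))
        c = j + 1
    return features


@dataclass
class IndelMatrix:
    sequence_ids: list[str]
    features: list[IndelFeature]
    presence: np.ndarray  # sequences x features, bool

    def as_dict(self) -> dict[str, dict[str, bool]]:
        return {
            sid: {f.label: bool(self.presence[i, j])
                  for j, f in enumerate(self.features)}
            for i, sid in enumerate(self.sequence_ids)
        }


def indel_presence_matrix(
    features: list[IndelFeature], alignment: AlignmentBlock
) -> IndelMatrix:
    """Per-sequence presence of every feature.

    A sequence carries an IN feature when it holds residues (non-gap) over
    at least half of the span columns, and a DEL feature when it is gapped
    over at least half of them.
    """
    gaps = _gap_matrix(alignment)
    pres = np.zeros((len(alignment.ids), len(features)), dtype=bool)
    for j, f in enumerate(features):
        span = gaps[:, f.start - 1:f.end]
        gap_frac = span.mean(axis=1)
        pres[:, j] = gap_frac >= 0.5 if f.kind == "DEL" else gap_frac < 0.5
    return IndelMatrix(list(alignment.ids), list(features), pres)


# ---------------------------------------------------------------------------
# ISP form assignment


@dataclass(frozen=True)
class IspRecord:
    seq_id: str
    organism: str
    length: int
    in_operon: bool


@dataclass
class IspAssignment:
    seq_id: str
    form: str         # ISP1 / ISP2 / ambiguous
    note: str = ""


def isp_form_assignment(records: list[IspRecord]) -> list[IspAssignment]:
    """ISP1 for in-operon sequences; ISP2 for isolated sequences longer than
    the organism's in-operon form; ties and shorter isolated forms are
    reported as ambiguous."""
    by_org: dict[str, list[IspRecord]] = {}
    for r in records:
        by_org.setdefault(r.organism, []).append(r)
    out: list[IspAssignment] = []
    for r in records:
        if r.in_operon:
            out.append(IspAssignment(r.seq_id, "ISP1", "within a petABC-like operon"))
            continue
        in_ops = [x for x in by_org[r.organism] if x.in_operon]
        if not in_ops:
            out.append(IspAssignment(
                r.seq_id, "ISP2", "isolated gene cluster; no in-operon "
                "counterpart recorded"))
        elif r.length > max(x.length for x in in_ops):
            out.append(IspAssignment(
                r.seq_id, "ISP2",
                f"isolated and longer ({r.length} aa) than the in-operon "
                f"form ({max(x.length for x in in_ops)} aa)"))
        else:
            out.append(IspAssignment(
                r.seq_id, "ambiguous",
                "isolated but not longer than the in-operon form"))
    return out
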