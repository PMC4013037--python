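"""Bioenergetic endowments and census/frequency reports.

An *endowment* is an organism's recorded portfolio of quinol-to-oxygen
bioenergetic systems, COX operon types and Rieske ISP forms. Six systems
are modelled: the cytochrome bc1 complex (BC1), the aa3-type cytochrome c
oxidase (AA3), the cbb3-type oxidase (CBB3), the bo and bd ubiquinol
oxidases (BO, BD) and bioenergy-linked N-metabolism (NMET).

The packaged fixtures transcribe the published N-metabolism census table,
the attested-subset diagram and the candidate-progenitor endowments; they
are loaded with :func:`load_table1`, :func:`load_fig1b_endowments` and
:func:`load_fig9_endowments`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .core_io import ProfileRow, _data_lines, normalize_organism, parse_profile_table


class BioenergeticSystem(enum.Enum):
    """The six quinol-to-oxygen bioenergetic systems."""

    BC1 = "BC1"
    AA3 = "AA3"
    CBB3 = "CBB3"
    BO = "BO"
    BD = "BD"
    NMET = "NMET"


COX_OPERON_TYPES = {"a-I", "a-II", "a-III", "a-IV", "b", "ab_transition"}
ISP_FORMS = {"ISP1", "ISP2"}
N_MET_MARKERS = {"NirB", "NirBD", "NiaD_related", "MxaF", "precursor"}


@dataclass(frozen=True)
class BioenergeticEndowment:
    """One organism's full bioenergetic endowment."""

    organism: str
    taxon_group: str
    systems: frozenset[BioenergeticSystem]
    cox_operon_types: frozenset[str] = frozenset()
    isp_forms: frozenset[str] = frozenset()
    photosynthesis: bool = False
    n_met_markers: frozenset[str] = frozenset()
    discounted: bool = False
    pathway: str | None = None

    def __post_init__(self) -> None:
        bad = self.cox_operon_types - COX_OPERON_TYPES
        if bad:
            raise ValueError(f"unknown COX operon types {sorted(bad)}")
        bad = self.isp_forms - ISP_FORMS
        if bad:
            raise ValueError(f"unknown ISP forms {sorted(bad)}")
        if self.cox_operon_types and BioenergeticSystem.AA3 not in self.systems:
            raise ValueError(
                f"{self.organism}: COX operon types recorded without the aa3 system"
            )

    @property
    def system_names(self) -> frozenset[str]:
        return frozenset(s.value for s in self.systems)


def _parse_systems(text: str) -> frozenset[BioenergeticSystem]:
    items = [t.strip() for t in text.split(",") if t.strip()]
    return frozenset(BioenergeticSystem(t) for t in items)


def _parse_set(text: str) -> frozenset[str]:
    return frozenset(t.strip() for t in text.split(",") if t.strip())


ENDOWMENT_COLUMNS = [
    "organism", "taxon_group", "systems", "cox_operon_types", "isp_forms",
    "photosynthesis", "n_met_markers",
]


def parse_endowments(path: str | Path) -> list[BioenergeticEndowment]:
    """Read an endowment TSV (optional trailing discounted/pathway column)."""
    lines = _data_lines(path)
    header = lines[0].split("\t")
    if header[: len(ENDOWMENT_COLUMNS)] != ENDOWMENT_COLUMNS:
        raise ValueError(f"bad endowment header: {header}")
    extra = header[len(ENDOWMENT_COLUMNS):]
    out = []
    for line in lines[1:]:
        parts = line.split("\t")
        parts += [""] * (len(header) - len(parts))
        row = dict(zip(header, parts))
        out.append(
            BioenergeticEndowment(
                organism=normalize_organism(row["organism"]),
                taxon_group=row["taxon_group"],
                systems=_parse_systems(row["systems"]),
                cox_operon_types=_parse_set(row["cox_operon_types"]),
                isp_forms=_parse_set(row["isp_forms"]),
                photosynthesis=row["photosynthesis"].strip().lower() == "yes",
                n_met_markers=_parse_set(row["n_met_markers"]),
                discounted=row.get("discounted", "").strip().lower() == "yes",
                pathway=row.get("pathway", "").strip() or None,
            )
        )
    return out


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("protomito").joinpath("data", name)))


def load_table1() -> list[ProfileRow]:
    """The packaged N-metabolism census transcription."""
    return parse_profile_table(_fixture_path("table1_nmet.tsv"))


def load_fig1b_endowments() -> list[BioenergeticEndowment]:
    """The packaged attested-subset fixture (pathway graph input)."""
    return parse_endowments(_fixture_path("fig1b_subsets.tsv"))


def load_fig9_endowments() -> list[BioenergeticEndowment]:
    """Candidate-progenitor endowments, first row is the proto-mitochondrial target."""
    return parse_endowments(_fixture_path("fig9_endowments.tsv"))


def proto_mitochondrion() -> BioenergeticEndowment:
    """The proto-mitochondrial endowment used as the default edit target."""
    for e in load_fig9_endowments():
        if e.pathway == "target":
            return e
    raise RuntimeError("fig9 fixture lacks the proto-mitochondrial target row")


# ---------------------------------------------------------------------------
# Census and frequency reports


@dataclass
class CensusReport:
    feature: str
    taxon_filter: str | None
    count: int
    organisms: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.count == sum(m for _, m in self.organisms)


def _taxon_matches(taxon_group: str, taxon_filter: str | None) -> bool:
    if taxon_filter is None:
        return True
    if taxon_group == taxon_filter:
        return True
    # hierarchical labels like "alpha-proteobacteria/methylotrophs"
    return taxon_group.split("/")[0] == taxon_filter


def count_feature(
    rows: list[ProfileRow],
    feature: str,
    state_filter: str | None = "yes",
    taxon_filter: str | None = None,
) -> CensusReport:
    """Count organisms whose ``feature`` matches ``state_filter``.

    Aggregated rows contribute their stated multiplicity. ``state_filter``
    matches the whole state or any ``&``-separated part of it (so
    "precursor" matches "precursor & 2 domains"); ``None`` counts every
    recorded state. An unknown feature (absent from the table vocabulary,
    on a non-empty table) is a hard error.
    """
    known = {r.feature for r in rows}
    if rows and feature not in known:
        raise KeyError(f"unknown feature {feature!r}; table has {sorted(known)}")
    hits: list[tuple[str, int]] = []
    for r in rows:
        if r.feature != feature:
            continue
        if not _taxon_matches(r.taxon_group, taxon_filter):
            continue
        if state_filter is not None:
            parts = {p.strip() for p in r.state.split("&")}
            if r.state != state_filter and state_filter not in parts:
                continue
        hits.append((r.organism, r.multiplicity))
    return CensusReport(feature, taxon_filter, sum(m for _, m in hits), hits)


def taxon_frequency_report(
    endowments: list[BioenergeticEndowment],
    features: dict[str, "callable"],
) -> dict[str, dict[str, float]]:
    """Per-taxon-group frequency of arbitrary endowment predicates.

    ``features`` maps a feature name to a predicate on an endowment.
    Each frequency is organisms-with-feature / organisms-in-group and lies
    in [0, 1]; empty groups are excluded with a warning.
    """
    groups: dict[str, list[BioenergeticEndowment]] = {}
    for e in endowments:
        groups.setdefault(e.taxon_group, []).append(e)
    out: dict[str, dict[str, float]] = {}
    for group, members in groups.items():
        if not members:  # defensive; grouping cannot create empty lists
            warnings.warn(f"taxon group {group!r} has size 0; excluded")
            continue
        out[group] = {
            name: sum(1 for e in members if pred(e)) / len(members)
            for name, pred in features.items()
        }
    return out


#: Ready-made predicates for the common frequency reports: per COX operon
#: type, fused-protein carriers and N-metabolism elements.
def has_operon_type(t: str):
    return lambda e: t in e.cox_operon_types


def has_system(s: BioenergeticSystem):
    return lambda e: s in e.systems


def has_marker(m: str):
    return lambda e: m in e.n_met_markers
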