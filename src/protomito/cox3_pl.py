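"""Phospholipid-binding-strength scoring of COX3 proteins.

The two N-terminal transmembrane helices of the 7-helix COX3 bind membrane
phospholipids — phosphatidyl-ethanolamine (PE) and phosphatidyl-glycerol
(PG) — that modulate oxygen entry into the catalytic centre of the oxidase.
Binding-site positions are anchored on the mature beef COX3 reference
(1-based); each aligned record is classed per site as identical / positive
substitution / other / gap against the reference residue, and per-PL
conserved counts (conserved = identical or positive, BLOSUM62 score > 0)
yield a strength category: *weak* when every PL class has fewer than 3
conserved sites, *strong* when every class has at least 5, *intermediate*
otherwise. Only the weak rule is from the source; the strong cut-off is a
package heuristic and a config key. Sites corresponding to E90 of beef
COX3 are reported separately and never enter the PL counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .core_io import GAP, AlignmentBlock, _data_lines, write_tsv
from .similarity_scoring import blosum62

WEAK_THRESHOLD = 3   # fewer than this per every PL class -> weak
STRONG_THRESHOLD = 5  # at least this in every PL class -> strong

PL_CLASSES = ("PE", "PG")
SITE_ROLES = {"H_or_pi_bond", "E90_like"}


@dataclass(frozen=True)
class Site:
    site_id: str
    reference_position: int  # 1-based on the mature reference sequence
    pl_class: str            # PE / PG / other
    role: str


def parse_site_map(path: str | Path) -> list[Site]:
    lines = _data_lines(path)
    header = lines[0].split("\t")
    if header != ["site_id", "reference_position", "pl_class", "role"]:
        raise ValueError(f"bad site map header: {header}")
    sites = []
    seen_pos: set[int] = set()
    for line in lines[1:]:
        sid, pos, pl, role = line.split("\t")
        pos = int(pos)
        if pos in seen_pos:
            raise ValueError(f"duplicate reference position {pos}")
        seen_pos.add(pos)
        if pl not in {"PE", "PG", "other"}:
            raise ValueError(f"bad pl_class {pl!r}")
        if role not in SITE_ROLES:
            raise ValueError(f"bad role {role!r}")
        sites.append(Site(sid, pos, pl, role))
    return sites


def load_site_map() -> list[Site]:
    """The packaged beef-anchored phospholipid site map."""
    return parse_site_map(Path(str(
        resources.files("protomito").joinpath("data", "cox3_pl_sites.tsv"))))


def map_reference_sites(
    alignment: AlignmentBlock, reference_id: str, sites: list[Site]
) -> tuple[dict[str, int], list[str]]:
    """Map each site's 1-based mature-reference position to a 1-based
    alignment column by walking the ungapped reference coordinates.

    Returns (site_id -> column, unmappable site ids). The reference being
    absent from the alignment is a hard error.
    """
    if reference_id not in alignment.ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    row = alignment.row(reference_id)
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, aa in enumerate(row, start=1):
        if aa != GAP:
            pos += 1
            pos_to_col[pos] = col
    column_map: dict[str, int] = {}
    unmappable: list[str] = []
    for s in sites:
        if s.reference_position in pos_to_col:
            column_map[s.site_id] = pos_to_col[s.reference_position]
        else:
            unmappable.append(s.site_id)
    return column_map, unmappable


@dataclass
class ConservationProfile:
    record_id: str
    site_classes: dict[str, str]          # site_id -> identical/positive/other/gap
    pl_conserved: dict[str, int]          # PL class -> conserved-site count
    e90_conserved: int
    category: str                         # weak / intermediate / strong
    conserved_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.conserved_total = sum(self.pl_conserved.values())


def categorize(pl_conserved: dict[str, int]) -> str:
    """Pure function of the per-PL conserved counts."""
    if all(pl_conserved.get(pl, 0) < WEAK_THRESHOLD for pl in PL_CLASSES):
        return "weak"
    if all(pl_conserved.get(pl, 0) >= STRONG_THRESHOLD for pl in PL_CLASSES):
        return "strong"
    return "intermediate"


def classify_conservation(
    alignment: AlignmentBlock,
    record_id: str,
    reference_id: str,
    sites: list[Site],
    column_map: dict[str, int] | None = None,
) -> ConservationProfile:
    """Class every mapped site of one record against the reference residue.

    Positive substitution here means a strictly positive matrix score
    (distinct from the >=0 convention of the COX4-likeness score)."""
    if column_map is None:
        column_map, _ = map_reference_sites(alignment, reference_id, sites)
    ref_row = alignment.row(reference_id)
    rec_row = alignment.row(record_id)
    m = blosum62()
    classes: dict[str, str] = {}
    pl_counts = {pl: 0 for pl in PL_CLASSES}
    e90 = 0
    for s in sites:
        if s.site_id not in column_map:
            continue
        col = column_map[s.site_id]
        ref_aa = ref_row[col - 1].upper()
        aa = rec_row[col - 1].upper()
        if aa == GAP:
            cls = "gap"
        elif aa == ref_aa:
            cls = "identical"
        else:
            try:
                score = m[aa, ref_aa]
            except KeyError:
                score = -4.0
            cls = "positive" if score > 0 else "other"
        classes[s.site_id] = cls
        conserved = cls in {"identical", "positive"}
        if s.role == "E90_like":
            e90 += int(conserved)
        elif conserved and s.pl_class in pl_counts:
            pl_counts[s.pl_class] += 1
    return ConservationProfile(
        record_id, classes, pl_counts, e90, categorize(pl_counts))


def strength_heatmap(
    profiles: list[ConservationProfile],
    sites: list[Site],
    out_tsv: str | Path | None = None,
):
    """Taxa x sites matrix of conservation classes with per-PL counts and
    the category column, as a pandas DataFrame (optionally written to TSV)."""
    import pandas as pd

    site_ids = [s.site_id for s in sites]
    rows = []
    for p in profiles:
        row = {sid: p.site_classes.get(sid, "unmapped") for sid in site_ids}
        for pl in PL_CLASSES:
            row[f"{pl}_conserved"] = p.pl_conserved.get(pl, 0)
        row["E90_conserved"] = p.e90_conserved
        row["category"] = p.category
        rows.append(row)
    df = pd.DataFrame(rows, index=[p.record_id for p in profiles])
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index_label="record")
    return df
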