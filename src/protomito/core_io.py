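"""Readers and writers for the external formats the pipeline touches.

All tabular formats are UTF-8, tab-separated with ``#`` comment lines.
Alignment columns and residue positions are 1-based throughout the package;
residue numbering keyed to a named reference sequence counts along the
mature (ungapped) sequence.

The amino-acid alphabet is the 20 standard letters plus ``X``; the ambiguity
codes B, Z and U are mapped to ``X`` with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = STANDARD_AA | {"X"}
_REMAP = {"B": "X", "Z": "X", "U": "X", "J": "X", "O": "X"}
GAP = "-"

#: Controlled vocabulary for cluster-table product labels (aliases resolved
#: at parse time; unknown labels are kept as "unknown" with a warning).
PRODUCT_VOCABULARY = {
    "COX1", "COX2", "COX3", "COX4",
    "ctaA/COX15", "ctaB/COX10", "ctaG/COX11",
    "SURF1", "SCO", "cytochrome_c", "PQQ_dehydrogenase", "MxaF",
    "NrfD2", "NrfD_like", "ABC_transporter", "regulator",
    "DUF983", "DUF2909", "EF_Ts_like", "unknown",
}

_PRODUCT_ALIASES = {
    "ctaC": "COX2", "ctaD": "COX1", "ctaE": "COX3", "ctaF": "COX4",
    "COXIV": "COX4", "COX15": "ctaA/COX15", "ctaA": "ctaA/COX15",
    "COX10": "ctaB/COX10", "ctaB": "ctaB/COX10",
    "COX11": "ctaG/COX11", "ctaG": "ctaG/COX11",
    "cyt_c": "cytochrome_c", "PQQ": "PQQ_dehydrogenase",
}

PROFILE_STATES = {"yes", "no", "precursor"}  # plus "<n> domains"


class FormatError(ValueError):
    """Raised on any malformed input file."""


@dataclass
class SequenceRecord:
    """One protein sequence: 20 standard letters plus X, no gaps."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"empty sequence for id {self.id!r}")
        cleaned = []
        remapped = set()
        for aa in self.residues.upper():
            if aa in _REMAP:
                remapped.add(aa)
                aa = _REMAP[aa]
            if aa == GAP:
                raise FormatError(f"gap character in sequence {self.id!r}")
            if aa not in ALPHABET:
                raise FormatError(f"illegal residue {aa!r} in sequence {self.id!r}")
            cleaned.append(aa)
        if remapped:
            warnings.warn(
                f"sequence {self.id}: ambiguity codes {sorted(remapped)} mapped to X"
            )
        self.residues = "".join(cleaned)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentBlock:
    """Equal-length gapped sequences with optional per-record group labels."""

    ids: list[str]
    rows: list[str]
    group_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            bad = [i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])]
            raise FormatError(f"ragged alignment; offending ids: {bad}")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate ids in alignment")
        if self.group_labels is not None:
            missing = set(self.ids) - set(self.group_labels)
            if missing:
                raise FormatError(f"group labels missing for records: {sorted(missing)}")
        # ungapping each row must yield a valid SequenceRecord
        for rid, row in zip(self.ids, self.rows):
            SequenceRecord(rid, "", row.replace(GAP, "") or "X")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)]

    def column(self, col: int) -> str:
        """1-based column."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(r[col - 1] for r in self.rows)

    def ungapped(self, rec_id: str) -> str:
        return self.row(rec_id).replace(GAP, "")

    def groups(self) -> dict[str, list[str]]:
        """Group name -> record ids (empty dict when no labels)."""
        out: dict[str, list[str]] = {}
        if self.group_labels:
            for rid in self.ids:
                out.setdefault(self.group_labels[rid], []).append(rid)
        return out


@dataclass
class GeneRow:
    organism: str
    cluster_id: str
    gene_index: int
    strand: str
    product_label: str
    protein_length: int
    domain_labels: list[str] = field(default_factory=list)


@dataclass
class GeneCluster:
    """Ordered annotated genes of one candidate operon."""

    organism: str
    cluster_id: str
    genes: list[GeneRow]

    def __post_init__(self) -> None:
        idx = [g.gene_index for g in self.genes]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise FormatError(
                f"gene_index not strictly increasing in cluster "
                f"{self.organism}/{self.cluster_id}"
            )

    @property
    def products(self) -> list[str]:
        return [g.product_label for g in self.genes]

    def genes_with(self, label: str) -> list[GeneRow]:
        return [g for g in self.genes if g.product_label == label]


def normalize_organism(name: str) -> str:
    """Underscores become spaces so organism names join across files."""
    return name.replace("_", " ").strip()


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein FASTA preserving record order.

    Duplicate ids and empty sequences are hard errors naming the offender.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, desc, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        for rec in bio:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(str(rec.seq[i:i + width]) + "\n")


def parse_alignment(
    path: str | Path, group_map: str | Path | Mapping[str, str] | None = None
) -> AlignmentBlock:
    """Read an aligned FASTA; ragged input is rejected with offending ids.

    ``group_map`` may be a mapping or a path to a two-column TSV
    (record id, taxon group).
    """
    ids: list[str] = []
    rows: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"no records in alignment {path}")
    labels: dict[str, str] | None = None
    if group_map is not None:
        if isinstance(group_map, (str, Path)):
            labels = {}
            for line in _data_lines(group_map):
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"bad group line {line!r}")
                labels[parts[0]] = parts[1]
        else:
            labels = dict(group_map)
    return AlignmentBlock(ids, rows, labels)


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(block.ids, block.rows):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# TSV tables


def _data_lines(path: str | Path) -> list[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.lstrip().startswith("#"):
                continue
            out.append(line)
    return out


def resolve_product_label(label: str) -> str:
    label = label.strip()
    label = _PRODUCT_ALIASES.get(label, label)
    if label not in PRODUCT_VOCABULARY:
        warnings.warn(f"unknown product label {label!r}; kept as 'unknown'")
        return "unknown"
    return label


CLUSTER_COLUMNS = [
    "organism", "cluster_id", "gene_index", "strand",
    "product_label", "protein_length", "domain_labels",
]


def parse_cluster_table(path: str | Path) -> list[GeneCluster]:
    """Read a gene-cluster TSV into clusters grouped by (organism, cluster_id).

    Rows are vocabulary-checked; an unknown product label becomes "unknown"
    with a warning, a non-monotone gene index is a hard error.
    """
    lines = _data_lines(path)
    if not lines:
        return []
    header = lines[0].split("\t")
    if header[: len(CLUSTER_COLUMNS)] != CLUSTER_COLUMNS:
        raise FormatError(
            f"cluster table header must start with {CLUSTER_COLUMNS}, got {header}"
        )
    grouped: dict[tuple[str, str], list[GeneRow]] = {}
    order: list[tuple[str, str]] = []
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) < 6:
            raise FormatError(f"short cluster row: {line!r}")
        organism = normalize_organism(parts[0])
        cluster_id = parts[1]
        try:
            gene_index = int(parts[2])
        except ValueError as exc:
            raise FormatError(f"bad gene_index in row {line!r}") from exc
        if gene_index < 0:
            raise FormatError(f"negative gene_index in row {line!r}")
        strand = parts[3]
        if strand not in {"+", "-"}:
            raise FormatError(f"bad strand {strand!r} in row {line!r}")
        label = resolve_product_label(parts[4])
        length = int(parts[5])
        domains = []
        if len(parts) > 6 and parts[6]:
            domains = [d.strip() for d in parts[6].split(",") if d.strip()]
        key = (organism, cluster_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(
            GeneRow(organism, cluster_id, gene_index, strand, label, length, domains)
        )
    return [GeneCluster(org, cid, grouped[(org, cid)]) for org, cid in order]


def write_cluster_table(clusters: Iterable[GeneCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CLUSTER_COLUMNS) + "\n")
        for cl in clusters:
            for g in cl.genes:
                fh.write(
                    "\t".join(
                        [
                            g.organism, g.cluster_id, str(g.gene_index), g.strand,
                            g.product_label, str(g.protein_length),
                            ",".join(g.domain_labels),
                        ]
                    )
                    + "\n"
                )


@dataclass
class ProfileRow:
    organism: str
    taxon_group: str
    feature: str
    state: str
    multiplicity: int = 1


def _valid_state(state: str) -> bool:
    if state in PROFILE_STATES:
        return True
    # "<n> domains" and combined forms like "precursor & 2 domains"
    for part in state.split("&"):
        part = part.strip()
        if part in PROFILE_STATES:
            continue
        tokens = part.split()
        if len(tokens) == 2 and tokens[1] in {"domain", "domains"} and tokens[0].isdigit():
            continue
        return False
    return True


def parse_profile_table(path: str | Path) -> list[ProfileRow]:
    """Read an organism x feature presence/absence table.

    Columns: organism, taxon_group, feature, state[, multiplicity].
    Aggregated rows ("other 130 fungi") carry their multiplicity explicitly.
    (organism, feature) pairs must be unique.
    """
    lines = _data_lines(path)
    if not lines:
        return []
    header = lines[0].split("\t")
    if header[:4] != ["organism", "taxon_group", "feature", "state"]:
        raise FormatError(f"bad profile header: {header}")
    rows: list[ProfileRow] = []
    seen: set[tuple[str, str]] = set()
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"short profile row: {line!r}")
        organism = normalize_organism(parts[0])
        feature = parts[2]
        state = parts[3]
        if not _valid_state(state):
            raise FormatError(f"illegal state {state!r} in row {line!r}")
        key = (organism, feature)
        if key in seen:
            raise FormatError(f"duplicate (organism, feature) pair {key}")
        seen.add(key)
        mult = int(parts[4]) if len(parts) > 4 and parts[4] else 1
        rows.append(ProfileRow(organism, parts[1], feature, state, mult))
    return rows


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Small helper used by all report writers."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
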