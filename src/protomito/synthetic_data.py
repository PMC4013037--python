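"""Seeded generators for every input class, plus the packaged fixtures.

The generators emulate the features the analysis depends on — operon gene
orders per type, hydrophobic transmembrane stretches, site-specific
conservation against a reference row, group-conserved indels, random
endowment sets, and group-structured alignments with a shared
"mitochondrial" branch — and always emit machine-readable ground truth
alongside the data. They deliberately do not model realistic phylogenetic
sequence evolution; see docs/methods.md for what that implies.

Determinism: every generator call derives one named pseudo-random stream
from (seed, stream name) via CRC-32, so equal specs give byte-identical
output and adding a generator never perturbs existing streams.
"""

from __future__ import annotations

import shutil
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .core_io import AlignmentBlock, GeneCluster, GeneRow, SequenceRecord
from .operon_classifier import load_cox3_reference
from .profiles import BioenergeticEndowment, BioenergeticSystem
from .similarity_scoring import load_reference_blocks

HYDROPHOBIC = np.array(list("ILVF"))
HYDROPHILIC = np.array(list("SGNDQKTERH"))
ALL_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Default per-residue substitution rate of the noise model.
DEFAULT_NOISE = 0.1


def stream(seed: int, name: str) -> np.random.Generator:
    """One named pseudo-random stream per generator call."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    arr[mask] = rng.choice(ALL_AA, mask.sum())
    return "".join(arr)


# ---------------------------------------------------------------------------
# Membrane proteins


@dataclass(frozen=True)
class MembraneProteinSpec:
    seed: int
    length: int = 120
    tm_spans: tuple[tuple[int, int], ...] = ()  # 1-based inclusive
    noise: float = DEFAULT_NOISE
    record_id: str = "synthetic_membrane_protein"


def generate_membrane_protein(spec: MembraneProteinSpec) -> tuple[SequenceRecord, list[tuple[int, int]]]:
    """Hydrophobic residues in the planted spans, hydrophilic elsewhere,
    with per-residue substitution noise. Overlapping spans are a hard error.
    Returns (record, planted spans)."""
    spans = sorted(spec.tm_spans)
    for (a1, b1), (a2, _) in zip(spans, spans[1:]):
        if a2 <= b1:
            raise ValueError(f"overlapping TM spans ({a1},{b1}) and starting {a2}")
    for a, b in spans:
        if not (1 <= a <= b <= spec.length):
            raise ValueError(f"span ({a},{b}) outside 1..{spec.length}")
    rng = stream(spec.seed, f"membrane:{spec.record_id}")
    arr = rng.choice(HYDROPHILIC, spec.length)
    for a, b in spans:
        arr[a - 1:b] = rng.choice(HYDROPHOBIC, b - a + 1)
    seq = _mutate(rng, "".join(arr), spec.noise)
    return SequenceRecord(spec.record_id, "synthetic membrane protein", seq), spans


# ---------------------------------------------------------------------------
# COX gene clusters


@dataclass(frozen=True)
class ClusterSpec:
    seed: int
    operon_type: str                 # a-I/a-II/a-III/a-IV/b/ab_transition/incomplete
    organism: str = "synthetic organism"
    cluster_id: str = "syn"
    with_sequences: bool = True
    noise: float = DEFAULT_NOISE


@dataclass
class ClusterTruth:
    operon_type: str
    planted_fusions: list[str] = field(default_factory=list)
    embedded_span: tuple[int, int] | None = None


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(HYDROPHILIC, length))


def _cox3_like(rng: np.random.Generator, noise: float, helices: int = 7) -> str:
    ref = load_cox3_reference().residues
    if helices == 5:
        ref = ref[72:]  # drop the 2-helix N-terminal block
    return _mutate(rng, ref, noise)


def generate_cluster(
    spec: ClusterSpec,
) -> tuple[GeneCluster, dict[str, SequenceRecord], ClusterTruth]:
    """A gene cluster realizing the defining rules of the planted type,
    with sequences keyed "<cluster_id>:<gene_index>" and truth labels."""
    known = {"a-I", "a-II", "a-III", "a-IV", "b", "ab_transition", "incomplete"}
    if spec.operon_type not in known:
        raise ValueError(f"unknown operon type {spec.operon_type!r}")
    rng = stream(spec.seed, f"cluster:{spec.cluster_id}:{spec.operon_type}")
    truth = ClusterTruth(spec.operon_type)
    genes: list[tuple[str, int, str]] = []  # (product, length, sequence)

    def core_cox2(fused: bool = False):
        if fused:
            genes.append(("COX2", 430, _random_protein(rng, 430)))
            truth.planted_fusions.append("COX2_cytc")
        else:
            genes.append(("COX2", 290, _random_protein(rng, 290)))

    def canonical_cox1():
        rec, _ = generate_membrane_protein(MembraneProteinSpec(
            int(rng.integers(2**31)), 530,
            tuple((1 + 40 * k, 25 + 40 * k) for k in range(12)),
            spec.noise, "cox1_core"))
        genes.append(("COX1", 530, rec.residues))

    t = spec.operon_type
    if t == "a-I":
        genes.append(("regulator", 210, _random_protein(rng, 210)))
        genes.append(("NrfD_like", 320, _random_protein(rng, 320)))
        genes.append(("NrfD2", 410, _random_protein(rng, 410)))
        core_cox2(fused=True)
        canonical_cox1()
        genes.append(("COX3", 261, _cox3_like(rng, spec.noise)))
        genes.append(("cytochrome_c", 120, _random_protein(rng, 120)))
    elif t == "a-II":
        core_cox2()
        # COX1 of 630-670 aa with a COX4-like C-terminal block
        length = int(rng.integers(630, 671))
        core = _random_protein(rng, length - 45)
        block = _mutate(rng, list(load_reference_blocks().values())[0].residues, 0.05)
        tail = _random_protein(rng, length - len(core) - len(block))
        genes.append(("COX1", length, core + block + tail))
        truth.planted_fusions.append("COX1_COX4")
        genes.append(("COX3", 189, _cox3_like(rng, spec.noise, helices=5)))
        genes.append(("PQQ_dehydrogenase", 600, _random_protein(rng, 600)))
        genes.append(("SURF1", 250, _random_protein(rng, 250)))
    elif t == "a-III":
        core_cox2()
        canonical_cox1()
        genes.append(("COX3", 261, _cox3_like(rng, spec.noise)))
        genes.append(("COX3", 261, _cox3_like(rng, spec.noise)))
        genes.append(("ctaB/COX10", 310, _random_protein(rng, 310)))
    elif t == "a-IV":
        core_cox2()
        core = _random_protein(rng, 540)
        block = _cox3_like(rng, spec.noise)
        genes.append(("COX1", 540 + len(block), core + block))
        truth.planted_fusions.append("COX1_3")
        truth.embedded_span = (541, 540 + len(block))
        genes.append(("ctaB/COX10", 300, _random_protein(rng, 300)))
    elif t == "b":
        genes.append(("ctaA/COX15", 340, _random_protein(rng, 340)))
        core_cox2()
        canonical_cox1()
        genes.append(("SCO", 200, _random_protein(rng, 200)))
        genes.append(("ctaG/COX11", 200, _random_protein(rng, 200)))
        genes.append(("COX3", 261, _cox3_like(rng, spec.noise)))
    elif t == "ab_transition":
        core_cox2()
        canonical_cox1()
        genes.append(("COX3", 261, _cox3_like(rng, spec.noise)))
        genes.append(("ABC_transporter", 420, _random_protein(rng, 420)))
        genes.append(("regulator", 220, _random_protein(rng, 220)))
    else:  # incomplete
        core_cox2()
        canonical_cox1()

    rows = []
    seqs: dict[str, SequenceRecord] = {}
    for idx, (product, length, seq) in enumerate(genes):
        rows.append(GeneRow(
            spec.organism, spec.cluster_id, idx, "+", product, length,
            ["cytochrome_c"] if product == "COX2" and length >= 350 else []))
        key = f"{spec.cluster_id}:{idx}"
        seqs[key] = SequenceRecord(key, product, seq)
    cluster = GeneCluster(spec.organism, spec.cluster_id, rows)
    return cluster, (seqs if spec.with_sequences else {}), truth


# ---------------------------------------------------------------------------
# Multiple sequence alignments with planted indels / conservation


@dataclass(frozen=True)
class IndelPlan:
    start: int                       # 1-based alignment columns
    end: int
    kind: str                        # IN / DEL relative to mitochondria
    carriers: tuple[str, ...]
    support: float = 1.0


@dataclass(frozen=True)
class ConservationPlan:
    """Target class per (record id, 1-based ungapped reference position)."""

    targets: tuple[tuple[str, int, str], ...] = ()  # (record, pos, class)


@dataclass(frozen=True)
class MsaSpec:
    seed: int
    groups: tuple[tuple[str, int], ...] = (("mitochondria", 4), ("alpha", 4))
    length: int = 120
    divergence: float = 0.05
    indel_plan: tuple[IndelPlan, ...] = ()
    conservation_plan: ConservationPlan = ConservationPlan()
    reference_id: str | None = None  # first record when None


def generate_msa(
    spec: MsaSpec,
) -> tuple[AlignmentBlock, dict]:
    """Group-labelled alignment with planted indels and site-conservation
    classes realized against the designated reference row.

    Returns (alignment, truth) where truth carries the realized indel plan
    and per-record conservation targets. A plan outside the alignment
    length is a hard error.
    """
    rng = stream(spec.seed, "msa")
    group_names = [g for g, _ in spec.groups]
    for plan in spec.indel_plan:
        if not (1 <= plan.start <= plan.end <= spec.length):
            raise ValueError(f"indel plan {plan} exceeds alignment length")
        if plan.kind not in {"IN", "DEL"}:
            raise ValueError(f"bad indel kind {plan.kind!r}")
        unknown = set(plan.carriers) - set(group_names)
        if unknown:
            raise ValueError(f"unknown carrier groups {sorted(unknown)}")

    base = "".join(rng.choice(ALL_AA, spec.length))
    ids, rows, labels = [], [], {}
    members: dict[str, list[str]] = {}
    for group, n in spec.groups:
        for k in range(n):
            rid = f"{group}_{k + 1}"
            ids.append(rid)
            labels[rid] = group
            members.setdefault(group, []).append(rid)
            rows.append(_mutate(rng, base, spec.divergence))

    grid = [list(r) for r in rows]
    index = {rid: i for i, rid in enumerate(ids)}
    for plan in spec.indel_plan:
        # IN: carriers keep residues, everyone else gapped; DEL: reverse
        for rid in ids:
            in_carrier = labels[rid] in plan.carriers
            gapped = (not in_carrier) if plan.kind == "IN" else in_carrier
            # realize within-group support: a 1-support plan is exact
            if rng.random() > plan.support:
                gapped = not gapped
            if gapped:
                for c in range(plan.start - 1, plan.end):
                    grid[index[rid]][c] = "-"

    ref_id = spec.reference_id or ids[0]
    truth_conservation = []
    if spec.conservation_plan.targets:
        from .similarity_scoring import blosum62
        m = blosum62()
        ref_row = grid[index[ref_id]]
        # map ungapped reference positions to columns
        pos_to_col, pos = {}, 0
        for col, aa in enumerate(ref_row):
            if aa != "-":
                pos += 1
                pos_to_col[pos] = col
        for rid, pos, target in spec.conservation_plan.targets:
            if rid not in index:
                raise ValueError(f"conservation plan names unknown record {rid!r}")
            if pos not in pos_to_col:
                raise ValueError(f"reference position {pos} is gapped/out of range")
            col = pos_to_col[pos]
            ref_aa = ref_row[col]
            choices = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != ref_aa]
            if target == "identical":
                aa = ref_aa
            elif target == "positive":
                aa = rng.choice([a for a in choices if m[a, ref_aa] > 0])
            elif target == "other":
                aa = rng.choice([a for a in choices if m[a, ref_aa] <= 0])
            elif target == "gap":
                aa = "-"
            else:
                raise ValueError(f"bad conservation target {target!r}")
            grid[index[rid]][col] = aa
            truth_conservation.append((rid, pos, target))

    block = AlignmentBlock(ids, ["".join(r) for r in grid], labels)
    truth = {
        "indels": list(spec.indel_plan),
        "conservation": truth_conservation,
        "reference_id": ref_id,
        "members": members,
    }
    return block, truth


def generate_grouped_alignment(
    seed: int,
    n_mito: int = 4,
    n_other: int = 8,
    length: int = 300,
    shared_rate: float = 0.25,
    leaf_rate: float = 0.03,
    other_rate: float = 0.08,
) -> AlignmentBlock:
    """Alignment in which a "mitochondria" group shares a long branch: the
    group descends from a common mutated ancestor while the remaining taxa
    radiate independently from the root sequence."""
    rng = stream(seed, "grouped_alignment")
    root = "".join(rng.choice(ALL_AA, length))
    mito_anc = _mutate(rng, root, shared_rate)
    ids, rows, labels = [], [], {}
    for k in range(n_mito):
        rid = f"mito_{k + 1}"
        ids.append(rid)
        labels[rid] = "mitochondria"
        rows.append(_mutate(rng, mito_anc, leaf_rate))
    for k in range(n_other):
        rid = f"bact_{k + 1}"
        ids.append(rid)
        labels[rid] = "bacteria"
        rows.append(_mutate(rng, root, other_rate))
    return AlignmentBlock(ids, rows, labels)


# ---------------------------------------------------------------------------
# Random endowments


def generate_endowments(
    seed: int, n: int = 20, system_weight: float = 0.6
) -> list[BioenergeticEndowment]:
    """Random endowment sets over the six systems (BC1 always present, as in
    every attested subset); operon types only when the aa3 oxidase is."""
    rng = stream(seed, "endowments")
    out = []
    for k in range(n):
        systems = {BioenergeticSystem.BC1}
        for s in (BioenergeticSystem.AA3, BioenergeticSystem.CBB3,
                  BioenergeticSystem.BO, BioenergeticSystem.BD,
                  BioenergeticSystem.NMET):
            if rng.random() < system_weight:
                systems.add(s)
        cox = set()
        if BioenergeticSystem.AA3 in systems:
            for t in ("a-I", "a-II", "b"):
                if rng.random() < 0.4:
                    cox.add(t)
        isp = {"ISP1"} if rng.random() < 0.8 else set()
        if rng.random() < 0.3:
            isp.add("ISP2")
        out.append(BioenergeticEndowment(
            organism=f"synthetic_{k + 1}",
            taxon_group=f"group_{int(rng.integers(1, 4))}",
            systems=frozenset(systems),
            cox_operon_types=frozenset(cox),
            isp_forms=frozenset(isp),
            photosynthesis=bool(rng.random() < 0.2),
        ))
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures

FIXTURE_FILES = (
    "table1_nmet.tsv",
    "fig1b_subsets.tsv",
    "fig9_endowments.tsv",
    "cox3_pl_sites.tsv",
    "cox3_reference.synthetic.fasta",
    "cox4_reference_blocks.synthetic.fasta",
    "fig3a_exemplar_clusters.tsv",
    "table_s3_characters.tsv",
)


def package_fixtures(out_dir: str | Path) -> Path:
    """Write the packaged in-source fixtures into ``out_dir``; idempotent
    (re-running produces identical bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = resources.files("protomito").joinpath("data")
    for name in FIXTURE_FILES:
        shutil.copyfile(str(data.joinpath(name)), out / name)
    return out
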