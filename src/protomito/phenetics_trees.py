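"""Phenetic character comparison, p-distances and neighbour-joining trees.

The character matrix compares discrete operon-architecture characters
(fusion states, syntenic diads, transcription order, ...) across taxa by
shared-state counts. Distance trees are built transparently from
p-distances (mismatches over pairwise-comparable columns) with a canonical
neighbour-joining implementation; published tree topologies are reproduced
only at the property level (group structure on synthetic data), never as
replicas of the original trees, which came from profile-based web tools.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import GAP, AlignmentBlock, _data_lines


# ---------------------------------------------------------------------------
# Character matrix


@dataclass
class CharacterMatrix:
    taxa: list[str]
    characters: list[str]
    states: dict[str, list[str]]  # taxon -> states, aligned with characters

    def __post_init__(self) -> None:
        for t in self.taxa:
            if len(self.states[t]) != len(self.characters):
                raise ValueError(f"row {t!r} has wrong number of states")


def parse_character_matrix(path: str | Path) -> CharacterMatrix:
    lines = _data_lines(path)
    header = lines[0].split("\t")
    characters = header[1:]
    taxa, states = [], {}
    for line in lines[1:]:
        parts = line.split("\t")
        taxa.append(parts[0])
        states[parts[0]] = parts[1:]
    return CharacterMatrix(taxa, characters, states)


def load_table_s3() -> CharacterMatrix:
    """The packaged 11-character operon-architecture matrix."""
    from importlib import resources

    return parse_character_matrix(Path(str(
        resources.files("protomito").joinpath("data", "table_s3_characters.tsv"))))


def shared_character_score(matrix: CharacterMatrix, taxon_a: str, taxon_b: str) -> int:
    """Number of characters with equal state between two taxa."""
    for t in (taxon_a, taxon_b):
        if t not in matrix.states:
            raise KeyError(f"unknown taxon {t!r}")
    return sum(
        a == b for a, b in zip(matrix.states[taxon_a], matrix.states[taxon_b])
    )


def closest_taxa(matrix: CharacterMatrix, target: str) -> tuple[list[str], int]:
    """Taxa sharing the largest number of characters with ``target``."""
    scores = {
        t: shared_character_score(matrix, t, target)
        for t in matrix.taxa if t != target
    }
    best = max(scores.values())
    return sorted(t for t, s in scores.items() if s == best), best


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any() or not np.allclose(np.diag(m), 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def pairwise_distance(alignment: AlignmentBlock, model: str = "p_distance") -> DistanceMatrix:
    """p-distances with pairwise exclusion of gap-containing columns.

    A pair with zero comparable columns is set to the maximal distance 1.0
    with a warning.
    """
    if model != "p_distance":
        raise ValueError(f"unknown model {model!r}")
    if len(alignment.ids) < 3:
        raise ValueError("at least 3 sequences are required")
    rows = [np.frombuffer(r.encode(), dtype=np.uint8) for r in alignment.rows]
    gap = ord(GAP)
    n = len(rows)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = (rows[i] != gap) & (rows[j] != gap)
        ncomp = int(ok.sum())
        if ncomp == 0:
            warnings.warn(
                f"no comparable columns between {alignment.ids[i]} and "
                f"{alignment.ids[j]}; distance set to 1.0")
            dist = 1.0
        else:
            dist = float((rows[i][ok] != rows[j][ok]).sum() / ncomp)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(alignment.ids), d)


# ---------------------------------------------------------------------------
# Neighbour joining


@dataclass
class Tree:
    """Unrooted tree: adjacency with branch lengths, string-labelled leaves."""

    adj: dict[int, dict[int, float]]
    labels: dict[int, str]
    negative_clamped: bool = False

    def leaves(self) -> list[str]:
        return sorted(self.labels.values())

    def _leafset(self, start: int, blocked: int) -> frozenset[str]:
        seen, stack, out = {blocked, start}, [start], []
        while stack:
            node = stack.pop()
            if node in self.labels:
                out.append(self.labels[node])
            for nbr in self.adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Leaf bipartitions induced by internal edges (topology identity)."""
        all_leaves = frozenset(self.labels.values())
        out = set()
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    side = self._leafset(v, u)
                    if 1 < len(side) < len(all_leaves) - 1:
                        out.add(frozenset({side, all_leaves - side}))
        return out

    def to_newick(self) -> str:
        root = next(n for n in self.adj if n not in self.labels) \
            if len(self.adj) > len(self.labels) else next(iter(self.adj))

        def sub(node: int, parent: int | None) -> str:
            children = [n for n in self.adj[node] if n != parent]
            if not children:
                return self.labels[node]
            inner = ",".join(
                f"{sub(c, node)}:{self.adj[node][c]:.6f}" for c in children
            )
            return f"({inner})"

        return sub(root, None) + ";"


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Canonical neighbour joining on the Q-matrix criterion.

    Ties in Q break deterministically toward the lexicographically lowest
    pair of current node labels; negative branch lengths are clamped to 0
    and flagged on the tree. Additive input matrices are recovered exactly
    (topology and branch lengths).
    """
    n0 = len(dist.labels)
    if n0 < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    d: dict[tuple[int, int], float] = {}
    active = list(range(n0))
    for i, j in itertools.combinations(active, 2):
        d[(i, j)] = d[(j, i)] = float(dist.matrix[i, j])
    names = {i: dist.labels[i] for i in active}  # tie-break labels
    adj: dict[int, dict[int, float]] = {i: {} for i in active}
    labels = {i: dist.labels[i] for i in active}
    clamped = False
    next_id = n0

    def connect(a: int, b: int, length: float) -> None:
        nonlocal clamped
        if length < 0:
            length, clamped = 0.0, True
        adj.setdefault(a, {})[b] = length
        adj.setdefault(b, {})[a] = length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[(i, k)] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[(i, j)] - r[i] - r[j]
            key = (q, tuple(sorted((names[i], names[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        u = next_id
        next_id += 1
        li = d[(i, j)] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[(i, j)] - li
        connect(i, u, li)
        connect(j, u, lj)
        names[u] = min(names[i], names[j])
        for k in active:
            if k in (i, j):
                continue
            duk = (d[(i, k)] + d[(j, k)] - d[(i, j)]) / 2
            d[(u, k)] = d[(k, u)] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
    centre = next_id
    connect(a, centre, la)
    connect(b, centre, lb)
    connect(c, centre, lc)
    return Tree(adj, labels, clamped)


def check_monophyly(tree: Tree, taxon_set: set[str]) -> tuple[bool, frozenset[str] | None]:
    """True iff some edge bipartitions the leaves exactly into taxon_set vs
    the rest; returns the matching side when found."""
    taxa = frozenset(taxon_set)
    all_leaves = frozenset(tree.labels.values())
    if not taxa <= all_leaves:
        raise KeyError(f"taxa not in tree: {sorted(taxa - all_leaves)}")
    if len(taxa) in (1, len(all_leaves) - 1, len(all_leaves)):
        return True, taxa  # trivial splits always exist on an unrooted tree
    for bp in tree.bipartitions():
        if taxa in bp:
            return True, taxa
    return False, None
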