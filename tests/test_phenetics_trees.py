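"""Character scores, p-distances, neighbour joining and monophyly."""

import itertools

import numpy as np
import pytest

from protomito.core_io import AlignmentBlock
from protomito.phenetics_trees import (
    CharacterMatrix, DistanceMatrix, Tree, check_monophyly, closest_taxa,
    load_table_s3, neighbor_joining, pairwise_distance, shared_character_score,
)
from protomito.synthetic_data import generate_grouped_alignment


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree (positive branch lengths) and its
    leaf-to-leaf path-distance matrix — the additivity oracle."""
    adj = {0: {}, 1: {}}
    w = rng.uniform(0.2, 1.0)
    adj[0][1] = adj[1][0] = w
    edges = [(0, 1)]
    leaves = [0, 1]
    nxt = 2
    for _ in range(n_leaves - 2):
        u, v = edges[int(rng.integers(len(edges)))]
        mid, leaf = nxt, nxt + 1
        nxt += 2
        length = adj[u].pop(v)
        adj[v].pop(u)
        edges.remove((u, v))
        a = rng.uniform(0.2, 0.8) * length
        adj.setdefault(mid, {})
        adj[mid][u] = adj.setdefault(u, {}).setdefault(mid, a) or a
        adj[u][mid] = a
        adj[mid][v] = adj.setdefault(v, {}).setdefault(mid, length - a) or (length - a)
        adj[v][mid] = length - a
        c = rng.uniform(0.2, 1.0)
        adj[mid][leaf] = c
        adj.setdefault(leaf, {})[mid] = c
        edges += [(u, mid), (mid, v), (mid, leaf)]
        leaves.append(leaf)

    def dists_from(a):
        d = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in d:
                    d[y] = d[x] + w
                    stack.append(y)
        return d

    labels = [f"t{l}" for l in leaves]
    D = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        da = dists_from(a)
        for j, b in enumerate(leaves):
            D[i, j] = da[b]
    D = (D + D.T) / 2  # exact symmetry despite float summation order
    tree = Tree({k: dict(v) for k, v in adj.items()},
                {l: f"t{l}" for l in leaves})
    return labels, D, tree


class TestCharacterMatrix:
    def test_identical_rows_share_all_eleven(self):
        cm = load_table_s3()
        assert len(cm.characters) == 11
        t = cm.taxa[0]
        assert shared_character_score(cm, t, t) == 11

    def test_score_symmetric_and_bounded(self):
        cm = load_table_s3()
        for a, b in itertools.combinations(cm.taxa, 2):
            s = shared_character_score(cm, a, b)
            assert s == shared_character_score(cm, b, a)
            assert 0 <= s <= len(cm.characters)

    def test_a_ii_exemplars_closest_to_protist_mitochondria(self):
        cm = load_table_s3()
        best, _ = closest_taxa(cm, "protist mitochondria")
        assert set(best) == {
            "Methylobacterium extorquens PA1 (a-II)",
            "Tistrella mobilis (a-II)",
        }

    def test_unknown_taxon_is_hard_error(self):
        with pytest.raises(KeyError):
            shared_character_score(load_table_s3(), "nobody", "protist mitochondria")

    def test_random_matrices_match_columnwise_oracle(self, rng):
        states = ["0", "1", "2"]
        taxa = [f"t{i}" for i in range(6)]
        chars = [f"c{i}" for i in range(9)]
        rows = {t: [str(rng.choice(states)) for _ in chars] for t in taxa}
        cm = CharacterMatrix(taxa, chars, rows)
        for a, b in itertools.combinations(taxa, 2):
            expected = sum(x == y for x, y in zip(rows[a], rows[b]))
            assert shared_character_score(cm, a, b) == expected


class TestPairwiseDistance:
    def test_identical_sequences_distance_zero(self):
        block = AlignmentBlock(["a", "b", "c"], ["MKLR", "MKLR", "MKLR"])
        d = pairwise_distance(block)
        assert np.allclose(d.matrix, 0)

    def test_quarter_mismatch(self):
        block = AlignmentBlock(["a", "b", "c"], ["AAAA", "AAAT", "TTTT"])
        d = pairwise_distance(block)
        assert d.get("a", "b") == pytest.approx(0.25)
        assert d.get("a", "c") == pytest.approx(1.0)

    def test_gap_columns_pairwise_excluded(self):
        block = AlignmentBlock(["a", "b", "c"], ["AA-A", "AATA", "AAAA"])
        d = pairwise_distance(block)
        assert d.get("a", "b") == pytest.approx(0.0)  # gapped column dropped

    def test_matches_bruteforce_recount(self, rng):
        aas = list("ACDG-")
        for _ in range(10):
            n, L = int(rng.integers(3, 7)), int(rng.integers(10, 40))
            rows = ["".join(rng.choice(aas, L)) for _ in range(n)]
            rows = [r if r.replace("-", "") else "A" * L for r in rows]
            block = AlignmentBlock([f"s{i}" for i in range(n)], rows)
            d = pairwise_distance(block)
            for i, j in itertools.combinations(range(n), 2):
                comp = [(x, y) for x, y in zip(rows[i], rows[j])
                        if x != "-" and y != "-"]
                expected = (sum(x != y for x, y in comp) / len(comp)
                            if comp else 1.0)
                assert d.matrix[i, j] == pytest.approx(expected)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
        lengths = {tree.labels[n]: list(tree.adj[n].values())[0]
                   for n in tree.labels}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_matrix_recovered_exactly(self, rng):
        labels, D, truth = random_additive_tree(rng, 4)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        assert tree.bipartitions() == truth.bipartitions()
        # branch lengths recovered: pairwise path distances match the input
        for i, a in enumerate(labels):
            da = _tree_leaf_distances(tree, a)
            for j, b in enumerate(labels):
                assert da[b] == pytest.approx(D[i, j], abs=1e-9)

    def test_random_additive_matrices_up_to_ten_taxa(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 11))
            labels, D, truth = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            assert tree.bipartitions() == truth.bipartitions()

    def test_agrees_with_scikit_bio_on_additive_input(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        for _ in range(10):
            labels, D, _ = random_additive_tree(rng, 7)
            ours = neighbor_joining(DistanceMatrix(labels, D))
            theirs = skbio_nj(SkbioDM(D, ids=labels))
            their_bps = set()
            all_leaves = frozenset(labels)
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(labels) - 1:
                    their_bps.add(frozenset({side, all_leaves - side}))
            assert ours.bipartitions() == their_bps

    def test_non_symmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))

    def test_newick_output_parses_with_biopython(self, rng, tmp_path):
        from io import StringIO
        from Bio import Phylo
        labels, D, _ = random_additive_tree(rng, 6)
        newick = neighbor_joining(DistanceMatrix(labels, D)).to_newick()
        tree = Phylo.read(StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)


def _tree_leaf_distances(tree, leaf_label):
    start = next(n for n, lbl in tree.labels.items() if lbl == leaf_label)
    d = {start: 0.0}
    stack = [start]
    out = {}
    while stack:
        x = stack.pop()
        for y, w in tree.adj[x].items():
            if y not in d:
                d[y] = d[x] + w
                stack.append(y)
    for n, lbl in tree.labels.items():
        out[lbl] = d[n]
    return out


class TestMonophyly:
    def test_caterpillar_first_two_leaves(self, rng):
        D = np.array([
            [0, 2, 5, 8, 9],
            [2, 0, 5, 8, 9],
            [5, 5, 0, 5, 6],
            [8, 8, 5, 0, 3],
            [9, 9, 6, 3, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCDE"), D))
        assert check_monophyly(tree, {"A", "B"})[0]
        assert not check_monophyly(tree, {"A", "C"})[0]

    def test_agrees_with_edge_removal_oracle(self, rng):
        import networkx as nx
        for _ in range(10):
            n = int(rng.integers(5, 13))
            labels, D, _ = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            g = nx.Graph()
            for u in tree.adj:
                for v in tree.adj[u]:
                    g.add_edge(u, v)
            for _ in range(8):
                size = int(rng.integers(2, n - 1))
                subset = set(rng.choice(labels, size=size, replace=False))
                expected = False
                for u, v in list(g.edges):
                    g.remove_edge(u, v)
                    comps = list(nx.connected_components(g))
                    g.add_edge(u, v)
                    for comp in comps:
                        side = {tree.labels[x] for x in comp if x in tree.labels}
                        if side == subset:
                            expected = True
                assert check_monophyly(tree, subset)[0] == expected

    def test_simulated_mitochondrial_group_recovered(self):
        hits = 0
        for rep in range(100):
            block = generate_grouped_alignment(rep)
            tree = neighbor_joining(pairwise_distance(block))
            mito = {l for l in tree.leaves() if l.startswith("mito")}
            hits += check_monophyly(tree, mito)[0]
        assert hits / 100 >= 0.90
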