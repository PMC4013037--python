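"""Parsimony model of bioenergetic-system loss and edit scoring of ancestors.

Attested system subsets form the nodes of a directed *subset graph*; an
edge u -> v exists when v equals u minus exactly one system, so every path
is a sequence of single-system losses. Operon-type and ISP changes never
create edges — they enter only the loss/acquisition edit scoring used to
rank candidate proto-mitochondrial progenitors, where an acquisition (via
lateral gene transfer) is treated as costlier than a loss.

Unattested intermediate subsets are never synthesized: only subsets seen
in extant organisms (or organelles) are nodes, mirroring the use of
sequenced genomes as the evidence base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .profiles import BioenergeticEndowment, BioenergeticSystem

Subset = frozenset[BioenergeticSystem]


@dataclass
class SubsetGraph:
    graph: nx.DiGraph  # nodes: Subset; attrs: organisms, discounted

    @property
    def nodes(self) -> list[Subset]:
        return list(self.graph.nodes)

    def organisms(self, subset: Subset) -> list[str]:
        return self.graph.nodes[subset]["organisms"]

    def find_node(self, systems) -> Subset:
        key = frozenset(
            s if isinstance(s, BioenergeticSystem) else BioenergeticSystem(s)
            for s in systems
        )
        if key not in self.graph:
            raise KeyError(f"subset {sorted(s.value for s in key)} not attested")
        return key

    def node_by_organism(self, organism: str) -> Subset:
        for n, data in self.graph.nodes(data=True):
            if organism in data["organisms"]:
                return n
        raise KeyError(f"no attested subset for organism {organism!r}")

    def to_dot(self) -> str:
        def label(n: Subset) -> str:
            return "{" + ",".join(sorted(s.value for s in n)) + "}"

        lines = ["digraph subsets {"]
        for n, data in self.graph.nodes(data=True):
            style = ' style="dashed"' if data.get("discounted") else ""
            lines.append(f'  "{label(n)}"{style};')
        for u, v, data in self.graph.edges(data=True):
            lines.append(f'  "{label(u)}" -> "{label(v)}" [label="{data["lost"].value}"];')
        lines.append("}")
        return "\n".join(lines)


def build_subset_graph(endowments: list[BioenergeticEndowment]) -> SubsetGraph:
    """One node per distinct attested system subset; edges drop one system.

    An edge (u, v) is present iff both subsets are attested, v is a subset
    of u and exactly one system separates them.
    """
    if not endowments:
        raise ValueError("at least one endowment is required")
    g = nx.DiGraph()
    for e in endowments:
        node = frozenset(e.systems)
        if node not in g:
            g.add_node(node, organisms=[], discounted=False)
        g.nodes[node]["organisms"].append(e.organism)
        g.nodes[node]["discounted"] = g.nodes[node]["discounted"] or e.discounted
    for u in g.nodes:
        for v in g.nodes:
            if v < u and len(u - v) == 1:
                (lost,) = u - v
                g.add_edge(u, v, lost=lost)
    return SubsetGraph(g)


@dataclass
class LossPathway:
    nodes: list[Subset]
    lost_systems: list[BioenergeticSystem]

    def __post_init__(self) -> None:
        assert len(self.lost_systems) == len(self.nodes) - 1
        for a, b, lost in zip(self.nodes, self.nodes[1:], self.lost_systems):
            assert a - b == {lost}

    def __len__(self) -> int:
        return len(self.lost_systems)


def enumerate_loss_pathways(
    sg: SubsetGraph, source: Subset, target: Subset
) -> list[LossPathway]:
    """All simple loss pathways from source to target.

    Sorted by length, then lexicographically by lost-system names. When the
    target is not a subset of the source the result is empty (not an error);
    source == target yields the single zero-length pathway.
    """
    if source not in sg.graph or target not in sg.graph:
        raise KeyError("source and target must be attested subsets")
    if source == target:
        return [LossPathway([source], [])]
    if not target < source:
        return []
    pathways = []
    for path in nx.all_simple_paths(sg.graph, source, target):
        lost = [sg.graph.edges[a, b]["lost"] for a, b in zip(path, path[1:])]
        pathways.append(LossPathway(list(path), lost))
    pathways.sort(key=lambda p: (len(p), [s.value for s in p.lost_systems]))
    return pathways


def direct_predecessors(sg: SubsetGraph, target: Subset) -> list[Subset]:
    """Attested subsets one single-system loss above the target."""
    return sorted(
        sg.graph.predecessors(target),
        key=lambda n: sorted(s.value for s in n),
    )


# ---------------------------------------------------------------------------
# Edit scoring (losses and acquisitions over full endowments)

EDIT_CLASSES = ("systems", "operon_types", "isp_forms", "photosynthesis")


@dataclass
class EditSummary:
    losses: dict[str, frozenset[str]] = field(default_factory=dict)
    acquisitions: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def total_losses(self) -> int:
        return sum(len(v) for v in self.losses.values())

    @property
    def total_acquisitions(self) -> int:
        return sum(len(v) for v in self.acquisitions.values())

    def per_class_totals(self) -> dict[str, tuple[int, int]]:
        return {
            c: (len(self.losses[c]), len(self.acquisitions[c])) for c in EDIT_CLASSES
        }


def endowment_edit(
    candidate: BioenergeticEndowment, target: BioenergeticEndowment
) -> EditSummary:
    """Feature-class-wise losses (candidate minus target) and acquisitions
    (target minus candidate)."""
    classes = {
        "systems": (candidate.system_names, target.system_names),
        "operon_types": (candidate.cox_operon_types, target.cox_operon_types),
        "isp_forms": (candidate.isp_forms, target.isp_forms),
        "photosynthesis": (
            frozenset({"photosynthesis"} if candidate.photosynthesis else set()),
            frozenset({"photosynthesis"} if target.photosynthesis else set()),
        ),
    }
    losses = {c: frozenset(a - b) for c, (a, b) in classes.items()}
    acquisitions = {c: frozenset(b - a) for c, (a, b) in classes.items()}
    return EditSummary(losses, acquisitions)


@dataclass
class RankedCandidate:
    rank: int
    endowment: BioenergeticEndowment
    edit: EditSummary


def rank_candidate_ancestors(
    endowments: list[BioenergeticEndowment],
    proto_target: BioenergeticEndowment,
    acquisitions_first: bool = True,
) -> list[RankedCandidate]:
    """Sort candidates by edit cost against the proto-mitochondrial target.

    Default policy weighs acquisitions before losses (lateral-gene-transfer
    acquisition is the costlier event); ties break alphabetically.
    """
    scored = []
    for e in endowments:
        edit = endowment_edit(e, proto_target)
        key = (
            (edit.total_acquisitions, edit.total_losses)
            if acquisitions_first
            else (edit.total_losses, edit.total_acquisitions)
        )
        scored.append((key, e.organism, e, edit))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [
        RankedCandidate(i + 1, e, edit) for i, (_, _, e, edit) in enumerate(scored)
    ]
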