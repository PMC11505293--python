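"""Process-specific subnetwork extraction and bridge-node identification.

A subnetwork (e.g. the ferroptosis subnetwork of the PCOS interactome) is
seeded from two sources: literature-tagged nodes (by gene-table category) and
members of an over-represented pathway. Non-seed "mediating" nodes are added
greedily, one intermediate at a time, until the seeds fall into a single
connected component of the induced subgraph. The "linking" (bridge) nodes
are the subnetwork-side endpoints of all edges crossing to the rest of the
parent graph; when there is exactly one, the subnetwork hangs off the
interactome through a single bottleneck gene (as KDM1A does for the
ferroptosis subnetwork).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import networkx as nx

logger = logging.getLogger(__name__)

#: Exhaustive mediator search is attempted up to this subset size, with at
#: most this many subsets examined per size, before falling back to greedy.
MEDIATOR_EXACT_BOUND = 4
MEDIATOR_EXACT_BUDGET = 200_000


@dataclass
class SubnetworkReport:
    """Seeds, mediators, induced edges and attachment points of a subnetwork."""

    seeds: dict[str, str] = field(default_factory=dict)  # symbol -> literature|pathway|both
    mediators: set[str] = field(default_factory=set)
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    unconnected_seed_groups: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.seeds) | self.mediators

    def role(self, node: str) -> str:
        if node in self.seeds:
            return f"seed_{self.seeds[node]}"
        return "mediator"


def _components_of(g: nx.Graph, nodes: set[str]) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(g.subgraph(nodes))]


def _greedy_mediators(
    parent: nx.Graph, seed_set: set[str], candidates: list[str], target: int
) -> set[str]:
    """Greedy single-intermediate merging used past the exact-search bound."""
    chosen: set[str] = set()
    while True:
        comps = _components_of(parent, seed_set | chosen)
        n_seed_groups = sum(1 for c in comps if c & seed_set)
        if n_seed_groups <= target:
            return chosen
        comp_index = {n: i for i, comp in enumerate(comps) for n in comp}
        best = None
        for cand in candidates:
            if cand in chosen:
                continue
            touched = {comp_index[x] for x in parent[cand] if x in comp_index}
            if len(touched) < 2:
                continue
            wsum = sum(
                parent.edges[cand, x].get("weight", 1.0)
                for x in parent[cand]
                if x in seed_set
            )
            key = (len(touched), wsum)
            if best is None or key > best[0]:
                best = (key, cand)
        if best is None:
            return chosen
        chosen.add(best[1])


def extract_subnetwork(
    parent: nx.Graph,
    literature_tag: str = "fpt_associated",
    pathway_members: set[str] | frozenset[str] = frozenset(),
) -> SubnetworkReport:
    """Extract the subnetwork seeded by a category tag plus pathway members.

    Seeds are parent nodes either carrying ``category == literature_tag`` or
    listed in ``pathway_members`` (tagged ``both`` when in both sources).
    Mediator candidates are non-seed parent nodes adjacent to at least two
    seeds (so every mediator sits on a two-edge path between seeds, the
    single-intermediate rule of the connector search); the selected set is
    the minimum-cardinality one that merges the seed set into as few induced
    components as the full candidate pool allows, found by exhaustive
    enumeration in increasing size and, past the size/budget bound, by a
    greedy fallback (most components merged; ties by summed edge weight to
    seeds, then lexicographic). Seed groups no single intermediate can merge
    are left as-is and counted.
    """
    cats = nx.get_node_attributes(parent, "category")
    lit = {n for n, c in cats.items() if c == literature_tag}
    path_nodes = {n for n in pathway_members if n in parent}
    seeds = {}
    for n in sorted(lit | path_nodes):
        src = "both" if n in lit and n in path_nodes else ("literature" if n in lit else "pathway")
        seeds[n] = src
    if not seeds:
        raise ValueError(
            f"no seed present in parent graph (tag {literature_tag!r}, "
            f"{len(pathway_members)} pathway member(s))"
        )

    seed_set = set(seeds)
    candidates = sorted(
        v
        for v in set(parent.nodes) - seed_set
        if sum(1 for x in parent[v] if x in seed_set) >= 2
    )

    def n_groups(mediator_set: set[str]) -> int:
        comps = _components_of(parent, seed_set | mediator_set)
        return sum(1 for c in comps if c & seed_set)

    target = n_groups(set(candidates))
    mediators: set[str] | None = None
    if n_groups(set()) == target:
        mediators = set()
    else:
        for m in range(1, min(MEDIATOR_EXACT_BOUND, len(candidates)) + 1):
            if comb(len(candidates), m) > MEDIATOR_EXACT_BUDGET:
                break
            found = next(
                (
                    set(sub)
                    for sub in combinations(candidates, m)
                    if n_groups(set(sub)) == target
                ),
                None,
            )
            if found is not None:
                mediators = found
                break
    if mediators is None:
        logger.info("mediator search past exact bound; using greedy fallback")
        mediators = _greedy_mediators(parent, seed_set, candidates, target)

    report = SubnetworkReport(
        seeds=seeds,
        mediators=mediators,
        unconnected_seed_groups=target - 1,
    )
    sub = parent.subgraph(report.nodes)
    report.edges = sorted(
        (min(u, v), max(u, v), d.get("weight", 1.0)) for u, v, d in sub.edges(data=True)
    )
    return report


def linking_nodes(parent: nx.Graph, sub: SubnetworkReport) -> set[str]:
    """Subnetwork nodes through which it attaches to the rest of the graph.

    Computed as the subnetwork-side endpoints of all boundary edges. If the
    subnetwork covers the whole parent graph there is no boundary; an empty
    set is returned with a logged notice. A singleton result is the
    single-bottleneck pattern: removing that node detaches the subnetwork
    from the remaining interactome.
    """
    inside = sub.nodes & set(parent.nodes)
    outside = set(parent.nodes) - inside
    if not outside:
        logger.info("subnetwork spans the whole parent graph; no boundary")
        return set()
    return {u for u, v in nx.edge_boundary(parent, inside, outside)}
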