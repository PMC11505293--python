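"""Minimal novel-connector prediction.

Seed genes that are not joined to the core network ("orphans") are connected
by adding the minimum number of background nodes. A connector set C resolves
an orphan o when the thresholded background graph contains a path

    o - x1 - ... - xk - c      (xi in C, c in the core, k <= L)

with every edge scoring above the confidence threshold. This is a restricted
Steiner-node problem; the search is iterative, first allowing a single
intermediate (L = 1) and then escalating to L = 2 for orphans still
unresolved. Added nodes are the "novel" predictions of the pipeline.

Exact mode enumerates candidate subsets in increasing size (bounded), with a
greedy fallback past the bound; greedy mode repeatedly adds the candidate
resolving the most orphans (ties: higher summed incident edge score, then
lexicographic), so results are reproducible for fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .graph_core import DEFAULT_PRIOR, DEFAULT_TAU, edge_score, largest_component
from .io_formats import DEFAULT_CHANNELS, EdgeRecord

logger = logging.getLogger(__name__)

#: Exhaustive search is attempted up to this many connectors per stage.
DEFAULT_EXACT_BOUND = 5

#: Deepest path-depth limit supported; deeper chains are implausible.
MAX_DEPTH = 2


@dataclass
class ConnectorResult:
    """Outcome of a connector search."""

    connectors: set[str] = field(default_factory=set)
    attachments: dict[str, list[str]] = field(default_factory=dict)
    unresolved: set[str] = field(default_factory=set)
    #: above-threshold background edges incident to a connector whose other
    #: endpoint is a network node or another connector (used to merge the
    #: connectors into the graph)
    edges: list[tuple[str, str, float]] = field(default_factory=list)


def threshold_background(
    records: Iterable[EdgeRecord],
    tau: float = DEFAULT_TAU,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    prior: float = DEFAULT_PRIOR,
) -> nx.Graph:
    """Thresholded background graph: edges with recombined score > tau."""
    b = nx.Graph()
    for rec in records:
        s = edge_score(rec, channels, prior)
        if s > tau:
            b.add_edge(rec.node_a, rec.node_b, weight=s)
    return b


def _supports(
    b: nx.Graph, orphan: str, core_nodes: set[str], candidates: set[str], depth: int
) -> set[frozenset[str]]:
    """All connector sets that carry one admissible path for ``orphan``.

    ``frozenset()`` means the orphan already reaches the core directly.
    """
    sup: set[frozenset[str]] = set()
    if orphan not in b:
        return sup
    for x in b[orphan]:
        if x in core_nodes:
            sup.add(frozenset())
        elif x in candidates:
            if any(c in core_nodes for c in b[x]):
                sup.add(frozenset({x}))
            if depth >= 2:
                for y in b[x]:
                    if y != orphan and y != x and y in candidates:
                        if any(c in core_nodes for c in b[y]):
                            sup.add(frozenset({x, y}))
    return sup


def _satisfied(supports: set[frozenset[str]], chosen: set[str]) -> bool:
    return any(s <= chosen for s in supports)


def _sum_score(b: nx.Graph, node: str) -> float:
    return sum(d["weight"] for _, _, d in b.edges(node, data=True)) if node in b else 0.0


def _greedy_stage(
    b: nx.Graph,
    supports: dict[str, set[frozenset[str]]],
    chosen: set[str],
) -> set[str]:
    """Greedy cover of the stage orphans; returns newly added connectors."""
    added: set[str] = set()
    pending = {o for o, sup in supports.items() if not _satisfied(sup, chosen)}
    while pending:
        members = {u for o in pending for s in supports[o] for u in s if u not in chosen}
        if not members:
            break
        # primary rule: most orphans resolved outright; ties by higher summed
        # incident edge score, then lexicographically first
        gain = {
            u: sum(1 for o in pending if _satisfied(supports[o], chosen | {u}))
            for u in members
        }
        pick = min(members, key=lambda u: (-gain[u], -_sum_score(b, u), u))
        if gain[pick] == 0:
            # no single node resolves an orphan (an L = 2 chain is still
            # incomplete): make progress by the most-used support member
            uses = {
                u: sum(1 for o in pending for s in supports[o] if u in s)
                for u in members
            }
            pick = min(members, key=lambda u: (-uses[u], -_sum_score(b, u), u))
        chosen.add(pick)
        added.add(pick)
        pending = {o for o in pending if not _satisfied(supports[o], chosen)}
    return added


def _exact_stage(
    b: nx.Graph,
    supports: dict[str, set[frozenset[str]]],
    chosen: set[str],
    bound: int,
) -> set[str] | None:
    """Minimum-cardinality cover of the stage orphans, or None past the bound.

    Nodes appearing in every admissible path of some orphan (a unique
    support) are forced first; the remainder is solved by exhaustive subset
    enumeration in increasing size with lexicographic tie-break.
    """
    added: set[str] = set()
    pending = {o for o, sup in supports.items() if not _satisfied(sup, chosen)}
    # forcing loop: an orphan with a single admissible support pins its nodes
    changed = True
    while changed:
        changed = False
        for o in sorted(pending):
            sup = supports[o]
            if len(sup) == 1:
                (only,) = sup
                need = only - chosen
                if need:
                    chosen |= need
                    added |= need
                    changed = True
        pending = {o for o in pending if not _satisfied(supports[o], chosen)}
    if not pending:
        return added
    pool = sorted(
        {u for o in pending for s in supports[o] for u in s if u not in chosen}
    )
    for m in range(1, min(bound, len(pool)) + 1):
        for subset in combinations(pool, m):
            trial = chosen | set(subset)
            if all(_satisfied(supports[o], trial) for o in pending):
                chosen |= set(subset)
                return added | set(subset)
    return None


def _attachment_path(
    b: nx.Graph, orphan: str, core_nodes: set[str], chosen: set[str]
) -> list[str] | None:
    """Shortest admissible path orphan -> core through chosen connectors."""
    if orphan not in b:
        return None
    allowed = chosen | core_nodes | {orphan}
    sub = b.subgraph(allowed)
    best: list[str] | None = None
    lengths = nx.single_source_shortest_path(sub, orphan, cutoff=MAX_DEPTH + 1)
    for target, path in sorted(lengths.items()):
        if target in core_nodes and (best is None or len(path) < len(best)):
            best = path
    return best


def find_connectors(
    core: nx.Graph,
    orphans: Iterable[str],
    background: Iterable[EdgeRecord],
    tau: float = DEFAULT_TAU,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    prior: float = DEFAULT_PRIOR,
    max_intermediates: int = MAX_DEPTH,
    mode: str = "exact",
    exact_bound: int = DEFAULT_EXACT_BOUND,
) -> ConnectorResult:
    """Find a minimal background-node set joining orphan seeds to the core.

    The search is staged: orphans resolvable with one intermediate (L = 1)
    are handled first; only leftovers escalate to L = 2. Depths beyond 2 are
    refused. An empty background simply leaves every orphan unresolved.
    """
    if mode not in ("exact", "greedy"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 1 <= max_intermediates <= MAX_DEPTH:
        raise ValueError(f"max_intermediates must be in [1, {MAX_DEPTH}]")
    orphans = set(orphans)
    core_nodes = largest_component(core) - orphans
    overlap = orphans & largest_component(core)
    if overlap:
        raise ValueError(f"orphans already in the core component: {sorted(overlap)}")

    b = threshold_background(background, tau, channels, prior)
    network_nodes = set(core.nodes)
    candidates = set(b.nodes) - network_nodes - orphans

    chosen: set[str] = set()
    resolved: dict[str, int] = {}
    pending = set(orphans)
    for depth in range(1, max_intermediates + 1):
        supports = {
            o: _supports(b, o, core_nodes, candidates, depth) for o in sorted(pending)
        }
        stage = {o: s for o, s in supports.items() if s}
        if stage:
            if mode == "exact":
                got = _exact_stage(b, stage, chosen, exact_bound)
                if got is None:
                    logger.warning(
                        "exact connector search exceeded subset bound %d at "
                        "depth %d; falling back to greedy",
                        exact_bound,
                        depth,
                    )
                    _greedy_stage(b, stage, chosen)
            else:
                _greedy_stage(b, stage, chosen)
        for o in list(pending):
            if o in stage and _satisfied(stage[o], chosen):
                resolved[o] = depth
                pending.discard(o)

    attachments = {}
    for o in sorted(resolved):
        path = _attachment_path(b, o, core_nodes, chosen)
        if path is not None:
            attachments[o] = path

    edges = [
        (u, v, d["weight"])
        for u, v, d in b.edges(data=True)
        if (u in chosen or v in chosen)
        and {u, v} <= (chosen | network_nodes)
    ]
    edges = sorted((min(u, v), max(u, v), w) for u, v, w in edges)
    return ConnectorResult(
        connectors=chosen,
        attachments=attachments,
        unresolved=set(orphans) - set(resolved),
        edges=edges,
    )


def annotate_novel(g: nx.Graph, result: ConnectorResult) -> nx.Graph:
    """Merge predicted connectors into the graph as ``novel_predicted`` nodes.

    Node count grows by exactly ``len(result.connectors)``; the qualifying
    above-threshold edges carried by the result are added. A connector that
    is already a graph node violates the search precondition and is a hard
    error.
    """
    present = set(result.connectors) & set(g.nodes)
    if present:
        raise ValueError(f"connector(s) already present in graph: {sorted(present)}")
    out = g.copy()
    for c in sorted(result.connectors):
        out.add_node(c, category="novel_predicted", seed=False, connector=True)
    for u, v, w in result.edges:
        if u in out and v in out:
            out.add_edge(u, v, weight=w)
    return out
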