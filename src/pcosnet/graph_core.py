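"""Combined-score recombination, graph construction and topology statistics.

The interaction graph is an undirected simple :class:`networkx.Graph` whose
edge weights are STRING-style combined scores S in [0, 1]. An edge enters the
graph only when the score recombined over the selected evidence channels
strictly exceeds the confidence threshold tau (default 0.7, i.e. "high
confidence"). Restricting the channels (default: experiments, curated
databases, text mining) and recombining honours the exclusion of predicted
association evidence such as co-expression or genomic neighborhood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_formats import DEFAULT_CHANNELS, EdgeRecord, GeneTable

logger = logging.getLogger(__name__)

#: STRING's documented prior probability that two random proteins interact.
DEFAULT_PRIOR = 0.041

#: High-confidence score threshold; edges must score strictly above it.
DEFAULT_TAU = 0.7

#: Default hub cutoff: a node is a hub when its degree reaches this value.
DEFAULT_HUB_THRESHOLD = 20


def recombine_combined_score(
    channel_scores: Mapping[str, float], prior: float = DEFAULT_PRIOR
) -> float:
    """Noisy-OR recombination of per-channel evidence scores.

    Each channel score s above the prior p is first corrected for the random
    expectation, ``s* = (s - p) / (1 - p)``, and the corrected scores are
    combined assuming independent evidence::

        S = 1 - (1 - p) * prod(1 - s*)

    which adds the prior back in. A single channel therefore passes through
    unchanged (S = s). Channels at or below the prior contribute nothing; if
    no channel exceeds the prior the score is 0 (no evidence).
    """
    if not 0.0 <= prior < 1.0:
        raise ValueError(f"prior {prior} outside [0, 1)")
    above = []
    for ch, s in channel_scores.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"channel {ch} score {s} outside [0, 1]")
        if s > prior:
            above.append((s - prior) / (1.0 - prior))
    if not above:
        return 0.0
    residual = math.prod(1.0 - s for s in above)
    return 1.0 - (1.0 - prior) * residual


def edge_score(
    record: EdgeRecord,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    prior: float = DEFAULT_PRIOR,
) -> float:
    """Recombined score of one edge over the selected channels.

    Records without any channel columns fall back to their file-supplied
    combined score unchanged.
    """
    chans = record.channels
    if not chans:
        return record.combined_score
    selected = {c: chans[c] for c in channels if c in chans}
    return recombine_combined_score(selected, prior)


def build_graph(
    edges: Iterable[EdgeRecord],
    seeds: GeneTable,
    tau: float = DEFAULT_TAU,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    prior: float = DEFAULT_PRIOR,
    extra_nodes: Iterable[str] = (),
) -> nx.Graph:
    """Build the thresholded interaction graph over the seed genes.

    An edge is kept iff both endpoints belong to ``seeds`` (or to the
    declared ``extra_nodes`` connector set) and its recombined score over the
    selected channels is strictly greater than ``tau``. Isolated seeds are
    retained as degree-0 nodes.
    """
    if len(seeds) == 0:
        raise ValueError("empty seed list")
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau {tau} outside (0, 1]")
    if not channels:
        raise ValueError("empty channel selection")
    allowed = set(seeds.symbols()) | set(extra_nodes)
    categories = seeds.categories()

    g = nx.Graph()
    for e in seeds.entries:
        g.add_node(e.symbol, category=e.category, seed=True)
    for x in extra_nodes:
        if x not in g:
            g.add_node(x, category="novel_predicted", seed=False)

    n_fallback = 0
    for rec in edges:
        if rec.node_a not in allowed or rec.node_b not in allowed:
            continue
        if not rec.channels:
            n_fallback += 1
        s = edge_score(rec, channels, prior)
        if s > tau:
            g.add_edge(rec.node_a, rec.node_b, weight=s)
    if n_fallback:
        logger.info(
            "%d edge(s) had no channel columns; used their combined_score as-is",
            n_fallback,
        )
    nx.set_node_attributes(
        g, {n: categories[n] for n in g.nodes if n in categories}, "category"
    )
    return g


@dataclass
class TopologySummary:
    """Node/edge counts, degree statistics and the hub table of a graph."""

    n_nodes: int
    n_edges: int
    average_degree: float
    degrees: dict[str, int]
    hub_table: list[tuple[str, int]]
    hub_threshold: int

    @property
    def average_degree_1dp(self) -> float:
        return round(self.average_degree, 1)


def topology_summary(
    g: nx.Graph,
    hub_threshold: int = DEFAULT_HUB_THRESHOLD,
    top_k: int | None = None,
) -> TopologySummary:
    """Compute exact degree statistics and the hub table.

    Hubs are nodes with degree >= ``hub_threshold``, sorted by degree
    descending with lexicographic tie-break; ``top_k`` switches to a
    largest-k-degrees mode instead of the fixed cutoff.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = {n: int(d) for n, d in g.degree()}
    ordered = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        hub_table = ordered[:top_k]
    else:
        hub_table = [(n, d) for n, d in ordered if d >= hub_threshold]
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        average_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        degrees=degrees,
        hub_table=hub_table,
        hub_threshold=hub_threshold,
    )


def largest_component(g: nx.Graph) -> set[str]:
    """Node set of the largest connected component (lexicographic tie-break)."""
    if g.number_of_nodes() == 0:
        return set()
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return set(comps[0])


def articulation_nodes(g: nx.Graph) -> set[str]:
    """Articulation (cut) vertices of the largest connected component.

    These are the nodes whose removal increases the number of connected
    components -- the structural bottlenecks through which subnetworks attach
    to the rest of the interactome.
    """
    comp = largest_component(g)
    if not comp:
        return set()
    return set(nx.articulation_points(g.subgraph(comp)))
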