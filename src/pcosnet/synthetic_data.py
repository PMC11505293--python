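"""Synthetic STRING-like inputs with planted ground truth.

Generates, fully reproducibly from one integer seed: a curated-style gene
table, an evidence-channel edge table, and a GMT annotation collection. The
planted structure (a connected seed core, orphan seeds reachable only
through designated connectors, one high-degree hub, and an enriched
annotation set) gives every pipeline stage a known right answer without any
download.

Scores are drawn so the confidence threshold is unambiguous: signal edges
carry one or two channel scores in (0.7, 1] (Beta(8, 2) scaled), noise edges
a single channel score in [0, 0.7) (Beta(2, 8) scaled). Because a noise edge
carries only one channel, its recombined score equals the raw score and can
never cross the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import DEFAULT_CHANNELS, EdgeRecord, GeneEntry, GeneSetCollection, GeneTable

DEFAULT_TAU = 0.7


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the curated study's scale: 120 literature seeds of which
    20 are orphans, 20 designated connectors, and a core wired so the final
    annotated network has 140 nodes and 511 above-threshold edges (average
    degree 7.3). The planted hub reaches degree 41 and the planted
    annotation set covers half the study genes.
    """

    n_seeds: int = 120
    n_orphans: int = 20
    n_connectors: int = 20
    n_background: int = 40
    n_fpt: int = 38
    core_edges: int = 471
    planted_hub_degree: int = 41
    n_noise_edges: int = 120
    # planted-annotation parameters
    universe_size: int = 500
    set_size: int = 10
    study_size: int = 20
    n_decoy_sets: int = 19
    effect: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_orphans > self.n_seeds:
            raise ValueError("n_orphans exceeds n_seeds")
        if self.n_orphans > 0 and not 1 <= self.n_connectors <= self.n_orphans:
            raise ValueError("need 1..n_orphans connectors when orphans exist")
        if self.n_connectors > self.n_background:
            raise ValueError("connectors must fit in the background pool")
        n_core = self.n_seeds - self.n_orphans
        if self.planted_hub_degree >= n_core:
            raise ValueError("planted_hub_degree must be below the core size")
        if self.core_edges < max(n_core - 1, self.planted_hub_degree):
            raise ValueError("core_edges too small for a connected core with the hub")
        if self.core_edges > n_core * (n_core - 1) // 2:
            raise ValueError("core_edges exceeds the complete-graph bound")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        if self.set_size > self.universe_size:
            raise ValueError("set_size exceeds universe_size")
        if self.n_fpt > self.n_seeds:
            raise ValueError("n_fpt exceeds n_seeds")


@dataclass
class GroundTruth:
    """What was planted: connectors, hub, and the above-threshold edge set."""

    connectors: set[str] = field(default_factory=set)
    orphan_map: dict[str, str] = field(default_factory=dict)
    hub: str = ""
    hub_degree: int = 0
    signal_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_set: str = ""


def _signal_score(rng: np.random.Generator) -> float:
    s = 0.7 + 0.3 * rng.beta(8.0, 2.0)
    return float(min(1.0, max(s, 0.7 + 1e-9)))


def _noise_score(rng: np.random.Generator) -> float:
    return float(min(0.7 - 1e-9, 0.7 * rng.beta(2.0, 8.0)))


def _symbols(prefix: str, n: int, width: int = 3) -> list[str]:
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_network(spec: SyntheticSpec) -> tuple[GeneTable, list[EdgeRecord], GroundTruth]:
    """Generate the seed gene table, the edge table, and the ground truth.

    Construction: a connected random core over the non-orphan seeds (random
    spanning tree plus random fill to exactly ``core_edges``), with the first
    core node rewired up to the planted hub degree; each orphan attached by a
    signal edge to its designated connector, each connector by a signal edge
    to one random core node; noise edges (below threshold) sprinkled over
    all nodes. Byte-identical output for identical spec and seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_core = spec.n_seeds - spec.n_orphans
    core = _symbols("GENE", n_core)
    orphans = _symbols("ORPH", spec.n_orphans)
    connectors = _symbols("CONN", spec.n_connectors)
    background = connectors + _symbols("BACK", spec.n_background - spec.n_connectors)
    hub = core[0]

    edges: dict[tuple[str, str], float] = {}

    def add_edge(a: str, b: str, score: float) -> None:
        key = (a, b) if a < b else (b, a)
        edges.setdefault(key, score)

    # spanning tree: each node joins a uniformly chosen earlier node
    for i in range(1, n_core):
        j = int(rng.integers(0, i))
        add_edge(core[i], core[j], _signal_score(rng))
    # hub rewiring up to the planted degree
    hub_neighbors = {b for (a, b) in edges if a == hub} | {a for (a, b) in edges if b == hub}
    others = [c for c in core[1:] if c not in hub_neighbors]
    need = spec.planted_hub_degree - len(hub_neighbors)
    if need < 0:
        raise ValueError("spanning tree already exceeds planted_hub_degree; enlarge the core")
    for c in rng.permutation(others)[: max(0, need)]:
        add_edge(hub, str(c), _signal_score(rng))
    # random fill (hub excluded so its planted degree stays exact)
    non_hub = core[1:]
    while len(edges) < spec.core_edges:
        i, j = rng.integers(0, len(non_hub), size=2)
        if i != j:
            add_edge(non_hub[int(i)], non_hub[int(j)], _signal_score(rng))

    for idx, o in enumerate(orphans):
        c = connectors[idx % spec.n_connectors]
        add_edge(o, c, _signal_score(rng))
    for c in connectors:
        # attach off-hub so the planted hub degree stays exact
        target = core[int(rng.integers(1, n_core))]
        add_edge(c, target, _signal_score(rng))

    signal_edges = set(edges)
    truth = GroundTruth(
        connectors={connectors[i % spec.n_connectors] for i in range(spec.n_orphans)},
        orphan_map={o: connectors[i % spec.n_connectors] for i, o in enumerate(orphans)},
        hub=hub,
        hub_degree=sum(1 for a, b in signal_edges if hub in (a, b)),
        signal_edges=signal_edges,
    )

    # noise edges below threshold, over every node class
    all_nodes = core + orphans + background
    noise: dict[tuple[str, str], float] = {}
    while len(noise) < spec.n_noise_edges:
        i, j = rng.integers(0, len(all_nodes), size=2)
        if i == j:
            continue
        a, b = all_nodes[int(i)], all_nodes[int(j)]
        key = (a, b) if a < b else (b, a)
        if key not in edges:
            noise.setdefault(key, _noise_score(rng))

    channel_names = list(DEFAULT_CHANNELS)
    records: list[EdgeRecord] = []
    for (a, b), score in sorted(edges.items()):
        chans = {channel_names[int(rng.integers(0, 3))]: score}
        if rng.random() < 0.3:  # second, weaker channel on some signal edges
            extra = channel_names[int(rng.integers(0, 3))]
            chans.setdefault(extra, float(score * rng.uniform(0.8, 1.0)))
        records.append(EdgeRecord.make(a, b, chans, combined_score=score))
    for (a, b), score in sorted(noise.items()):
        chans = {channel_names[int(rng.integers(0, 3))]: score}
        records.append(EdgeRecord.make(a, b, chans, combined_score=score))

    entries = []
    fpt = set()
    if spec.n_fpt:
        fpt = {str(s) for s in rng.permutation(core + orphans)[: spec.n_fpt]}
    for s in core + orphans:
        cat = "fpt_associated" if s in fpt else "pcos_curated"
        entries.append(GeneEntry(s, cat))
    return GeneTable(entries), records, truth


def generate_annotation(
    spec: SyntheticSpec, study: Sequence[str]
) -> tuple[GeneSetCollection, GroundTruth]:
    """Generate an annotation collection with one planted enriched set.

    The universe is the study plus filler genes up to ``universe_size``. The
    planted set receives ``round(effect * n)`` study genes (capped at the set
    size) and random filler; decoys are drawn uniformly from the universe,
    so their overlaps follow the hypergeometric null. With effect 0 the
    planted set is itself a uniform draw (null mode).
    """
    spec.validate()
    study = [str(s) for s in study]
    if len(set(study)) != len(study):
        raise ValueError("study genes must be unique")
    if len(study) > spec.universe_size:
        raise ValueError("study larger than the universe")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7)))
    filler = _symbols("UNIV", spec.universe_size - len(study), width=4)
    universe = sorted(set(study) | set(filler))
    if len(universe) != spec.universe_size:
        raise ValueError("study symbols collide with universe filler names")

    k_forced = min(round(spec.effect * len(study)), spec.set_size)
    planted_members = set(rng.choice(study, size=k_forced, replace=False)) if k_forced else set()
    pool = [g for g in universe if g not in planted_members]
    planted_members |= {
        str(g) for g in rng.choice(pool, size=spec.set_size - k_forced, replace=False)
    }

    names = [f"set_{i + 1:02d}" for i in range(spec.n_decoy_sets + 1)]
    planted_name = names[int(rng.integers(0, len(names)))]
    sets = {}
    for name in names:
        if name == planted_name:
            members = frozenset(planted_members)
        else:
            members = frozenset(
                str(g) for g in rng.choice(universe, size=spec.set_size, replace=False)
            )
        sets[name] = ("synthetic set", members)
    collection = GeneSetCollection(sets, universe_override=frozenset(universe))
    return collection, GroundTruth(planted_set=planted_name)
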