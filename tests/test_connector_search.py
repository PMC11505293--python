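"""Minimal-connector search: examples, staged brute-force oracle, bookkeeping."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from pcosnet import annotate_novel, build_graph, find_connectors
from pcosnet.connector_search import threshold_background
from conftest import make_records


def core_of(*symbols):
    g = nx.Graph()
    nodes = list(symbols)
    g.add_nodes_from(nodes)
    for a, b in zip(nodes, nodes[1:]):
        g.add_edge(a, b, weight=0.9)
    return g


# ---------------------------------------------------------------------------
# independent staged brute-force oracle


def _reaches(b: nx.Graph, orphan, core, allowed, depth) -> bool:
    """Is there a path orphan -> core with <= depth intermediates in allowed?"""
    if orphan not in b:
        return False
    for x in b[orphan]:
        if x in core:
            return True
        if x in allowed:
            if any(c in core for c in b[x]):
                return True
            if depth >= 2:
                for y in b[x]:
                    if y in allowed and y != orphan and any(c in core for c in b[y]):
                        return True
    return False


def staged_brute_force(b: nx.Graph, core, orphans, max_depth=2):
    """Stage-wise minimum connector set by exhaustive subset enumeration."""
    cands = sorted(set(b.nodes) - set(core) - set(orphans))
    chosen: set = set()
    resolved: set = set()
    for depth in range(1, max_depth + 1):
        pending = [
            o
            for o in sorted(set(orphans) - resolved)
            if _reaches(b, o, core, set(cands), depth)
        ]
        pending = [o for o in pending if not _reaches(b, o, core, chosen, depth)]
        if not pending:
            resolved |= {
                o for o in orphans if _reaches(b, o, core, chosen, depth)
            }
            continue
        done = False
        for m in range(0, len(cands) + 1):
            for sub in combinations(cands, m):
                trial = chosen | set(sub)
                if all(_reaches(b, o, core, trial, depth) for o in pending):
                    chosen = trial
                    done = True
                    break
            if done:
                break
        resolved |= {o for o in orphans if _reaches(b, o, core, chosen, depth)}
    return chosen, set(orphans) - resolved


def random_instance(seed):
    """Random thresholded instance: small core, orphans, candidate pool."""
    rng = np.random.default_rng(seed)
    n_core = int(rng.integers(2, 4))
    n_orph = int(rng.integers(1, 6))
    n_cand = int(rng.integers(3, 10))
    core = [f"C{i}" for i in range(n_core)]
    orphans = [f"O{i}" for i in range(n_orph)]
    cands = [f"X{i}" for i in range(n_cand)]
    edges = [(a, b, 0.9) for a, b in zip(core, core[1:])]
    for o in orphans:
        for x in cands:
            if rng.random() < 0.35:
                edges.append((o, x, 0.9))
    for x in cands:
        if rng.random() < 0.5:
            edges.append((x, core[int(rng.integers(0, n_core))], 0.9))
        for y in cands:
            if x < y and rng.random() < 0.15:
                edges.append((x, y, 0.9))
    return core, orphans, make_records(edges)


class TestExamples:
    def test_unique_single_connector(self):
        core = core_of("A", "B")
        recs = make_records([("O", "X", 0.9), ("X", "A", 0.9)])
        res = find_connectors(core, {"O"}, recs)
        assert res.connectors == {"X"}
        assert res.attachments["O"] == ["O", "X", "A"]
        assert res.unresolved == set()

    def test_shared_connector_beats_private_ones(self):
        core = core_of("A", "B")
        recs = make_records(
            [
                ("O1", "X", 0.9), ("O2", "X", 0.9), ("X", "A", 0.9),
                ("O1", "Y1", 0.9), ("Y1", "A", 0.9),
                ("O2", "Y2", 0.9), ("Y2", "A", 0.9),
            ]
        )
        res = find_connectors(core, {"O1", "O2"}, recs, mode="exact")
        assert res.connectors == {"X"}

    def test_unreachable_orphan_unresolved(self):
        core = core_of("A", "B")
        recs = make_records([("O", "X", 0.9), ("X", "Y", 0.9)])  # Y never reaches core
        res = find_connectors(core, {"O"}, recs)
        assert res.unresolved == {"O"}
        assert res.connectors == set()

    def test_empty_background_no_error(self):
        res = find_connectors(core_of("A", "B"), {"O"}, [])
        assert res.unresolved == {"O"}

    def test_depth_two_chain(self):
        core = core_of("A", "B")
        recs = make_records([("O", "Y", 0.9), ("Y", "X", 0.9), ("X", "A", 0.9)])
        res = find_connectors(core, {"O"}, recs, max_intermediates=2)
        assert res.connectors == {"X", "Y"}
        res1 = find_connectors(core, {"O"}, recs, max_intermediates=1)
        assert res1.unresolved == {"O"}

    def test_orphan_inside_core_is_error(self):
        with pytest.raises(ValueError, match="core component"):
            find_connectors(core_of("A", "B"), {"A"}, [])

    def test_deeper_than_two_refused(self):
        with pytest.raises(ValueError):
            find_connectors(core_of("A", "B"), {"O"}, [], max_intermediates=3)


class TestOracle:
    @pytest.mark.parametrize("block", range(5))
    def test_exact_matches_staged_brute_force(self, block):
        """Exact mode equals stage-wise exhaustive minimum on random instances."""
        for i in range(20):
            seed = 1000 * block + i
            core, orphans, recs = random_instance(seed)
            g = core_of(*core)
            res = find_connectors(g, set(orphans), recs, mode="exact", exact_bound=10)
            b = threshold_background(recs)
            ref_chosen, ref_unresolved = staged_brute_force(b, core, orphans)
            assert len(res.connectors) == len(ref_chosen), f"seed {seed}"
            assert res.unresolved == ref_unresolved, f"seed {seed}"

    def test_greedy_never_beats_exact_and_connects_same_orphans(self):
        for seed in range(40):
            core, orphans, recs = random_instance(seed + 50_000)
            g = core_of(*core)
            exact = find_connectors(g, set(orphans), recs, mode="exact", exact_bound=10)
            greedy = find_connectors(g, set(orphans), recs, mode="greedy")
            assert len(greedy.connectors) >= len(exact.connectors)
            assert greedy.unresolved == exact.unresolved

    def test_determinism(self):
        core, orphans, recs = random_instance(77)
        g = core_of(*core)
        runs = [find_connectors(g, set(orphans), recs, mode="greedy") for _ in range(2)]
        assert runs[0].connectors == runs[1].connectors
        assert runs[0].attachments == runs[1].attachments


class TestAnnotateNovel:
    def test_ground_truth_merge_counts(self, small_network):
        genes, edges, truth = small_network
        g = build_graph(edges, genes)
        from pcosnet.graph_core import largest_component

        orphans = set(g.nodes) - largest_component(g)
        res = find_connectors(g, orphans, edges)
        assert res.connectors == truth.connectors
        g2 = annotate_novel(g, res)
        assert g2.number_of_nodes() == g.number_of_nodes() + len(truth.connectors)
        cats = nx.get_node_attributes(g2, "category")
        assert all(cats[c] == "novel_predicted" for c in res.connectors)

    def test_empty_connector_set_leaves_graph_unchanged(self):
        from pcosnet.connector_search import ConnectorResult

        g = core_of("A", "B")
        g2 = annotate_novel(g, ConnectorResult())
        assert nx.utils.graphs_equal(g, g2)

    def test_edge_bookkeeping(self):
        core = core_of("A", "B", "C")
        recs = make_records(
            [("O", "X", 0.9), ("X", "A", 0.9), ("X", "B", 0.9)]
        )
        g = core.copy()
        g.add_node("O")
        res = find_connectors(g, {"O"}, recs)
        g2 = annotate_novel(g, res)
        assert g2.number_of_edges() == g.number_of_edges() + 3

    def test_existing_connector_is_error(self):
        from pcosnet.connector_search import ConnectorResult

        g = core_of("A", "B")
        with pytest.raises(ValueError, match="A"):
            annotate_novel(g, ConnectorResult(connectors={"A"}))
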