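"""Over-representation analysis with FDR control and set-cover summarization.

Given a study gene set (the interactome nodes) and a gene-set collection
(KEGG-style pathways in GMT), each set is tested with the one-sided
hypergeometric upper tail: with universe size N, set size K, study size n and
overlap k, the p-value is P[X >= k] for X ~ Hypergeom(N, K, n), evaluated via
the survival function (stable summation, never 1 - CDF). The enrichment
ratio R = (k/n)/(K/N) is the observed-over-expected overlap. p-values are
adjusted by Benjamini-Hochberg step-up; significant sets are summarized by a
greedy weighted set cover that picks a small representative subset of terms
maximizing significance-weighted gene coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import GeneSetCollection, normalize_symbol

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.05

#: Floor on q-values inside set-cover weights, avoiding infinite weight at 0.
WEIGHT_EPS = 1e-16


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set ORA statistics."""

    name: str
    overlap: int          # k
    set_size: int         # K (restricted to the universe)
    study_size: int       # n
    universe_size: int    # N
    p_value: float
    q_value: float
    overlap_genes: frozenset[str] = frozenset()

    @property
    def expected(self) -> float:
        """Expected overlap e = n * K / N."""
        return self.study_size * self.set_size / self.universe_size

    @property
    def enrichment_ratio(self) -> float:
        """R = (k/n)/(K/N); 0 when the overlap is empty."""
        if self.overlap == 0:
            return 0.0
        return (self.overlap / self.study_size) / (self.set_size / self.universe_size)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    On sorted p-values, q(i) = min_{j >= i} min(1, m * p(j) / j).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def hypergeom_ora(
    study: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of a study set against every set in a collection.

    The universe defaults to the collection's annotated-gene union; study
    genes outside the universe are dropped with a logged count. Sets with no
    overlap are reported with p = 1 and R = 0. q-values are BH-adjusted
    across the collection.
    """
    study_norm = {normalize_symbol(s) for s in study}
    univ = (
        frozenset(normalize_symbol(s) for s in universe)
        if universe is not None
        else collection.universe
    )
    study_in = study_norm & univ
    dropped = len(study_norm) - len(study_in)
    if dropped:
        logger.info("dropped %d study gene(s) outside the universe", dropped)
    if not study_in:
        raise ValueError("study set is empty after intersection with the universe")

    n_univ = len(univ)
    n_study = len(study_in)
    names = collection.names()
    ks, Ks, overlaps = [], [], []
    for name in names:
        members = collection.members(name) & univ
        hit = members & study_in
        ks.append(len(hit))
        Ks.append(len(members))
        overlaps.append(frozenset(hit))
    ks_arr = np.array(ks)
    # survival function sf(k-1) = P[X >= k]; stable upper-tail summation
    p = hypergeom.sf(ks_arr - 1, n_univ, np.array(Ks), n_study)
    p = np.where(ks_arr == 0, 1.0, np.clip(p, 0.0, 1.0))
    q = bh_fdr(p.tolist())
    return [
        EnrichmentResult(
            name=name,
            overlap=ks[i],
            set_size=Ks[i],
            study_size=n_study,
            universe_size=n_univ,
            p_value=float(p[i]),
            q_value=float(q[i]),
            overlap_genes=overlaps[i],
        )
        for i, name in enumerate(names)
    ]


def significant_results(
    results: Iterable[EnrichmentResult], fdr_threshold: float = DEFAULT_FDR_THRESHOLD
) -> list[EnrichmentResult]:
    """Sets passing the FDR cut (q < threshold), in collection order."""
    return [r for r in results if r.q_value < fdr_threshold]


@dataclass
class CoverSelection:
    """Greedy weighted-set-cover outcome over the significant sets."""

    selected: list[str] = field(default_factory=list)
    covered: set[str] = field(default_factory=set)
    coverage_fraction: float = 0.0


def weighted_set_cover(
    significant: Sequence[EnrichmentResult],
    max_sets: int | None = None,
    coverage_target: float = 1.0,
) -> CoverSelection:
    """Pick a small representative subset of significant sets.

    Each set carries weight w = -log10(max(q, 1e-16)); the greedy step picks
    the set maximizing (newly covered study genes) * w, with ties broken by
    larger newly-covered count, then smaller q, then lexicographic name.
    Selection stops at ``max_sets``, at the coverage target (fraction of all
    study genes annotated to any significant set), or when no set adds a new
    gene.
    """
    if not significant:
        return CoverSelection()
    to_cover: set[str] = set()
    for r in significant:
        to_cover |= r.overlap_genes
    if not to_cover:
        return CoverSelection()
    weights = {r.name: -np.log10(max(r.q_value, WEIGHT_EPS)) for r in significant}
    by_name = {r.name: r for r in significant}

    selected: list[str] = []
    covered: set[str] = set()
    remaining = dict(by_name)
    while remaining:
        if max_sets is not None and len(selected) >= max_sets:
            break
        if len(covered) / len(to_cover) >= coverage_target:
            break
        best_name, best_key = None, None
        for name in sorted(remaining):
            new = len(remaining[name].overlap_genes - covered)
            key = (
                new * weights[name],
                new,
                -remaining[name].q_value,
            )
            if best_key is None or key > best_key or (key == best_key and name < best_name):
                best_name, best_key = name, key
        if best_name is None or best_key[1] == 0:
            break
        selected.append(best_name)
        covered |= by_name[best_name].overlap_genes
        del remaining[best_name]
    return CoverSelection(
        selected=selected,
        covered=covered,
        coverage_fraction=len(covered) / len(to_cover),
    )


def enrichment_report(
    results: Sequence[EnrichmentResult], selection: CoverSelection | None = None
) -> pd.DataFrame:
    """Ranked enrichment table, sorted by q then p then name."""
    chosen = set(selection.selected) if selection is not None else set()
    rows = [
        {
            "name": r.name,
            "genes": ";".join(sorted(r.overlap_genes)),
            "k": r.overlap,
            "K": r.set_size,
            "expected": round(r.expected, 6),
            "enrichment_ratio": round(r.enrichment_ratio, 6),
            "p_value": r.p_value,
            "q_value": r.q_value,
            "selected": r.name in chosen,
        }
        for r in results
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "name", "genes", "k", "K", "expected",
            "enrichment_ratio", "p_value", "q_value", "selected",
        ],
    )
    if len(frame):
        frame = frame.sort_values(["q_value", "p_value", "name"], ignore_index=True)
    return frame
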