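"""Readers and writers for every external representation the pipeline touches.

Supported formats: curated gene tables (TSV or bare symbol lists), interaction
edge tables in the STRING "protein links detailed" flat-file dialect, gene-set
collections in Broad GMT, plain TSV result tables, and GraphML export of the
final attributed graph.

Gene symbols are uppercased and whitespace-trimmed before any comparison; no
alias or ortholog mapping is attempted (the pipeline operates on human symbols
only).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: The three gene categories carried through the pipeline.
CATEGORIES = ("pcos_curated", "fpt_associated", "novel_predicted")

#: STRING evidence channels, in the order of the flat-file dialect.
CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experiments",
    "database",
    "textmining",
)

#: Channels used by default when recombining the combined score: experimental
#: evidence, curated knowledge bases, and text mining.
DEFAULT_CHANNELS = ("experiments", "database", "textmining")


def normalize_symbol(symbol: str) -> str:
    """Uppercase and trim a gene symbol."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneEntry:
    symbol: str
    category: str
    name: str = ""


@dataclass
class GeneTable:
    """Curated seed genes with category tags.

    Symbols are unique after uppercasing; each carries exactly one of the
    three categories in :data:`CATEGORIES`.
    """

    entries: list[GeneEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"unknown category {e.category!r} for {e.symbol}")
            if e.symbol in seen:
                raise ValueError(f"duplicate symbol {e.symbol}")
            seen[e.symbol] = e.category

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def categories(self) -> dict[str, str]:
        """Map symbol -> category."""
        return {e.symbol: e.category for e in self.entries}

    def category_counts(self) -> Counter:
        return Counter(e.category for e in self.entries)

    def by_category(self, category: str) -> list[str]:
        return [e.symbol for e in self.entries if e.category == category]


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected interaction with per-channel evidence scores in [0, 1].

    Endpoints are stored in lexicographic order so that (A, B) and (B, A)
    denote the same record.
    """

    node_a: str
    node_b: str
    channel_scores: tuple[tuple[str, float], ...] = ()
    combined_score: float = 0.0

    @staticmethod
    def make(
        node_a: str,
        node_b: str,
        channel_scores: Mapping[str, float] | None = None,
        combined_score: float = 0.0,
    ) -> "EdgeRecord":
        a, b = sorted((normalize_symbol(node_a), normalize_symbol(node_b)))
        if a == b:
            raise ValueError(f"self-loop on {a}")
        scores = tuple(sorted((channel_scores or {}).items()))
        for ch, s in scores:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"channel {ch} score {s} outside [0, 1]")
        if not 0.0 <= combined_score <= 1.0:
            raise ValueError(f"combined score {combined_score} outside [0, 1]")
        return EdgeRecord(a, b, scores, combined_score)

    @property
    def channels(self) -> dict[str, float]:
        return dict(self.channel_scores)

    @property
    def key(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT) serving as the annotation universe for ORA.

    ``universe`` defaults to the union of all member sets; an explicit
    override may enlarge it (never shrink below the union).
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe_override: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set {name!r}")
        if self.universe_override is not None:
            union = self.member_union()
            if not union <= self.universe_override:
                raise ValueError("universe override does not contain all members")

    def member_union(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    @property
    def universe(self) -> frozenset[str]:
        if self.universe_override is not None:
            return self.universe_override
        return self.member_union()

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# gene tables


def read_gene_table(path: str | Path, category_default: str = "pcos_curated") -> GeneTable:
    """Read a gene table from TSV (``symbol[\\tcategory[\\tname]]``) or a bare
    one-symbol-per-line list.

    Symbols are uppercased and deduplicated; a duplicate symbol with
    conflicting categories is a hard error. Lines starting with ``#`` are
    skipped. An empty file is a hard error.
    """
    if category_default not in CATEGORIES:
        raise ValueError(f"unknown default category {category_default!r}")
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            rows.append((fields[0], *fields[1:3], "", "")[:3])
    if rows and rows[0][0].lower() == "symbol":
        rows = rows[1:]
    if not rows:
        raise ValueError(f"empty gene table: {path}")

    entries: dict[str, GeneEntry] = {}
    for sym_raw, cat_raw, name in rows:
        sym = normalize_symbol(sym_raw)
        cat = cat_raw.strip() or category_default
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r} for symbol {sym} in {path}")
        if sym in entries:
            if entries[sym].category != cat:
                raise ValueError(
                    f"duplicate symbol {sym} with conflicting categories "
                    f"{entries[sym].category!r} vs {cat!r}"
                )
            continue
        entries[sym] = GeneEntry(sym, cat, name)
    return GeneTable(list(entries.values()))


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tcategory\tname\n")
        for e in table.entries:
            fh.write(f"{e.symbol}\t{e.category}\t{e.name}\n")


# ---------------------------------------------------------------------------
# STRING-dialect edge tables

_NODE_COLUMN_PAIRS = (
    ("protein1", "protein2"),
    ("node1", "node2"),
    ("node_a", "node_b"),
)


def read_string_links(path: str | Path, score_scale: str = "auto") -> list[EdgeRecord]:
    """Read a STRING "protein links detailed"-dialect edge table.

    The file is whitespace- or tab-delimited with a header naming the two
    node columns and ``combined_score``; per-channel columns are optional.
    ``score_scale`` is one of ``unit`` (scores already in [0, 1]), ``milli``
    (STRING's native 0-1000 integers) or ``auto`` (milli assumed when any
    score exceeds 1).

    Undirected duplicate rows (A,B)/(B,A) are merged keeping the per-channel
    maximum; self-loops are dropped with a logged warning.
    """
    if score_scale not in ("auto", "unit", "milli"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    cols = list(df.columns)
    node_cols = next((pair for pair in _NODE_COLUMN_PAIRS if set(pair) <= set(cols)), None)
    if node_cols is None or "combined_score" not in cols:
        dialects = ", ".join("/".join(p) for p in _NODE_COLUMN_PAIRS)
        raise ValueError(
            f"unrecognized header {cols} in {path}: need one node-column pair "
            f"({dialects}) plus combined_score, with optional channel columns "
            f"{list(CHANNELS)}"
        )
    channel_cols = [c for c in cols if c in CHANNELS]
    score_cols = channel_cols + ["combined_score"]

    values = df[score_cols].to_numpy(dtype=float)
    if score_scale == "auto":
        score_scale = "milli" if (values > 1).any() else "unit"
    limit = 1000.0 if score_scale == "milli" else 1.0
    for i in range(len(df)):
        bad = [(c, v) for c, v in zip(score_cols, values[i]) if not 0 <= v <= limit]
        if bad:
            raise ValueError(
                f"{path}, line {i + 2}: score {bad[0][1]} in column {bad[0][0]} "
                f"outside declared {score_scale} scale [0, {limit:g}]"
            )
    if score_scale == "milli":
        values = values / 1000.0

    merged: dict[tuple[str, str], dict] = {}
    n_self = 0
    for i, row in enumerate(df.itertuples(index=False)):
        a = normalize_symbol(str(getattr(row, node_cols[0])))
        b = normalize_symbol(str(getattr(row, node_cols[1])))
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        chans = dict(zip(channel_cols, values[i, : len(channel_cols)]))
        combined = values[i, -1]
        slot = merged.setdefault(key, {"channels": {}, "combined": 0.0})
        for ch, s in chans.items():
            if s > 0:  # a zero column means "no evidence on this channel"
                slot["channels"][ch] = max(slot["channels"].get(ch, 0.0), s)
        slot["combined"] = max(slot["combined"], combined)
    if n_self:
        logger.warning("dropped %d self-loop row(s) in %s", n_self, path)

    return [
        EdgeRecord.make(a, b, slot["channels"], slot["combined"])
        for (a, b), slot in sorted(merged.items())
    ]


def write_string_links(
    records: Sequence[EdgeRecord], path: str | Path, channels: Sequence[str] = CHANNELS
) -> None:
    """Write edge records as a unit-scale STRING-dialect table (TAB-delimited)."""
    used = [c for c in channels if any(c in r.channels for r in records)]
    with open(path, "w") as fh:
        fh.write("\t".join(["node_a", "node_b", *used, "combined_score"]) + "\n")
        for r in sorted(records, key=lambda r: r.key):
            vals = [f"{r.channels.get(c, 0.0):.6f}" for c in used]
            fh.write("\t".join([r.node_a, r.node_b, *vals, f"{r.combined_score:.6f}"]) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: ``name TAB description TAB member...``."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {lineno}: GMT line needs name, description "
                    f"and at least one member (got {len(fields)} field(s))"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(normalize_symbol(m) for m in fields[2:] if m.strip())
            if not members:
                raise ValueError(f"{path}, line {lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc, members = collection.sets[name]
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# result tables


def graph_to_edge_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node_a": min(u, v), "node_b": max(u, v), "score": round(d.get("weight", 1.0), 6)}
        for u, v, d in g.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    return frame.sort_values(["node_a", "node_b"], ignore_index=True)


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export with sorted node/edge insertion for byte-stable output."""
    out = nx.Graph(**g.graph)
    for n in sorted(g.nodes):
        out.add_node(n, **g.nodes[n])
    for u, v in sorted(tuple(sorted(e)) for e in g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    nx.write_graphml(out, str(path))


def write_results(report, out_dir: str | Path) -> list[Path]:
    """Write the full result file set for a completed pipeline run.

    Emits ``nodes.tsv``, ``hubs.tsv``, ``enrichment.tsv``, ``subnetwork.tsv``,
    ``edges.tsv``, ``graph.graphml`` and ``summary.json``; output is
    byte-stable across runs given identical inputs and seed.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: list[Path] = []

    def emit_tsv(name: str, frame: pd.DataFrame) -> None:
        p = out_dir / name
        frame.to_csv(p, sep="\t", index=False)
        written.append(p)

    g = report.graph
    cats = nx.get_node_attributes(g, "category")
    nodes = pd.DataFrame(
        [
            {
                "symbol": n,
                "category": cats.get(n, ""),
                "degree": g.degree(n),
                "is_novel": cats.get(n) == "novel_predicted",
            }
            for n in sorted(g.nodes)
        ]
    )
    emit_tsv("nodes.tsv", nodes)

    hubs = pd.DataFrame(report.topology.hub_table, columns=["hub", "degree"])
    emit_tsv("hubs.tsv", hubs)

    emit_tsv("enrichment.tsv", report.enrichment_table)

    sub = report.subnetwork
    sub_rows = [
        {"symbol": n, "role": sub.role(n), "is_linking": n in report.linking}
        for n in sorted(sub.nodes)
    ]
    emit_tsv("subnetwork.tsv", pd.DataFrame(sub_rows, columns=["symbol", "role", "is_linking"]))

    emit_tsv("edges.tsv", graph_to_edge_frame(g))

    gml = out_dir / "graph.graphml"
    export_graphml(g, gml)
    written.append(gml)

    summary = out_dir / "summary.json"
    with open(summary, "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(summary)
    return written


# ---------------------------------------------------------------------------
# packaged reference data


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_curated_genes() -> GeneTable:
    """The packaged curated PCOS-ferroptosis interactome gene list
    (140 symbols: 82 pcos_curated, 38 fpt_associated, 20 novel_predicted)."""
    return read_gene_table(_data_path("pcos_interactome_genes.tsv"))


def load_hub_table() -> pd.DataFrame:
    """The packaged major-hub table (12 rows, degree >= 20, TP53 highest)."""
    return pd.read_csv(_data_path("pcos_hubs.tsv"), sep="\t", comment="#")


def load_pathways() -> GeneSetCollection:
    """The packaged 16 over-represented KEGG pathway gene sets."""
    return read_gmt(_data_path("kegg_pathways.gmt"))
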