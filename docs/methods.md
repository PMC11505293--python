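# Methods

## Scope and data model

The package reconstructs, as an offline and fully testable pipeline, an
interactome analysis of polycystic ovary syndrome (PCOS) extended with
ferroptosis (FPT) biology: a curated gene list is expanded into a
high-confidence protein–protein interaction network, stranded genes are
joined by predicted "novel" connectors, topology and pathway
over-representation are characterized, and the ferroptosis-specific
subnetwork is extracted together with the node(s) bridging it to the rest
of the network.

Three external representations are read and written: curated gene tables
(TSV with `symbol`, optional `category` and `name`, or bare symbol lists),
interaction tables in the STRING "protein links detailed" flat-file dialect
(node pair, optional per-channel scores, `combined_score`; native 0–1000
integer scale auto-detected and mapped to [0, 1]), and gene-set collections
in Broad GMT. Gene symbols are uppercased and trimmed before any
comparison; no alias or ortholog mapping is attempted, since the analysis
operates on human symbols as curated. Self-loops are dropped with a logged
warning (they occur in real exports); duplicate undirected rows are merged
keeping the channel-wise maximum, a conservative union of evidence. A zero
channel column is treated as "no evidence on this channel" rather than an
explicit score of zero.

## Score recombination and network construction

Evidence channels are integrated by the standard noisy-OR with prior
correction: each channel score s above the prior p is rescaled to
s\* = (s − p)/(1 − p), the probability that no channel is true is
multiplied out, and the prior is added back, S = 1 − (1 − p)·Π(1 − s\*).
The prior defaults to p = 0.041, the documented random expectation that two
proteins interact; it is configurable. Channels at or below the prior
contribute nothing (they are not negative evidence), and if no channel
exceeds the prior the score is defined as 0. A single channel therefore
passes through algebraically unchanged, which the tests assert to machine
precision.

Only the experiments, curated-database and text-mining channels are used by
default, excluding predicted evidence such as co-expression or genomic
neighborhood; the channel set is a parameter. An edge enters the network
only if both endpoints are declared genes and S is **strictly** above
τ = 0.7 (the "high confidence" reading: a boundary edge at exactly 0.7 is
excluded). Records without channel columns fall back to their
file-supplied combined score, with a logged notice. Isolated seeds are kept
as degree-0 nodes so that orphan genes remain visible to the connector
stage.

Topology statistics are exact integer degrees; the average degree 2|E|/|N|
is reported at full precision and rounded to one decimal. Hubs are nodes
with degree ≥ h; h defaults to 20, the smallest degree in the curated hub
table, which reproduces its 12 rows; a top-k mode exists because the
original cutoff is a convention, not a derived quantity. Articulation
nodes are computed on the largest component via depth-first low-link
(networkx).

## Connector search

"Novel" connector prediction is formalized as a restricted Steiner-node
problem: find a minimum-cardinality set C of background nodes such that
every orphan has a path to the core component whose ≤ L intermediates all
lie in C, with every edge above τ. The search is iterative: L = 1 first,
then L = 2 only for orphans still unresolved; deeper chains are refused as
implausible for this kind of curated expansion. Per orphan the admissible
"supports" (connector sets carrying one path) are enumerated directly —
paths of depth ≤ 2 have at most two intermediates, so the enumeration is
closed-form. Exact mode first pins nodes forced by orphans with a unique
support, then enumerates remaining subsets in increasing size up to a bound
(default 5 per stage) with lexicographic tie-break, falling back to greedy
past the bound. Greedy mode repeatedly adds the candidate resolving the
most orphans, with ties broken by higher summed incident edge score and
then lexicographic order; when an L = 2 chain is only half-built it
progresses by the most-used support member. All tie-breaks are total
orders, so identical inputs give identical results. Because the exact
protocol is staged, its minimality guarantee is per stage: a single-stage
L = 2 optimum can in principle be smaller than the staged solution, and the
brute-force oracle in the tests follows the same staged protocol.

## Over-representation analysis

ORA uses the one-sided hypergeometric upper tail P[X ≥ k], computed through
the survival function (stable tail summation, never 1 − CDF, which loses
precision for small p). The universe defaults to the union of all
annotated genes in the collection; a larger reference universe can be
supplied (the package pads with placeholder genes to a stated size) because
genome-scale web tools use such references and the choice materially
changes expected counts. Study genes outside the universe are dropped with
a logged count; an empty intersection is a hard error. Sets with zero
overlap report p = 1 and enrichment ratio R = 0; otherwise
R = (k/n)/(K/N) exactly.

Benjamini–Hochberg step-up adjustment is implemented directly (sorted
cumulative minimum of m·p/rank) and cross-checked against statsmodels in
the tests. The weighted set cover summarizing significant sets is greedy:
weight w = −log₁₀(max(q, 10⁻¹⁶)) (the floor avoids infinite weight at
q = 0), gain = newly covered study genes × w, ties broken by larger
newly-covered count, then smaller q, then name. Selection stops at a set
budget, a coverage target, or zero marginal gain. Greedy set cover carries
the usual (1 − 1/e) approximation guarantee, which the tests verify against
exhaustive two-set optima.

## Subnetwork extraction and linking nodes

Subnetwork seeds come from two sources: nodes whose gene-table category
matches a literature tag (default `fpt_associated`) and the members of a
named pathway; both-source seeds are tagged as such. "Mediating" nodes are
defined as single intermediates: non-seed nodes adjacent to at least two
seeds, so each lies on a two-edge path between seeds — the same L = 1 rule
as the connector search. The selected mediator set is the smallest one that
merges the seeds into as few induced components as the full candidate pool
allows (exhaustive enumeration up to size 4 within a subset budget, then
greedy most-components-merged fallback). Seed groups no single intermediate
can merge are left separate and counted, rather than silently bridged by
longer chains — an alternative shortest-path-union rule was considered and
not implemented, because it changes the meaning of "mediator" from a local
witness to a global path choice.

Linking nodes are the subnetwork-side endpoints of all boundary edges. A
singleton is the bottleneck pattern: removing that node provably detaches
the subnetwork (asserted by component counts in the tests). If the
subnetwork spans the whole graph there is no boundary and the result is
empty with a logged notice.

## Synthetic data

The generator emulates the analysis's input shape with planted ground
truth. Defaults mirror the curated study's scale: 120 seed genes (20 of
them orphans), 20 designated connectors, and a connected core wired to
exactly 471 internal edges so the final annotated network has 140 nodes and
511 above-threshold edges (average degree 7.3); one core node is rewired to
degree exactly 41 (the planted hub); 38 seeds carry the ferroptosis tag.
The core is a uniform random spanning tree plus uniform fill, which keeps
it connected by construction. Signal edges draw one or two channel scores
from Beta(8, 2) scaled into (0.7, 1]; noise edges draw a single channel
score from Beta(2, 8) scaled into [0, 0.7). Because a noise edge carries
only one channel, its recombined score equals its raw score, so the
threshold behaviour is unambiguous while multi-channel recombination is
still exercised on signal edges. Orphans touch the above-threshold graph
only through their designated connector, making the minimal connector set
unique and exactly recoverable. All randomness flows through one
generator seeded by a single integer; identical specs give byte-identical
edge tables.

The annotation generator plants one enriched set among uniform decoys: the
planted set receives round(effect·n) study genes (capped at the set size)
plus uniform filler, so effect 0 is an exact null and effect 1 with K = n
forces total overlap. Decoy overlaps follow the hypergeometric null by
construction.

What the synthetic data does **not** emulate: the heavy-tailed degree
distribution of real interactomes, correlated evidence between channels,
literature co-citation structure, or overlapping real pathway annotations.
Passing tests therefore demonstrate algorithmic correctness and calibration
under controlled conditions, not biological validity of any particular
real-data result.

## Calibration and test design

The null-calibration check asks that the fraction of sets with p < 0.05,
over 2000 simulated uniform studies against one fixed null collection, lie
within the binomial 99% band around 0.05. Hypergeometric p-values are
discrete and super-uniform — P(p ≤ α) ≤ α with equality only when α sits on
the attainable grid — so the null design was chosen analytically such that
the exact test size is as close to nominal as the grid allows: universe
850, set size 125, study size 50 give size 0.049988 at the 0.05 level. One
set is tested per simulated study so the 2000 trials are independent and
the binomial reference applies exactly. Planted-signal recovery uses
effect 0.5 with K = 10, n = 20, N = 500, requiring the planted set to
attain the smallest q in at least 95 of 100 seeded runs.

Problem sizes throughout the suite are chosen so exhaustive oracles stay
exact: ORA is compared against full enumeration of all C(N, n) draws for
N ≤ 12; connector search against staged subset enumeration with ≤ 10
orphans and ≤ 15 candidates; mediator minimality against subset enumeration
with ≤ 8 seeds; articulation points against remove-and-recount on random
12-node graphs.

## Numerical choices and edge cases

- Strict inequality at τ; scores validated against the declared scale with
  line numbers in errors.
- Hub table, connector sets, cover selections and mediator sets all use
  documented total-order tie-breaks (degree/gain first, then score or q,
  then lexicographic name), so every output is deterministic.
- Result files are written with sorted rows and sorted GraphML insertion,
  making re-runs byte-identical.
- Degenerate inputs: empty seed list, empty study after universe
  intersection, GMT lines with fewer than three fields, and conflicting
  duplicate categories are hard errors; empty background (no connectors
  found, orphans unresolved) and empty enrichment (header-only table) are
  valid outcomes.

## Known limitations

- The packaged curated lists are transcriptions of a published curated
  compilation; 12 of the 38 ferroptosis-tier category assignments were
  reconstructed from narrative context because the source table's
  color-coding does not survive plain-text transcription (symbols and all
  counts are exact). The packaged symbol list preserves the source's
  apparent typos (e.g. both ACSL4 and ASCL4) rather than correcting them.
- Real-data claims that depend on live STRING/WebGestalt content (which
  specific pathways are significant, a particular gene's degree) are not
  reproducible offline; the package covers them with fixture bookkeeping
  plus property tests on synthetic data, and reproducing them requires a
  pinned STRING download supplied as an ordinary edge table.
- The connector search refuses depths beyond two intermediates; the
  mediator rule is deliberately local (single intermediates).
- No betweenness or eigenvector centralities, community detection, or
  layout/visualization; no identifier-mapping services; no Excel I/O.
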