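# Methods

This note documents the models, conventions and numerical choices behind
`lbdhub`, in the spirit of a package reference manual: what is computed,
under which assumptions, and where the design was genuinely open.

## Graph model

A predication graph is a directed typed multigraph: nodes are concepts
(CUI, name, a non-empty set of semantic-type codes), and at most one edge
exists per (subject, predicate, object) triple. Duplicate input rows merge
their PMID support; a node's semantic types are the union over all rows
mentioning it. Edge multiplicity is defined as the number of *distinct*
supporting PMIDs — article-level evidence — not the raw row count.
Self-loop rows are dropped at load time (counted, reported). Composite
identifiers use the concrete syntax `base|linked` with the base being the
substring before the first `|`; the input format never needs more
structure than that.

Degree queries count distinct incident edges matching a (predicate,
direction) filter; multiplicity is deliberately not counted, so degrees
feed path statistics rather than citation volume. Directions are `out`,
`in` and `both` (their union). The predicate vocabulary is open: any
uppercase token is accepted.

## Metapaths and HeteSim

A schema is an ordered tuple of (predicate, direction) steps read from the
source toward the target; a path instance is a *simple* node sequence
(no repeats) realizing it. Simple paths are required because at depth 2 a
walk that may revisit nodes degenerates toward self-similarity.
Enumeration is exhaustive and deterministic (schemas ordered by string
form, instances by node sequence); the pipeline uses an equivalent
backward enumeration from the target, which visits each path once instead
of once per candidate source.

HeteSim follows the standard meeting-probability construction: walk
forward from the source along the first ⌊L/2⌋ steps and backward from the
target along the rest, with uniform transition over the neighbors
matching each step; the score is the cosine of the two distributions,
hence in [0, 1], and 0 whenever either side places no mass on the middle
layer. Odd-length schemas split the middle edge: every concrete
middle-edge instance becomes a pseudo-node on which both walks can meet.
Transition probabilities ignore PMID multiplicity. That choice is the
simplest defensible one — evidence volume is an editorial signal, not a
topological one — and it is surfaced rather than hidden: multiplicity
influences results only through which edges exist at all and through
instance counts in DWPC. Walk mass that reaches a dead end is dropped
(the vectors need not sum to 1; the cosine normalizes).

Two useful identities hold by construction and are enforced by tests:
symmetry, HeteSim(s, t | P) = HeteSim(t, s | reverse(P)); and
self-similarity, HeteSim(s, s | P + reverse(P)) = 1 whenever P is
realized at s.

## Degree-weighted path counts

DWPC for one schema's instances is Σ over instances of ∏ over path nodes
of d^(−w). The per-node degree convention: the first node contributes its
degree along the first step in traversal orientation; every later node
contributes its degree along the step by which the path arrives at it
(reverse orientation) — an L-step path yields L+1 degrees, all ≥ 1 on a
realized path. The damping exponent defaults to w = 0.4, the conventional
published default for degree-weighted path counting; w = 0 recovers the
raw instance count, and DWPC is non-increasing in w whenever any
along-path degree exceeds 1.

## Rank aggregation

Each schema votes with a full ranking of the candidate sources by
DWPC-weighted HeteSim (midranks on ties). Aggregation is an unsupervised
inverse-disagreement scheme: starting from uniform voter weights w_m,
iterate

    mu(i)  = Σ_m w_m · r_m(i)
    d_m    = Σ_i (r_m(i) − mu(i))²
    w_m   ∝ 1 / (d_m + ε),        ε = 1e-9

until the largest weight change falls below `tol` (default 1e-8) or
`max_iter` (default 500). A node absent from a list is assigned rank
N + 1, with N the size of the common node universe, so unranked sources
are never rewarded. The published description of the revised aggregation
scheme this emulates does not pin down its internals; this concrete
update rule was chosen because it is convergent, testable, and exposes
all of its knobs (tol, max_iter, ε).

A source's aggregated relevance is Σ_m w_m · HeteSim_m(i) with 0 for
schemas that do not reach it — a convex combination, hence again in
[0, 1]. The alternative of reporting per-schema maxima was rejected as
less stable under schema multiplicity. Per simulation, relevance is
min–max normalized ((s − min)/(max − min); an all-equal vector maps to
0.5 everywhere to avoid a divide-by-zero while preserving percentile
semantics) and percentile-ranked with the midrank convention,
100·(less + 0.5·equal)/N, which matches the tie handling of Kendall
tau-b (computed via scipy, variant "b"; an exhaustive O(N²) pair-count
oracle backs it in the tests).

## Simulation architecture

A simulation spec names its targets, the allowed source semantic types
(default {AAPP, GNGM, HORM}), the search depth n (default 2 — the depth
at which exhaustive typed enumeration stays tractable), and w. Candidate
sources are all type-allowed non-target concepts. Multi-target relevance
is combined by the mean (a "min" alternative is exposed); the mean was
chosen because a source strongly tied to one target and moderately to the
other should outrank one moderately tied to both only in proportion.

Intersection reduces composite CUIs to base IDs, keeping the maximum
percentile over variants (strongest evidence per concept family), keeps
bases present in *all* intersected simulations, and filters on
`frequency` — the number of contributing (variant, simulation) rows —
with default minimum 2, the natural floor for a two-simulation
intersection. Hub selection filters intersection rows by mean percentile
and summed metapath count, optionally restricted to a whitelist, and
orders by (metapath count desc, mean percentile desc, CUI). Cross-domain
reporting sorts the hub-simulation intersection descending by the
declared hub priority order, ties broken by CUI; top-k reporting
(default k = 10) is segregated by semantic type *after* ranking, because
protein and gene concepts vastly outnumber hormones and would otherwise
monopolize a global list. Percentiles are computed per simulation, before
intersection. Every sort everywhere is stable with a lexicographic CUI
tie-break, so identical inputs give byte-identical outputs.

## Theme mapping

The document unit is one (source concept, PMID) pair. A lexicon is an
ordered list of (theme, lowercase token set) pairs; "unknown" is a
reserved label, not a theme. Documents are tokenized by lowercasing and
splitting on non-alphanumerics; the theme with the highest token-hit
count wins (occurrences count, so repeated words weigh more), zero hits
yield "unknown", and ties go to the earliest theme in lexicon order and
are counted for the caller. Assignment is single-label — distribution
percentages must sum to 100. No stemming or stop-word removal is applied
by default (determinism and transparency); the shipped six-theme lexicon
is illustrative and editable, not a canonical vocabulary.

## Synthetic benchmark

The generator emulates the structure a literature-mined graph presents to
a two-target study, at desk scale, with all randomness derived from one
seed (graph and corpus use fixed sub-stream offsets, so outputs are pure
functions of the configuration):

* two disease-like targets, never directly connected;
* per-target *mediator* concepts through which indirect connections run;
* 500 background sources (semantic types drawn from a fixed mixture over
  AAPP/GNGM/HORM/DSYN/PHSU), each tied to exactly one target, directly or
  through its mediators, plus within-community preferential-attachment
  edges that give the degree distribution a heavy tail;
* 10 bridge concepts tied to both targets; a bridge's number of distinct
  routes scales with its per-edge PMID multiplicity (default 5), which is
  what makes the planted signal visible to a uniform-transition walker —
  multiplicity alone would be invisible to it;
* a 3-node hub pathway chain at graph distance exactly 2 from both
  targets (always through mediators, never adjacent), adjoining most of
  each side's mediators so hubs are the best-connected members of the
  two-target intersection;
* a downstream cascade of `hub_fanout` (default 30) effectors, level 1
  adjacent to every hub (distance 3 from the targets) and level 2 behind
  level 1 (distance 4), reachable *only* through the hub pathway;
* composite-ID variants for 10% of background sources;
* a corpus (default n = 2000, 20% noise tokens) whose documents draw
  their tokens from the true theme's lexicon pool; true-"unknown"
  documents contain only generic filler words.

PMIDs are synthetic 8-digit strings. Planted structure is verified in the
tests by independent breadth-first-search distance oracles, never by the
pipeline under test.

What the benchmark shows — and what it does not: recovery of planted
bridges, hubs and downstream effectors demonstrates that the scoring,
aggregation, intersection and hub-expansion machinery does what it
claims on graphs whose truth is known. The generator does not attempt to
fit real predication-graph degree distributions, predicate semantics or
citation dynamics quantitatively, so recovery rates here do not translate
into recall figures on literature-scale graphs.

One benchmark-specific design choice: the synthetic hub simulations
re-target each selected hub *alone*, whereas the shipped real study plan
pairs each hub with the primary disease target. Planted downstream
effectors have, by construction, no depth-2 connection to the original
targets, so a mean combination with a paired target would structurally
halve exactly the deep signal the depth-extension benchmark measures;
re-targeting the hub alone is the direct analog of the hub-expansion
mechanism being tested.

## Problem sizes and numerics

Default benchmark sizes (500 background sources, ~650 nodes, ~1700 edges,
20 generator seeds; oracle checks on 100 random 4–12-node graphs over all
schemas of length ≤ 3) keep the full suite and the acceptance script in
the tens of seconds on one CPU while leaving every planted effect
comfortably detectable. HeteSim agreement with the matrix oracle is
required to 1e-9 (observed ~1e-16); tau-b agreement with the pair-count
oracle to 1e-10. Degenerate inputs are handled explicitly: empty graphs
load to empty results, all-equal score vectors normalize to 0.5,
unreachable pairs score 0, empty intersections warn and return empty
tables, and unsatisfiable hub criteria raise with a suggestion to relax
thresholds.

## Known limitations

* The aggregation scheme is a documented, testable stand-in for a
  published-but-unspecified "revised" rank aggregator; other convergent
  weighting rules would be equally admissible.
* HeteSim transitions ignore evidence multiplicity (see above); a
  frequency-weighted walk is a plausible variant the API leaves room for.
* Whether inverse predicates (CAUSES vs CAUSED_BY) should be collapsed is
  corpus-dependent; the loader takes predicates as given and direction
  handling is explicit in every schema.
* Exhaustive enumeration is desk-scale by design; there is no sampled or
  approximate mode for literature-scale graphs.
* Theme lexicons are illustrative; real studies should supply
  domain-curated token lists.
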