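# Methods

## Data model

A connectome is a set of named neurons and two edge layers: chemical
synapses (directed, positive integer weight = synapse count, at most one
record per ordered pair, parallel records summed on load) and gap
junctions (stored once per unordered pair, positive integer weight).
Because available wiring data do not annotate gap-junction directionality,
every gap junction is treated as bidirectional in all queries: the *dyad
state* of an ordered pair (a, b) is `forward`, `backward`, `reciprocal` or
`none`, and a lone gap junction — or a one-way chemical synapse plus a gap
junction — yields `reciprocal`.  The chemical-only view is produced by
channel filtering of the same object, never by a second loader, so both
analyses share one validated data structure.  Neurons carry an optional
curated layer (sensory / inter / premotor / motor; unknown when absent)
and an optional scalar soma position in [0, 1] along the
anterior–posterior axis.  Neurons listed in a layer table but absent from
the edge list are retained as isolated nodes so catalogue counts stay
stable.

Supported dialects: `generic_csv` (`pre,post,kind,weight`; round-trip
safe), `adjacency_matrix` (chemical only, documented), and the
"neuronal wiring" spreadsheet layout (send/receive codes deduplicated as
mirror records by taking the per-pair maximum with a mismatch warning;
electrical-junction rows deduplicated per unordered pair; neuromuscular
rows excluded from the neuron graph and logged).

## Triad taxonomy

A triad is (X, Y, Z) with role identity preserved: X, Y are the pair, Z a
common neighbor, so the X–Z and Y–Z dyads are never `none`.  Each of
those dyads is one of three states (role→Z, Z→role, bidirectional).  With
X and Y distinguishable only when the X–Y dyad is unidirectional, the
count is 9 (X→Y) + 6 (X↔Y) + 6 (X, Y unconnected) = 21 types.  Ids follow
the lexicographic order of the Z-dyad state pair (out < in < both), which
reproduces the conventional positions of all six named circuits
(#1 multi-output FFL, #2 multi-inter FFL, #5 multi-input FFL,
#10 mutually regulating, #13 mutually regulated, #15 fully bidirectional);
this correspondence is unit-tested, and every downstream statistic is
keyed by the canonical dyad-state triple rather than the id, so a
numbering transposition could not corrupt results.  Classification
canonicalizes under X↔Y swap (sorting the two Z-dyad states) whenever the
X–Y dyad is symmetric.

## Homogeneity scoring

For sets (pairs with ≥ `min_neighbors` = 5 common neighbors; connected
pairs in the main analysis), the dominant type's count k out of set size n
is scored with the upper-tail hypergeometric probability P[H ≥ k] with
population N = all triads pooled over the sets being analyzed and
K = pooled count of that type.  Pooling is within the connectivity class
under analysis (all connected sets, or all unconnected sets), recorded in
every report.  The p-value is computed by log-space summation of the exact
pmf over the upper tail (`logsumexp` over `hypergeom.logpmf`), which keeps
full relative accuracy deep in the tail where a 1 − cdf formulation loses
everything to cancellation; the suite verifies 1e-12 relative agreement
with a big-integer oracle.  A set is homogeneous iff p ≤ α = 0.05 — per
set, deliberately without multiplicity correction, matching the method's
stated threshold — **and** the dominant type holds at least half the
members.  Dominant-type ties break by smaller p, then lower canonical
order (deterministic, favoring the more surprising type).  A stricter
listing at p ≤ 1e-5 is available as a report option.

The network-level null permutes the member triad labels uniformly across
all member slots of all sets, conserving each set's size and the global
type multiset exactly (hard-asserted in tests).  Real-vs-null
homogeneous-set counts are compared per type by z-score with two-sided
normal p, Bonferroni-corrected over the types present.  When a null count
has zero variance the comparison is flagged degenerate and p is reported
as the ensemble's resolution bound 1/(R+1) rather than a fabricated tail
value.  The per-type z-test is anti-conservative for counts with
near-zero null mean (observing a single homogeneous set of a rare type
can clear Bonferroni), a property of the count-z formulation itself that
users should keep in mind at small R.

Supporting statistics: synapse coverage (fraction of total edge weight on
the X–Y and member X–Z/Y–Z dyads of at least one homogeneous set; both
channels counted) and the bilateral ratio (symmetric : asymmetric X–Y
pairs, a pair being symmetric iff the names differ only in a terminal
L/R).

## CNR statistics

`cnr_curve` computes, per common-neighbor count, the fraction of unordered
pairs whose dyad state is not `none`, using the boolean symmetric
adjacency matrix (with a zero diagonal, (B·B)[i,j] counts exactly the
common neighbors excluding i and j).  The line is ordinary least squares
on bin fractions over bins holding ≥ `min_pairs_per_bin` = 5 pairs —
unweighted by default, since no weighting is part of the method statement;
a pair-count-weighted fit is available behind a flag.  Fewer than two
eligible bins flags the fit infeasible.  The ensemble test draws
`n_networks` nulls, drops (and counts) any null with an infeasible fit,
errs above 20% dropped, and reports z = (real − mean)/sd with a two-sided
normal p.

Degree-preserving nulls attempt `swap_factor × |E|` double-edge swaps per
channel (default 10, the standard mixing heuristic), directed on chemical
edges and undirected on gap edges, never interconverting the two layers —
the synapse classes are biologically distinct and are analyzed separately
downstream.  Swaps creating self-loops or duplicate records are rejected;
weights ride with edges, so all three degree sequences and total weight
per channel are conserved exactly.  The Erdős–Rényi null matches the node
count and the directed edge count (gap junctions counting twice) with
chemical weight-1 edges and no degree constraint.

Distance controls correlate either the common-neighbor count (over all or
connected pairs — both scopes are implemented because the published
figure's pair population is ambiguous; reports name the scope used) or a
0/1 connected indicator (all pairs) with |pos_x − pos_y|.  The one-tailed
p for negative correlation uses t = r·√((m−2)/(1−r²)) on m−2 df; zero
variance in either variable returns a degenerate flag with p = 1.  Caveat:
pairs sharing a node are dependent, so at large pair counts this nominal
reference is anti-conservative (the Mantel-test problem); the null
simulations in the suite therefore run at modest network size.

## Synthetic data

The generator emulates what the pipeline assumes about real wiring data:
layered neuron pools with curated labels, uniform [0, 1] soma positions
(bilateral L/R partners share one position), heavy-tailed-degree or
distance-dependent backgrounds where requested, and — centrally — planted
common-neighbor sets of chosen triad types with known ground truth.
Planted X–Y channels follow the empirically observed composition of the
bidirectional types: #10 reciprocal chemical, #13 and #15 gap, all other
connected types chemical; Z dyads are chemical.  Background edges are
drawn per ordered pair (default p = 0.02–0.03 in the study scripts, a
density comparable to the sparse backgrounds the method expects) and any
draw landing on an internal dyad of a planted set is redrawn elsewhere, so
planted triad types survive verbatim; background edges may still add new
common neighbors to a planted pair, which is the realistic dilution the
recovery tests exercise.  Identical seeds give byte-identical edge lists.

What the generator does **not** emulate: the real degree sequence (nulls
for real data come from the swap-based randomizer instead), spatial 3-D
anatomy, multi-animal variability, and synapse-sign annotations.  Passing
recovery tests therefore demonstrate correctness of the machinery under
the stated statistical structure, not biological completeness.

## Circuit dynamics

Graded-response units follow Michaelis–Menten rate equations

    dA_i/dt = Σ_chem sign·β·A_pre/(K + A_pre) + Σ_gap g·(A_j − A_i)
              + s_i(t) − α·A_i,   A_i(0) = 0,

with defaults α = β = K = g = 1 and rectangular stimulus pulses of
amplitude 1 and duration 1 (to X for the mutually regulating circuit; to
Z₁ and Z₂ offset by half a pulse width — unsynchronized — for the mutually
regulated circuit).  The asymmetric-drive condition doubles β(Z₁→X) and
multiplies K(Z₁→X) ten-fold relative to Z₁→Y.  An inhibitory variant
(sign = −1) is exposed and smoke-tested only.  Because the precise
published equation forms are not fully specified, every conclusion drawn
from these simulations is directional (connected vs unconnected twin,
monotonicity in g), never numeric.

Integration is fixed-step classical RK4 — chosen over adaptive stepping
for a bit-reproducible test surface — with step-halving as the
convergence check (default tolerance 1e-3; dt = 0.01 gives discrepancies
orders of magnitude below that).  Stimulus discontinuities fall on step
boundaries at the default dt.  Trajectories remain non-negative for
positive-sign circuits with non-negative inputs (property-tested).  The
activation threshold in the amplification report is drawn midway between
the two twins' peak excursions, i.e. at a level only the feedback circuit
crosses, mirroring how such thresholds are drawn in circuit diagrams; the
metrics are peak activity and time above threshold (grid measure), and the
coordination metric is max_t |A_X − A_Y|.

## Pipeline and reproducibility

`run_pipeline` executes loading/generation → CNR and slope tests →
distance controls (skipped with a flag when positions are missing) → set
extraction → homogeneity and enrichment → layer localization, X–Y channel
composition and the chemical-only reanalysis → headline circuit metrics,
writing one JSON/CSV per stage plus a coarse-grained summary (per
significant type: dominant layer pair and channel makeup).  Every random
stage has an explicit seed derived from the config; the config and its
hash (output-directory excluded) are persisted next to the outputs, and
reruns are byte-identical.

Study sizes in the analysis scripts and acceptance checks (~130–180
neurons, 15–24 planted sets, 100–500 null replicates) were chosen as the
smallest ensembles at which the planted effects and their nulls separate
cleanly and stably across seeds.

## Known limitations

- Gap junctions are forced bidirectional; if directional gap data become
  available the dyad-state logic is the single place to amend.
- The pooled hypergeometric population makes a set's p-value depend on
  which other sets are analyzed; a population of a single type is its own
  reference (p = 1), so homogeneity is only meaningful against a mixed
  population.
- The pair-level correlation tests ignore node-induced dependence between
  pairs (see above).
- The layer-pair enrichment background defaults to all homogeneous sets;
  "all sets" is available as a sensitivity option since the published
  background population is not stated.
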