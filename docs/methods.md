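# Methods

## Effect extraction

Published survival effects enter the pipeline as hazard ratios with
confidence intervals; all pooling happens on the natural-log scale. The
point estimate is `y = ln HR` — the published HR is taken as authoritative —
and the CI contributes only the standard error,
`se = (ln hi − ln lo)/(2z)` with `z` the *exact* normal quantile at
`(1 + level)/2` (1.959964 at 95%). Using the exact quantile rather than
1.96 keeps the derived p-values self-consistent; users reproducing hand
calculations with a 3.92 divisor will see ≈0.1% drift in SEs, far below any
tolerance used here. A CI whose log-scale midpoint is more than 0.1 se away
from `ln HR` (usually a rounding artifact in the source table) triggers a
warning but is accepted: published rounding routinely breaks log-symmetry
and rejecting such rows would discard usable studies.

## Pooling, heterogeneity, model choice

Fixed-effect pooling is inverse-variance weighting; heterogeneity is
Cochran's `Q` about the fixed-effect mean with `df = k − 1`,
`I² = max(0, (Q − df)/Q)`, and the between-study variance is the
DerSimonian–Laird (DL) moment estimator `τ̂² = max(0, (Q − df)/C)`,
`C = Σw − Σw²/Σw`. DL was chosen over REML or Paule–Mandel because it is
the classic estimator of the era's standard meta-analysis software and it
reproduces the printed values of the reference analysis; the pooled CI uses
normal quantiles (no Knapp–Hartung small-sample adjustment) for the same
reason — the bundled table's printed CI 1.07–2.24 arises from `z`, not `t`,
quantiles. The `auto` model applies the heterogeneity gate: random effects
when `p_Q < 0.05`, fixed otherwise, applied independently within each
subgroup level. Single-study "pools" are returned as the study itself with
`Q = 0`, `df = 0`.

Known property of this stack, verified by simulation in the test suite: at
`k = 30`, `τ² = 0.3` the DL estimate of `τ²` is nearly unbiased (mean
within 10% of truth over 1000 replicates) but the 95% CI for μ undercovers
slightly (observed ≈92%, asserted band 90–97%) — the familiar DL behaviour
at high heterogeneity, accepted rather than corrected because matching the
classic estimator is the point.

## Meta-regression

Random-effects meta-regression uses the method-of-moments residual `τ²`
(the regression generalisation of DL): with fixed-effect weight matrix `W`
and `P = W − WX(X'WX)⁻¹X'W`, `τ̂² = max(0, (Q_E − (k − p))/tr P)`, followed
by WLS with weights `1/(v_i + τ̂²)` and normal z tests per coefficient. No
Knapp–Hartung adjustment is applied. Because reference analyses rarely
state their meta-regression variant, moderator p-values from other software
are treated as soft context, not as reproduction targets; the estimator is
validated instead by a simulation test (true slope 0.5 recovered within 3
Monte-Carlo SEs over 500 replicates of 40 studies).

## Publication-bias tests

Egger's test uses the classic 1997 parameterisation — OLS of the
standardized effect `y/se` on precision `1/se` with intercept; the
statistic is intercept/SE referred to `t(k−2)`. This is documented
explicitly because the equivalent weighted `y`-on-`se` formulation gives an
intercept of different scale and sign convention. Begg's test computes
Kendall's tau (tau-a; tied pairs excluded from both counts) between the
variance-stabilized deviations `u_i = (y_i − ȳ_fixed)/√(v_i − 1/Σw)` and
the variances, normalized as `z = (P − Q)/√(k(k−1)(2k+5)/18)` with the
Begg–Mazumdar continuity correction of one unit (a flag disables it). Both
tests hold their nominal type-I error within [0.02, 0.08] at α = 0.05 on
unbiased synthetic ensembles (1000 replicates, k = 50), asserted in the
suite. Funnel boundaries are pseudo-CI polylines `μ_fixed ± z(level)·se`
over an SE grid, with the apex at the fixed-effect mean.

## Network analysis

Edge filtering is strict (`score > threshold`) following the usual STRING
phrasing "combined score > 0.4"; the `>=` convention is available via a
flag. Degree, betweenness and closeness come from networkx: betweenness is
unnormalized Brandes pair counting (a brute-force all-simple-paths oracle
cross-checks it exhaustively on 4-node graphs and on random graphs up to 8
nodes), closeness is Freeman closeness within each connected component
(isolated nodes 0), matching CytoNCA-style handling of disconnected
graphs, which is otherwise ill-defined.

Hub screening: the cutoff `m` expands from `k` until the intersection of
the top-`m` nodes under all three centralities contains at least `k`
members; the intersection is ordered degree-desc, betweenness-desc, then
node name. The expanding-intersection rule is this package's own fixed,
deterministic interpretation of "hubs shared by all three centralities" —
published workflows rarely specify one.

MCODE follows the three published stages with the plugin's default
parameters (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut on,
fluff off): vertex weight = core-clustering coefficient of the closed
neighborhood (density of its innermost k-core) × that core's k; greedy
breadth-first expansion from the highest-weight unvisited seed, admitting
neighbors within `node_score_cutoff` of the seed weight; post-processing
discards complexes lacking a 2-core and the haircut trims to the 2-core.
Iteration order is everywhere deterministic (weight desc, then node name),
so module lists are reproducible. The module score is density × size
= `2E/(N−1)`. Recovery is validated on planted ground truth: three K₈
cliques in a G(200, 0.02) background are recovered at mean Jaccard ≥ 0.9
over 20 seeds (measured: 1.0).

## Enrichment

Over-representation uses the hypergeometric upper tail `P(X ≥ k)`
(verified against exhaustive enumeration for universes ≤ 15 and against
one-sided Fisher exact tests). Terms are filtered on *raw* p < 0.05 — the
criterion conventional DAVID-style analyses state — while BH q-values are
always reported alongside, so FDR control is available without silently
changing the filtering criterion. The default universe is the union of all
genes in the collection; an explicit background list overrides it. Symbols
are upper-cased and deduplicated at every boundary. The plain
hypergeometric (not DAVID's EASE-adjusted variant) is used; EASE would
subtract one from the overlap and is deliberately not emulated.

## Synthetic data

The generators produce every input the pipeline reads, with known ground
truth, and are pure functions of config + seed (bit-identical reruns,
asserted). Study tables: `θ_i ~ N(μ, τ²)`, `se_i ~ U(se_low, se_high)`,
`y_i ~ N(θ_i, se_i²)`, emitted as HR/95% CI rounded to 6 decimals — the
rounding deliberately exercises the reader's tolerance path and bounds
round-trip recovery at ~1e-5. The biased variant suppresses each
non-significant candidate (two-sided p above a threshold) with a given
probability, drawing suppression coins from a stream independent of the
study stream so that zero suppression reproduces the plain generator
exactly; generation is capped to fail loudly when suppression is hopeless.
Graphs: planted modules are wired to an exact internal edge count
(`round(density · C(s,2))`); background G(n, p) edges are placed only on
pairs that are not both planted-module members, so modules touch the rest
of the graph solely through the explicit sparse inter-module connections —
this keeps planted memberships a usable ground truth (unrestricted
background edges merge planted cliques into one detected module).
Edge scores are U(0.4, 1.0) inside modules and U(0.15, 0.9) elsewhere.
Annotation universes plant exact query overlaps into chosen terms and fill
the rest of the query from genes outside all planted terms, so non-planted
terms overlap at null rates.

What the simulations do *not* emulate: real survival-time generation
(censoring, proportional-hazards violations), correlated cohorts from a
shared publication, degree-sequence-preserving graph nulls, or GO term
ancestry. Passing the recovery tests therefore shows the estimators are
correct under their own assumptions, not that those assumptions hold in any
particular literature.

Null calibration of the enrichment test is asserted as a rejection-rate
bound (≤ 0.08 at α = 0.05) plus a median-p check rather than a
Kolmogorov–Smirnov uniformity test: the hypergeometric tail is discrete
and conservative (super-uniform), so a KS test against U(0,1) rejects for
any large pooled sample even when the test is perfectly valid.

## Problem sizes and numerical choices

The bundled analysis (11 studies) is instantaneous; simulation-backed
tests use 500–1000 replicates at k = 30–50 studies, 20 seeds of 200-node
graphs, and exhaustive enumeration only where the space is tiny (4-node
graphs, universes ≤ 15) — sizes chosen so the full suite completes in well
under a minute while keeping Monte-Carlo error far below the asserted
bands. Ties are broken lexicographically everywhere a ranking feeds a
decision. Degenerate inputs (k = 1 pools, empty graphs, edgeless modules,
zero-overlap terms) return the documented identities or raise early with a
named cause rather than propagating NaNs.

## Known limitations

The study table carries the source publication's printed values verbatim,
including a duplicated cohort label ("Cohort 1-serum" twice with different
N) that the source never resolves; and the two Deng cohorts are the same
72 patients assayed in tissue and serum, so the naive N-column sum
overstates the number of distinct cases (1524 vs 1452) — totals derived
from the table account for the overlap but the pooling itself, like the
reference analysis, treats all 11 rows as independent. Database-snapshot
quantities (node counts of a particular STRING export, specific hub-gene
identities, specific enriched pathways) depend on resources frozen at
retrieval time and are exercised via synthetic ground truth instead.
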