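# Methods

## The procedure being modelled

The pipeline reproduces a specific exploratory analysis pattern used in
dyshomeostasis research: treat the cross-correlation structure of a
multi-system physiological panel as a network, and ask whether two groups
(e.g., patients vs healthy controls) differ in how that network is wired —
at baseline, and in the per-subject response to an intervention. The
statistic throughout is Spearman's rank correlation, because physiological
and questionnaire variables routinely violate normality; the network
comparison is the Mann–Whitney U test over node-level topology metrics.

Two analyses are run per dataset:

- **Baseline networks**: Spearman networks of each group's pre-intervention
  values.
- **Delta networks**: networks of per-subject after − before changes.
  Variables not re-measured post-intervention in one group are carried
  forward from baseline (their raw baseline value enters the delta table,
  flagged), so the variable stays in the network rather than being dropped.

## Correlation and edge filtering

- **rho**: product-moment correlation of mid-ranks (average ranks on ties).
- **p-values**: two-sided. Default `auto` mode uses the t approximation
  `t = rho*sqrt((n-2)/(1-rho^2))` on `n-2` df for `n > 9` and exact
  enumeration of all `n!` permutations of one margin for `n <= 9`
  (threshold configurable; with ties the observed tied rank values are
  permuted, conditioning on both tie patterns). At `|rho| = 1` the
  t-approximation returns p = 0. The approximation's worst-case deviation
  from the exact p at n = 5 is ~0.08 — but in the region that decides
  edges at alpha = 0.05 (exact p below ~0.15) it stays within 0.05.
- **Edges**: `p < alpha`, default alpha 0.05, two-sided, no multiplicity
  correction — deliberately, because the reproduced procedure applies
  none; with 210 pairs this implies roughly 10 false-positive edges per
  null network, a property the calibration tests quantify rather than
  suppress.
- **Missing data**: pairwise deletion, per-pair `n_used` reported. A pair
  with undefined correlation (constant column, fewer than 3 complete
  pairs) is logged and recorded as missing, never an edge.

## Topology metrics (NetworkAnalyzer dialect)

All metrics are computed on the simple undirected unweighted graph; edge
signs and correlation strengths are annotations only. Conventions chosen
to keep every node comparable across groups:

- **degree** — incident edge count.
- **eccentricity** — max shortest-path distance within the node's
  connected component; isolated nodes 0.
- **stress** — number of geodesics between other node pairs passing
  through the node as interior vertex; each unordered (s, t) pair counts
  once per distinct geodesic. A flag exposes the doubled ordered-pairs
  convention used by some tools.
- **clustering coefficient** — realized fraction of edges among
  neighbours; 0 for degree < 2.
- **neighbourhood connectivity** — mean neighbour degree; 0 for isolated
  nodes.
- **topological coefficient** — for degree >= 2,
  `avg_m J(v,m) / degree(v)` over nodes m that share a neighbour with v
  *or are adjacent to it*; `J(v,m)` = common-neighbour count, plus 1 if m
  is adjacent to v. Degree < 2 gives 0. Including adjacent-but-no-shared-
  neighbour partners in the candidate set is required for the dialect's
  reference values (e.g., the middle of a 3-path scores 0.5, a K4 node
  scores 1); a stricter shared-neighbour-only reading would zero the
  3-path case.

Implementation is BFS with geodesic counting (`sigma(s,v)*sigma(v,t)`
accumulation over pairs with `d(s,v)+d(v,t)=d(s,t)`); the test suite
checks it exactly against an independent Floyd–Warshall +
geodesic-enumeration reference on every 5-node graph and hundreds of
random 6–12-node graphs.

## Group comparison

- **U** from pooled mid-ranks (equals pair counting with half-credit for
  ties); **Z** from the tie-corrected normal approximation with 0.5
  continuity correction; exact p by enumeration of all group assignments
  when `n1 + n2 <= 12`.
- **Effect size** `r = |Z|/sqrt(N)` with N = total node count of both
  networks, signed positive when group A's values run higher (direction
  from U vs its null mean, mean difference as tie-break). The N
  convention is recorded in the report metadata and provenance because
  published (p, r) pairs in this literature are not always recoverable
  from a single convention.
- **Node-inclusion policy**: all panel nodes by default, isolated ones
  carrying zero-valued metrics; a non-isolated-only policy is available
  and recorded, since it materially changes means on sparse networks.
- **Caveat (recorded in every report)**: node-level metric values within
  one network are not independent samples. The Mann–Whitney test itself is
  well calibrated on independent draws (measured ~5% rejection at
  alpha = 0.05), but comparing two *networks* inflates the null rejection
  rate to ~15–20% because a single random edge shifts many nodes' metrics
  at once. The package reproduces the field's procedure as practised and
  documents this inflation in its tests instead of correcting for it;
  p-values from `compare_networks` should be read as descriptive.

Baseline (raw-variable) group comparisons are routed per variable:
independent two-sample t-test iff both groups pass Shapiro–Wilk normality
and Levene's variance-homogeneity test at 0.05, otherwise Mann–Whitney;
all routing flags are exported. The standard assumption tests and the
t-test are delegated to scipy; the Mann–Whitney machinery is this
package's own (it must expose U, Z, exact mode and the tie/continuity
conventions exactly).

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: two groups
(default n = 32 and 18), paired before/after measurements, group-specific
Spearman correlation structure, and a five-category 21-variable panel.

- **Copula**: a latent multivariate normal with Pearson matrix
  `2*sin(pi*rho_s/6)` applied entrywise to the target Spearman matrix
  hits the Spearman target exactly in distribution (measured max error
  0.005 at n = 50,000; the ±0.02 calibration bound is part of the
  acceptance suite). Targets are specified on the Spearman scale because
  that is the pipeline's statistic.
- **PD repair**: eigenvalue clipping at 1e-8 with diagonal
  renormalization, iterated; failure reports the offending matrix. All
  built-in scenario matrices pass with Frobenius modification <= 0.03.
- **After-values**: `after = before + delta`, with delta drawn from its
  own correlation structure, shifted by per-variable effect means and
  scaled by the per-variable noise scale. Additive generation (rather than
  re-sampling the after-timepoint) guarantees subject-level deltas exist,
  which the delta-network stage consumes.
- **Marginals**: normal by default; an optional `exp` transform produces
  skewed positive marginals. Spearman structure is invariant to monotone
  transforms — itself a test.
- **What it does not emulate**: the study's actual marginal means/SDs and
  units, questionnaire item structure, measurement error correlated
  across timepoints, drop-out. Passing tests therefore certify the
  *machinery* (calibration, power, discrimination) under a clean
  Gaussian-copula world, not distributional realism of any clinical
  dataset.

### Built-in scenarios

- `null` — both groups independent variables. Used for type-I behaviour.
- `hub_vs_balanced` (n = 150 per group) — group A concentrates
  correlation on hubs: a two-level "spider" (hub ↔ five inner nodes at
  0.38, each inner ↔ one outer node at 0.38) plus a six-spoke star at
  0.52 (a weak 0.13 spoke–spoke correlation is the price of positive
  definiteness for five-plus spokes at ≥ 0.5). Group B spreads a moderate
  0.40 equicorrelation over all pairs, so its detected network is
  near-complete: eccentricity 1 and stress 0 everywhere — the polar
  opposite of hub concentration, and robust to the ~10 false-positive
  edges per network that alpha = 0.05 implies. Designs with several small
  disjoint components for B were rejected: false-positive edges chain
  small components into long paths and randomize the eccentricity
  contrast.
- `paper_like` (n = 32/18) — a qualitative reconstruction of the
  patient/control contrast from named relationships only (the underlying
  matrices were never published): patient-like group ties fatigue to
  baroreflex function, baroreflex to aortic stiffness and central systolic
  pressure to cognition with LF/HF isolated; control-like group ties
  fatigue to cognition and LF/HF to blood-pressure regulation. Delta
  structure: fatigue changes track baroreflex/stiffness changes in the
  patient-like group with a mild (−0.5 SD) mean fatigue reduction;
  fatigue–autonomic and negative TMT A–fatigue couplings in the
  control-like group, whose fatigue scales are marked unmeasured
  post-intervention (exercising the baseline-substitution rule).

## Problem sizes and determinism

Simulation-based checks use 50 seeds (scenario discrimination), 200 seeds
(edge-detection power), 300 seeds (null network rejection) and 1000 seeds
(edge false-positive rate) — sizes at which the binomial standard error is
comfortably below the asserted margins. All randomness flows through
`numpy.random.default_rng(seed)`; identical config + seed reproduces every
artifact byte-for-byte (the provenance file, which carries a timestamp, is
the only exception).

## Known limitations

- The network-level Mann–Whitney p-values inherit the dependence problem
  described above; a subject-level permutation test would be the
  statistically sound alternative but is out of scope because it is not
  the procedure being reproduced.
- Marginal Spearman thresholding cannot distinguish direct from mediated
  association; no partial-correlation or regularized inference is
  attempted.
- Exact Spearman p enumeration is factorial; the default auto threshold
  (n <= 9) keeps it affordable and the study-scale groups (n = 18, 32) use
  the t approximation.
- Force-directed layout and figure styling are rendering concerns; the
  exports carry every attribute a viewer needs (category, degree, metrics,
  signed rho) and stop there.
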