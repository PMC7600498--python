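# Methods

`catapanel` analyses *replicated check-all-that-apply (CATA)* data: a trained
panel of `J` assessors evaluates `P` products in `R = 2` replicate sessions,
and for each evaluation ticks the descriptors (out of `A`) that apply, with a
protocol bound of 2–5 citations per evaluation.  The data model is the dense
binary array `x[j, p, r, a] ∈ {0, 1}`; everything else in the package is a
reduction of this array.

## Per-panelist reproducibility indices

For panelist `j` and product `p` the two replicate citation sets are
cross-tabulated over the `A` descriptors into counts `n11` (ticked in both
replicates), `n10`, `n01`, `n00`, with margins `n1. = n11 + n10` and
`n.1 = n11 + n01`.  Averaging over the `n` products:

* `R = n⁻¹ Σ 2·n11 / (n1. + n.1)` — a Dice coefficient between the replicate
  sets; 1 iff the sets are identical and non-empty everywhere.
* `p11 = n⁻¹ Σ n11 / n1.` — the estimated probability of re-citing in
  replicate 2 a descriptor cited in replicate 1.
* `chi2` — the mean uncorrected Pearson statistic of the per-product 2×2
  table, `A (n11·n00 − n10·n01)² / (n1.·n0.·n.1·n.0)`.  Its maximum is the
  table total `A`; large values mean strong replicate association.

No Yates continuity correction is applied (pinned by tests).  Products whose
table is degenerate for an index (empty margins — impossible under the 2–5
protocol but representable in the data model) are dropped from that
panelist's average with a warning, and the per-index product count is
reported; a panelist with no usable product raises an error rather than
returning NaN.

## Outlier screening

Screening asks whether the *lowest* `R` / `p11` values are outliers (poor
reproducibility).  Three tests are computed each round:

* **Grubbs** — `G = (mean − min)/s`, p-value from the exact t-based tail
  bound `p = min(1, n·P(T_{n−2} > t))`, `t² = n(n−2)G²/((n−1)² − nG²)`.
* **Dixon** — the size-appropriate gap ratio (r10 for n 3–7, r11 8–10,
  r21 11–13, r22 14–30), p by piecewise-linear interpolation in the embedded
  published critical-value table (levels 0.01–0.10, anchored at (0, 1) and
  (1, 0)).  The interpolated p is approximate away from the tabulated band
  but exact in the decision-relevant 5% region (Monte-Carlo size ≈ 0.054 at
  n = 23).
* **Chi-square criterion** — `(min − mean)²/s²` against chi-square(1).  This
  classical criterion is strongly anticonservative for a sample extreme:
  p < 0.05 corresponds to |z| > 1.96, which the minimum of ~23 values
  exceeds in roughly 40% of perfectly homogeneous panels.

Because of that last point, the default *removal decision* requires Grubbs
**and** Dixon to agree (both p < α on the same index); the chi-square test is
reported alongside but does not trigger removal unless explicitly added to
`decision_tests`.  With the agreement rule the family-wise false-removal
probability of the whole screen (two correlated indices, two correlated
tests) stays near the nominal level (~7% measured under a homogeneous
simulated panel at α = 0.05), while a genuinely unreliable panelist
(simulated reliability 0.1 among 0.9 peers) is flagged essentially always.
Removal is one panelist per round — the lowest `R`, ties broken by lowest
`p11` — followed by re-testing, up to `max_removals` (default 2);
`simultaneous=True` removes every flagged extreme in one round instead.

The Table-3-style summary reports mean, sample standard deviation, min, max
and first quartile per index, Pearson correlations between indices, and a
Shapiro–Wilk normality p-value (the p-value convention is this package's
choice for the otherwise unlabelled normality row).

## Panel-level tests

**Cochran's Q** (delegated to statsmodels, with the all-blocks-constant case
returning Q = 0, p = 1 with a warning) is applied per descriptor:

* replicate effect — blocks are the `J × P` evaluations, treatments the two
  replicates; for k = 2 the statistic is exactly the uncorrected McNemar
  statistic;
* product effect — blocks are the `J × R` panelist-replicate pairs,
  treatments the products;
* a pooled "All attributes" row adds the attribute as a further blocking
  factor, the only construction that yields a single overall Q.

The pooled row should be read descriptively: the citation-count bound (2–5
ticks per evaluation) couples attribute responses within an evaluation, so
pooled blocks are not independent and the pooled test is conservative
(measured rejection ≪ 0.05 under the null simulator).  The per-attribute
tests, whose blocks are independent evaluations, are calibrated (measured
type-I error 0.059 at α = 0.05 over 2000 simulated attribute tests).

**Friedman's test** is implemented with the general tie-corrected form
`(k−1) Σ_j (R_j − b(k+1)/2)² / (Σ r² − bk(k+1)²/4)` on within-block average
ranks, df = k − 1; it accepts k = 2 and returns 0, p = 1 with a warning for
an all-tied matrix.  It is cross-checked in the tests against scipy (k ≥ 3)
and against *exact* exhaustive permutation distributions enumerated by
dynamic programming over column rank/count sums, compared with the mid-p
convention at block counts where the chi-square approximation is meant to
operate (measured agreement ≲ 0.015 at 60–100 blocks; at 4–5 blocks the
asymptotic p differs from any exact reference by up to ~0.4, which is a
property of the approximation, not of the implementation).

Per-product index averages (Table-5 shape) reuse the single-wine index
values averaged over panelists, with Friedman across products (blocks =
panelists) per index.

## Replicate distances and Sammon mapping

The per-replicate citation-count table (rows = product × replicate) is
treated as a correspondence table, and distances between rows are
chi-square row distances `sqrt(Σ_a (P_ia/r_i − P_i'a/r_i')²/c_a)`.
Zero-mass rows are dropped with a warning.

The Sammon mapping minimises
`E(Y) = (Σ δ)⁻¹ Σ_{i<j} (δ_ij − d_ij)²/δ_ij` by gradient descent from a
deterministic classical (Torgerson) MDS initialisation, with step-halving
whenever a step would increase the stress (up to 40 halvings per iteration,
step growth 1.2 on success) and a relative-improvement stopping tolerance of
1e−12.  The recorded stress trace is therefore non-increasing and the final
stress never exceeds the initialisation stress.  Exact zero target distances
off the diagonal are replaced by `1e−8 × max distance` so the stress stays
defined; coincident embedded points are protected by a denominator floor.
Distances generated from genuinely 2-D configurations are recovered to
stress < 1e−6 (classical MDS is already exact there and the descent only
polishes).

## Correspondence analysis

CA is computed from the SVD of the standardized residuals
`S = (P − r cᵀ) / sqrt(r cᵀ)` of the correspondence matrix `P = N/n`:
principal inertias are the squared singular values and sum exactly to the
total inertia `χ²/n`; principal coordinates are `diag(1/√r) U Σ` (rows) and
`diag(1/√c) V Σ` (columns); the symmetric map shows both in principal
coordinates.  Cell contributions to total inertia are `r_i c_j S_ij² /
inertia × 100` and sum to 100.  SVD sign indeterminacy is fixed by making
the largest-magnitude row coordinate of each dimension positive, so
coordinate fixtures are stable.  All-zero rows/columns are dropped with a
warning; a table whose inertia is ≤ 1e−12 is treated as exactly independent
(zero inertia, zero contributions, warning).  The chi-square test of the
table uses no continuity correction; it is computed on the averaged
citation-count table — CA itself is invariant to the global 1/R averaging
constant.

The CA attribute subset is the union over products of each product's top-3
most cited descriptors, plus any explicitly included descriptor (the hook
for a descriptor cited many times overall without entering any top 3),
minus exclusions, ordered by overall citation rank.  Ranked descriptor
lists break ties alphabetically.

## Consensus cluster count and cluster profiles

Products are clustered on the first three CA dimensions (dimension count is
a parameter).  The cluster count is chosen by vote over a grid of five
distance measures (Euclidean, Manhattan, maximum, Canberra, Minkowski with
configurable exponent, default 2) × six methods (k-means — paired only with
the Euclidean distance — ward.D, ward.D2, single, complete, average), each
solution for k in [2, 10] scored by silhouette (on the combination's own
distance), Calinski–Harabasz (on the coordinates; it is variance-based) and
the Dunn index (min inter-cluster distance / max intra-cluster diameter).
Each (distance, method, index) combination votes for its best k; the modal k
wins, ties resolved toward the smallest k — this package's documented,
reduced version of the 30-index battery of the reference approach, keeping
the "most combinations" aggregation rule.  R's `ward.D` (Ward update on raw
distances) is reproduced by feeding scipy's Ward linkage the square roots of
the distances, since scipy squares internally (equivalent to `ward.D2`).
Final memberships default to Ward (ward.D2) on Euclidean distances; labels
are renumbered by first appearance so they are deterministic.

Cluster odor profiles sum the citation counts of member products per
descriptor; Pearson residuals `(obs − exp)/sqrt(exp)` against the
margin-product expectation identify over/under-cited descriptors per cluster
(Table-7 shape), and the spider data are unweighted means over member
products of per-product citation proportions.

## Synthetic panels

The simulator provides ground truth for every stage:

* `theta[p, a] ∈ (0, 1)` — latent citation propensities, built as clustered
  profiles: each of `n_clusters` clusters owns a disjoint signature block of
  `A // n_clusters` descriptors at `base_rate + separation`, all else at
  `base_rate`; optional seeded jitter.
* replicate 1 — citation count `m ~ Uniform{2..5}`, then `m` descriptors by
  sequential weighted sampling without replacement with weights
  `theta[p]^λ_j` (λ is a per-panelist discrimination exponent, default 1).
* replicate 2 — *keep-then-refill*: each replicate-1 choice kept
  independently with probability `ρ_j` (the panelist's reliability), a fresh
  count `m'` drawn, surplus kept descriptors subsampled uniformly, deficits
  refilled by the same weighted sampling over unchosen descriptors.  ρ maps
  directly onto `p11`: `p11 ≈ ρ + (1 − ρ) × chance re-pick`.

Defaults describe a typical trained-panel wine-profiling design — 23
panelists, 17 products, 2 replicates, 25 attributes, 2–5 citations, 4
clusters — with `ρ = 0.25`, `base_rate = 0.08`,
`separation = 0.35`, chosen once so the simulated panel lands in the regime
a trained wine panel exhibits (mean p11 ≈ 0.3–0.4, citation proportions
~10–50%, a clearly significant product effect, a null replicate effect).
The exact draw order is documented in `simulate.py` so outputs are
bit-stable under a seed.

What the generator does **not** emulate: semantic correlation between
descriptors (beyond the count constraint), panelist fatigue, serving-order
or session effects, and any replicate-level drift.  Passing recovery tests
therefore show the pipeline recovers structure of this idealised kind; they
cannot certify behaviour under attribute co-occurrence or drift that real
panels may show.

## Problem sizes and numerical conventions

The test-suite simulations use full-scale panels (23×17×2×25) for the
screening checks (100 seeds per scenario), 20×12×2×25 panels for cluster
recovery (50 seeds), 250 small panels (12×4×2×8) for Cochran calibration
(2000 attribute-level tests), 100 random datasets for exact oracle
equivalence, and 500 random tables for CA invariants; the whole suite runs
in about a minute on one CPU.  Index means are computed with a single fixed
summation path so the vectorized implementation equals the brute-force
enumeration bit for bit.  CSV artifacts are written with a fixed `%.12g`
float format, making pipeline re-runs byte-identical under equal
configuration and seed.

## Known limitations

* Dixon p-values are table interpolations, accurate near the tabulated
  levels only; decisions at α far from 0.01–0.10 should use Grubbs.
* The pooled "All attributes" Cochran row is conservative under citation-
  count constraints (see above); per-descriptor tests are the calibrated
  ones.
* Chi-square outlier p-values follow the classical convention of the R
  `outliers` package and should not be used alone for screening decisions.
* The consensus battery is three validity indices, not thirty; with very
  weak cluster separation its vote can be diffuse, and the smallest-k tie
  rule then biases toward few clusters.
* CA requires a non-degenerate table; products never cited on the selected
  attribute subset are dropped with a warning and receive no cluster label.
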