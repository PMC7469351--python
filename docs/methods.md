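# Methods

## Model

The study space is a set of `m` regions with observed case counts `y_i` and
fixed baseline expected counts `μ_i⁰ > 0` (typically from indirect age–sex
standardization; `expected_counts` computes `μ_i⁰ = Σ_s pop_is · C_s / P_s`,
which conserves the total case count). Counts are modelled as independent
Poisson. Given `K` pairwise-disjoint connected windows `w_1..w_K`,

    log μ_i = α + Σ_k β_k z_ki + log μ_i⁰,

so regions in window `k` share the rate multiplier `θ_k = exp(α + β_k)` and
all other regions share `θ_out = exp(α)`. The design is saturated by group,
hence the MLE is closed form: `θ̂_k = O_k / E_k` and `θ̂_out = O_out / E_out`
(window totals of counts and expectations); the score equations — fitted
totals equal observed totals per group — hold exactly and are asserted in
the tests. Hot-spot windows should have `β_k > 0`; this is enforced by the
scan (only high-rate windows score above zero), not by the fitter, which
flags `β̂_k ≤ 0` with a warning so that misspecified candidates remain
diagnosable. A window with zero observed cases is fitted at the boundary
(`θ̂_k = 0`, `β̂_k = −∞`) rather than rejected. The log-likelihood always
includes the `log y_i!` terms so that criterion values are on one common
scale across `K` and against the null model — the relative statistic below
divides by the null criterion, so additive constants matter.

Baseline expectations enter strictly as a fixed offset; covariate modelling
inside `μ_i⁰` and overdispersion/spatial random effects are out of scope.
Regions with `μ_i⁰ = 0` make the likelihood undefined and are removed up
front (`drop_zero_expected`), reducing `m`.

## Scan statistic and candidate generation

Every window `w` is scored with the conditional Poisson scan statistic

    LLR(w) = O_w log(O_w/e_w) + (O−O_w) log((O−O_w)/(O−e_w)),  e_w = E_w·O/E,

zero unless the inside rate exceeds the outside rate. Conditioning on the
observed total (the `O/E` rescaling) is the standard convention for scan
statistics; it makes the statistic invariant to the overall rate level and
equal to the log-likelihood ratio of the one-cluster GLM against the null on
the same totals — an identity the test suite checks to 1e-10 and that holds
for any ratio of total observed to total expected.

Window families:

* **circular** (default): for each center region, the nested sets of its
  1st, 2nd, … nearest regions by centroid distance, capped at a fraction
  (default 0.5) of the total baseline expectation. Implemented as a
  precomputed distance-order matrix with cumulative sums, so one scan of an
  m = 324 map costs a few vectorized array operations; the Monte Carlo loops
  below rely on this.
* **flexible**: all connected subsets of each region's
  `neighbor_limit`-nearest neighbourhood (default 20) containing that
  region, enumerated by the standard branch-and-forbid recursion with an
  emission cap.
* **restricted**: the flexible family restricted to regions individually
  elevated against their baseline, using the one-sided Poisson mid-p
  `P(X > y_i) + ½P(X = y_i)` at mean `μ_i⁰` with threshold `alpha1`
  (default 0.2, the conventional choice). This prunes the enumeration
  drastically and is the practical choice for maps of hundreds of regions.

Candidates are produced by the sequential secondary-cluster procedure
(SCP): repeatedly take the most likely cluster among windows containing no
previously detected region, up to `kmax` (default 20) or until a
candidate's Monte Carlo p-value `p_s` exceeds `ps_threshold` (default 1.0,
i.e. keep everything; a candidate that crosses the threshold is dropped and
iteration stops). Previously detected regions are excluded from window
*membership*; their counts stay in the totals, keeping every iteration's
statistic comparable and the candidates pairwise disjoint. Per-candidate
`p_s` compares the candidate's LLR against one null distribution of the
*maximum* LLR over the full window family (the usual secondary-cluster
convention), so all `p_s` values share a single Monte Carlo sample. Ties in
the maximization resolve to the smaller window, then the lexicographically
smallest member-id list; distance ties in window construction and k-NN
adjacency resolve by region id — all outputs are bit-reproducible for fixed
seeds.

## Criterion and selection

Approximating −2 log marginal likelihood of the cluster model by Laplace
expansion and keeping terms of order O(1) and larger in `m` gives
`−2 l(ψ̂|z) − 2 log h(z) + (K+1) log m`, where `h(z)` is the probability of
the window placement. With small windows, `h(z) = (1/m)^K` (each window is
one of ~m placements), so

    C(K) = −2 l(ψ̂|z) + (3K + 1) log m   (K ≥ 1),
    C0   = −2 l(α̂₀) + log m,

the null case taking `q = 1` and an empty placement (`log h = 0`) — the
natural continuation of the formula at `K = 0`. Each window thus costs
`3 log m`: one `log m` for its rate parameter and two for its location.
Selection maximizes `RDC(K) = (C0 − C(K))/C0` over the nested prefixes of
the SCP ordering (candidates arrive in decreasing detection strength; an
exhaustive subset search is available behind a flag for small candidate
lists but is exponential). Ties go to the smaller `K`; `K̂ = 0` when no
prefix improves on the null. `C0 ≤ 0` would make the relative statistic
meaningless and aborts with a diagnostic; with full Poisson likelihoods on
real count data `C0` is far above zero. Windows fitted with `β̂_k ≤ 0`
remain in their prefix — the penalty handles them — but are logged.

The identity `C(K+1) − C(K) = 3 log m − 2·(log-likelihood gain)` is
asserted on every trace. For comparison the selection also emits −2 log L,
AIC (`−2l + 2q`) and BIC (`−2l + q log m`) traces; on data with many
candidate windows these keep decreasing with `K` while `C` turns at an
interior minimum — the qualitative trajectory pattern the acceptance suite
reproduces.

## Overall significance

The statistic of the overall test is `T = max_K RDC(K)`. Null datasets are
multinomial redistributions of the observed total with cell probabilities
`μ_i⁰/Σμ_j⁰` (conditioning on the total, as the scan itself does). Each
replicate regenerates candidates with the same scanning configuration —
with `ps_threshold = 1` and no inner Monte Carlo, since `T*` depends only
on the windows and the criterion; this removes a nested simulation loop and
makes the test cost `R` scans. Refitting the observed windows instead of
rescanning is available (`regenerate=False`) but rescanning is the default,
matching how the observed `T` was produced.
`p_M = (1 + #{T* ≥ T})/(R + 1)` lies on the grid `{r/(R+1)}`; because the
observed data under the null are exchangeable with the replicates, the test
is exact up to grid discreteness (ties count against rejection, so it errs
conservative). Replicates are seeded counter-style by index, so results are
independent of scheduling.

## Synthetic study design

The real national admission dataset behind the reference analysis is not
redistributable, so the simulation module reconstructs its quantitative
skeleton on a synthetic map: an 18×18 rook-adjacency lattice (m = 324, the
reference region count), five disjoint planted clusters A–E of sizes
(5, 7, 8, 8, 5) — 33 cluster regions — with baseline expectation totals
A 1941.88, B 772.14, C 760.88, D 437.49, E 598.06 and a study-area total of
333524.31, the remainder spread uniformly over background regions. Each
cluster's total is split equally among its members (the within-cluster
allocation is a package choice; only cluster totals are fixed by the
design). Scenarios S1–S7 set per-cluster relative risks: S1 all 1.0 (null),
S2/S3/S4 all clusters at 1.5/1.3/1.2, S5 mixed (1.6, 1.3, 1.4, 1.3, 1.2),
S6/S7 only cluster A at 1.3/1.2. Counts are independent Poisson with mean
`RR_i · μ_i⁰`. Clusters are grown by randomized breadth-first accretion
from separated seeds (minimum graph distance 2 between clusters).

What the generator does *not* emulate: the real map's irregular geography
and adjacency, heterogeneous region-level baselines within clusters, and
spatial correlation beyond the planted rate elevations. Passing tests
therefore demonstrate the procedure's behaviour under correctly specified
independent Poisson sampling on a regular map, not robustness to
overdispersion or misspecified baselines.

Detection quality is summarized region-wise over datasets whose result is
significant at the nominal level: sensitivity `|detected ∩ true|/|true|`
and PPV `|detected ∩ true|/|detected|` (undefined, reported missing, when
nothing is detected); clusters with RR = 1.0 do not count as true regions.
For the SCP arm, "significant" means at least one cluster with
`p_s ≤ level` and the detected set is the union of such clusters.

## Problem sizes and numerical choices

* Monte Carlo defaults in the simulation tools are R = 99 replications and
  100–200 datasets per scenario — an order of magnitude below a full
  journal-scale study (R = 9999, 1000 datasets); both are configurable.
  The acceptance script uses 200 null datasets with R = 99.
* The consistency and trajectory studies plant *ball-shaped* clusters
  (a region plus its rook neighbours) when the circular scan is under
  test: selection consistency presupposes that the true clusters lie in
  the scanned window family, and lattice distance balls are exactly the
  circular windows. Irregular (BFS-grown) clusters on a lattice get
  fragmented by circular windows into several candidates — visible as
  `K̂` exceeding the planted count with sensitivity near 1 — which is a
  property of the window family, not of the selection criterion; the
  flexibly shaped scan is the remedy on real maps.
* The trajectory fixture adds five moderate (RR 1.12) clusters behind
  three strong ones so that every candidate up to `kmax = 8` captures
  genuine structure, the regime in which conventional criteria keep
  decreasing while C turns; on pure noise the late candidates' gains sit
  near the AIC/BIC penalties and per-step monotonicity of BIC is a coin
  flip.
* Degenerate inputs: empty candidate lists give `K̂ = 0` with empty
  traces; windows covering the whole study area are inadmissible; a
  coincident-centroid tie never errors (id order decides); `x log x`
  terms at `x = 0` evaluate to 0.
* `float64` throughout; closed-form fits involve only logs of positive
  ratios; the criterion identity holds to ~1e-9 in the property tests.

## Known limitations

* Low-rate (cold-spot) windows are outside the model (`β_k > 0` intended);
  elliptic and space-time windows are not implemented.
* The unrestricted flexible enumeration is exponential in the
  neighbourhood size; beyond ~15 neighbours use the restricted variant.
* Per-cluster `p_s` values follow the secondary-cluster convention and are
  conservative for secondary clusters — that conservatism is precisely what
  the criterion-based selection is designed to repair.
* The criterion's location penalty assumes windows small relative to the
  study area; selections approaching the expectation cap stretch that
  approximation.
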