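# Methods

## Problem setting

The package targets short, replicated expression time courses: a handful of
unevenly spaced time points (the canonical design is 0.5, 1, 2, 4, 6 and
24 h) with a few biological replicates, expressed as paired
`x_igr = log2(treated/control)` ratios per gene *g*, time *i*, replicate *r*.
Series this short rule out classical time-series models — there are too few
observations per gene to estimate autoregressive or spline parameters — so
clustering must either work with pre-enumerated discrete shapes or with
summary descriptions of each curve. The package implements one method of
each kind plus the validity metrics needed to compare them.

Missing cells are tolerated anywhere as long as every gene keeps at least one
replicate at every retained time point; medians and median slopes are taken
over the available replicates. No across-array normalisation is performed or
offered: normalising across arrays perturbs the correlation structure across
time points that these methods rely on, so any normalisation is deliberately
left upstream. A generic quality filter is provided that drops a gene when
more than a configurable fraction (default 10%) of its measurements are
below detection or flagged as outliers; it abstracts two boolean flag
tensors (detected, outlier) rather than any scanner-specific flag semantics.

## Feature-based k-medoid clustering

Each gene's curve is reduced to a fixed vector of curve descriptors:

* **median slopes** `v_i = med_r (x_{i+1,gr} − x_{igr}) / (t_{i+1} − t_i)`
  on a baseline-augmented grid. Because paired treated/control samples are
  identical before treatment, the point (t = 0, x = 0) is prepended to every
  replicate series, so n observed time points yield n slopes and the initial
  response rate is captured. For a 6-point design this gives 12 features in
  total. The augmentation resolves an ambiguity in the feature count — the
  slope definition indexes the n − 1 inter-observation gaps, but the stated
  total of 12 features only holds once the baseline gap is included; the
  `include_baseline_slope=False` switch restores the 11-feature reading for
  sensitivity analysis.
* **max/min of the median profile** (log2 units) over the observed points
  (the implicit baseline is excluded from extrema),
* **times of the extrema** in clock hours (not rank indices), preserving the
  unequal spacing the slopes already use; ties break to the earliest time so
  extraction is deterministic,
* **steepest positive and negative median slope**, `max_i v_i` and
  `max_i(−v_i)` (so a monotone rising curve has a non-positive
  steepest-down value).

Features enter the clusterer unscaled with equal weight; Euclidean distance
mixes hours (0.5–24) with log2 units (≈ ±3), so the extremum-time features
dominate. That weighting is retained as the method's defined behaviour; a
`standardize=True` z-score switch exists for sensitivity analysis.

Vectors are partitioned around medoids (PAM): BUILD greedily seeds k medoids
minimising total point-to-medoid distance, SWAP applies the best strictly
improving (medoid, non-medoid) exchange until none exists. Single-exchange
local search can stall in non-global optima — on random 4–10-point instances
plain BUILD+SWAP misses the exhaustive-enumeration optimum in roughly 3% of
cases — so by default the SWAP phase is additionally restarted from 10
random medoid subsets drawn from a fixed seed and the lowest-objective
solution is kept. This keeps results deterministic (ties resolve to the
lowest row index, BUILD wins ties) while making the search exact on every
small instance we have enumerated; `n_restarts=0` restores the plain
algorithm.

**Choosing k.** The gap statistic compares `log W_k` of the PAM solution
with its expectation under B (default 100) reference data sets drawn
uniformly over each feature's observed range; constant columns are held
fixed. `W_k` is the PAM objective itself (total distance to medoid) rather
than Tibshirani's pairwise-sum dispersion, keeping the selection criterion
aligned with what the clusterer optimises. The stopping inequality is
`gap(k) > gap(k+1) − s_k` with `s_k = sd_b(log W*_kb)·sqrt(1+1/B)`
(a `tibshirani` rule switch gives the canonical `s_{k+1}` form). All
satisfying k are reported as elbow candidates — in practice several are
inspected side by side with homogeneity and silhouette — and the smallest is
the default choice. Note one consequence of the literal rule: any flat or
decreasing gap curve satisfies the inequality at *every* k, so "no
structure" manifests as the smallest satisfying k being 1, not as an empty
candidate set.

## Profile-grammar clustering

The comparator method clusters genes onto discrete candidate profiles.
With *c* units of change, all `(2c+1)^(n−1)` profiles anchored at 0 with
adjacent steps in {−c, …, c} are enumerated (guarded at 10⁷). From these, m
candidates are chosen by greedy farthest-point selection seeded with the
flat profile, approximately maximising the minimum pairwise distance of the
candidate set. Each gene's median profile is assigned to the candidate with
the smallest `1 − Pearson` distance; the correlation is location- and
scale-free, so no per-gene unit calibration is needed. Zero-variance
profiles are uncorrelated with everything by convention (distance 1), which
sends constant genes to the lowest-index candidate deterministically.

**Significance.** Each candidate's cluster size is compared with the count
it attracts when every gene's time order is independently shuffled
(replicates are collapsed to the median profile first). The p-value counts
the observed ordering among the permutations,
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, which makes the test exactly
valid (the naive fraction can return 0 and inflates the family-wise error
above the nominal level). Significance is Bonferroni-corrected over the m
candidates at α (default 0.05); note `n_perm` must exceed `m/α` for any
candidate to be able to reach significance. Every gene is assigned to some
profile but only profiles attracting significantly many genes are flagged,
so not every gene lies in a significant cluster.

## Validity metrics

* **Homogeneity** `H_ave = (1/P) Σ_i D(g_i, F(g_i))` — mean Euclidean
  distance of each point to its cluster centre, averaged over all points.
  The centre is the medoid in a k-medoid context and optionally the mean
  centroid for partitions from other methods. Values < 2 are read as good
  tightness, > 3 as poor (these bands are conventions for log2-ratio
  feature spaces, not universal thresholds).
* **Silhouette** `s(i) = (b − a)/max(a, b)` with a(i) the mean distance to
  the point's own cluster and b(i) the best alternative cluster; singleton
  clusters score 0 (Rousseeuw's convention), which matters for the tiny 3–6
  gene clusters these data produce. Averages > 0.5 indicate strong
  structure, 0.25–0.5 reasonable, < 0.25 none. Computed via
  scikit-learn's `silhouette_samples`, cross-checked in the tests against
  an explicit pairwise-loop oracle.
* **Rand index** — fraction of gene pairs co-clustered in both or separated
  in both partitions (scikit-learn `rand_score`). The plain index drifts
  towards 1 as cluster counts grow, so the adjusted Rand index is available
  wherever the plain one is; plain remains the default for comparability
  with the homogeneity/silhouette workflow.

## Synthetic data

The generator draws `x_igr = a_g · template(t_i) + ε_igr` with
`ε ~ N(0, noise_sd²)` on the log2 scale (Gaussian replicate noise is the
standard error model for log-ratio array data) and a per-gene amplitude
factor `a_g ~ U(0.75, 1.25)` by default. Template shapes emulate the
response patterns seen in radiation time-course studies — a biphasic
inflammatory/cytokine-like curve with early and 24 h peaks, a
DNA-damage-like 4 h peak, its mirrored repression, a slow late rise, and a
flat non-responder — with peak amplitudes near 2.5 log2 units, i.e. the
dynamic range of strongly responding transcripts. Shapes are qualitative;
no published measurement is treated as ground truth. Default replicate
noise is 0.3 log2 units, a realistic replicate scatter; 4 replicates and
the 6-point grid match the canonical design.

The default template set for recovery benchmarks is the four *response*
shapes. The flat template is deliberately excluded there: a non-responding
gene has no defined extremum times, so under any noise its t_max/t_min are
uniform draws over the grid and flat genes scatter in raw feature space —
they are not a separable class for this feature set (including them caps
recovery Rand at ≈ 0.96 even at noise 0.1). Flat is intended for null
experiments. A related artefact is worth knowing: a flat-only experiment's
*feature matrix* is not structure-free, because the noise-driven extremum
times are discrete (six grid values) and genuinely cluster better than a
continuous uniform reference, so the gap statistic reports structure there.
The generator emulates replicate noise and amplitude variation only — not
probe effects, missingness patterns, heavy-tailed outliers or correlated
noise across time — so recovery results bound what the methods can do under
idealised conditions; they do not certify performance on real arrays.

## Numerical and reproducibility choices

All stochastic operations (generator, gap references, permutations, PAM
restarts) take explicit seeds and are exactly reproducible; CLI outputs are
plain TSV/JSON with the seed recorded in the metadata. Tie-breaks are
deterministic throughout (lowest index / earliest time). `log W` is floored
at 1e−300 to keep degenerate zero-dispersion solutions finite. Swap
improvements must exceed 1e−12 to rule out cycling on ties.

Benchmark problem sizes (120-gene synthetic experiments, 200 brute-force
PAM instances, B = 50 gap references in the acceptance script, a few
hundred permutations per test) were chosen so the whole suite runs on a
laptop-class single core in well under a minute while keeping Monte-Carlo
error small relative to the margins being asserted.

## Known limitations

* The equal-weight, unscaled feature space makes Euclidean distances
  dominated by the hour-valued extremum times; that is the method's defined
  behaviour, but users clustering data on different time grids should
  consider the `standardize` switch and treat cluster counts as
  grid-dependent.
* The profile-grammar clusterer is a re-specification of the published
  approach (median-profile Pearson assignment, within-gene time-order
  permutation null), not a port of the original Java tool; exact numerical
  parity with that tool is out of scope.
* PAM with restarts is exact on all small instances we enumerated but
  remains a heuristic; global optimality is not guaranteed at scale.
* The gap statistic's uniform reference is the simplest variant; the
  PCA-rotated reference is not implemented.
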