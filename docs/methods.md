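# Methods

## The analysis problem

Structural covariance networks (SCNs) describe how inter-individual
variation in regional brain morphometry co-varies between regions: if two
cortical areas grow or atrophy together across a cohort, the cross-subject
correlation of their grey-matter volumes (GMV) is high, and the pair is
treated as an edge of a group-level network. `scnkit` implements the full
group-comparison workflow used in clinical SCN studies of an atlas with 90
cerebral regions (AAL-style parcellation): two cohorts (patients vs.
matched controls, typically a few dozen subjects each) each yield **one**
network, and topological differences between the two networks are tested by
permutation.

## Pipeline

1. **Demographics.** Continuous variables are compared with the Student
   pooled-variance two-sample t-test (df = n1 + n2 − 2); the sex composition
   with the Pearson chi-square on the 2×2 table **without** continuity
   correction. The uncorrected statistic is used because it is what standard
   clinical statistics packages report by default in this literature; on the
   bundled 24-patient spinal-cord-injury cohort (22 M / 2 F) versus its
   26-subject control arm (24 M / 2 F) it evaluates to 0.007. A
   Kolmogorov–Smirnov normality check is available as an advisory only and
   never switches the test.
2. **Confound regression.** Each region's volume is regressed on
   [1, age, gender] by OLS, pooled across *all* subjects (both groups in
   one fit). Per-group fitting would remove group-mean structure
   inconsistently before network construction; a caller can still pass any
   covariate list. The residual matrix (subjects × 90) is the input to
   everything downstream.
3. **Covariance networks.** Within each group, the 90×90 Pearson
   correlation matrix of residual volumes across subjects; diagonal zeroed.
4. **Proportional thresholding.** At sparsity S the K = round(S·N(N−1)/2)
   edges with largest |r| are kept and binarized (round = half-up;
   floor available as a config option since the convention is not
   universal). The default grid is S = 0.05 … 0.50 in steps of 0.01 — 46
   levels; for N = 90 that is 200 … 2003 of 4005 candidate edges. Ties in
   |r| are broken by ascending (i, j) pair order, making the whole series a
   deterministic, *nested* family of graphs. Edge sign is discarded; no
   significance filtering of correlations is applied before thresholding.
5. **Graph metrics.** Global: mean Watts–Strogatz clustering coefficient
   Cp; characteristic path length Lp; global efficiency Eglob and network
   local efficiency Eloc (Latora–Marchiori); small-world index
   σ = (Cp/⟨Cp_null⟩)/(Lp/⟨Lp_null⟩) against degree-preserving
   (Maslov–Sneppen double-edge-swap) nulls, 100 nulls and 10·E swap
   attempts by default. Nodal: degree, nodal efficiency, betweenness
   centrality (Brandes; each unordered pair counted once; unnormalized by
   default — group contrasts are invariant to the (N−1)(N−2)/2 factor).
6. **AUC permutation inference.** Each metric curve over the 46 levels is
   reduced to its trapezoid area (AUC). Group difference = AUC(group 1) −
   AUC(group 2). In each of R permutation cycles (R = 5000 by default) the
   confound-adjusted residual *rows* are reshuffled between groups at the
   original sizes — the confound fit is not redone, since it is the adjusted
   regional values that are exchanged — and both networks, graph series and
   AUCs are recomputed from scratch. p = (#{|null| ≥ |observed|} + 1)/(R+1),
   two-tailed. Nodal metrics are corrected by Benjamini–Hochberg FDR within
   each metric's 90-node family; global metrics are reported unadjusted at
   α = 0.05.
7. **Clinical association.** Partial correlation between a region's raw
   volume and a clinical score controlling age and gender: Pearson r of the
   two OLS residual vectors, t = r·√(df/(1−r²)), df = n − 2 − k, computed
   within the patient group. P-values across an ROI × variable grid are
   reported unadjusted, mirroring how such grids are reported in this
   literature.

### Numerical choices

- Shortest paths are level-synchronous BFS expressed as matrix products,
  evaluated for the whole 46-level nested stack in one batch; frontier
  products use float32 (exact for the small integer counts involved) and
  all reductions are float64, so every metric agrees with an independent
  graph library to ≤1e-10.
- Disconnected graphs are inevitable at S = 0.05; Lp is then the mean over
  *reachable* ordered pairs (logged), rather than infinite, so the AUC over
  the sparsity range stays finite. Efficiencies count unreachable pairs as
  zero contribution.
- σ is undefined when the rewired nulls have zero clustering (possible only
  on very small, very sparse graphs); the value is reported as `inf`/`nan`
  rather than silently clamped.
- Permutations that produce a constant ROI column in a permuted group
  (measure-zero for continuous data) are resampled and logged.
- All randomness flows through explicit `numpy.random.Generator` objects;
  the pipeline derives per-stage seeds from the master seed by counter, so
  a rerun with the same config + seed is byte-identical.

## Synthetic cohort generator

No subject-level imaging data are distributable with the package, so every
stage is exercised on a generator whose ground truth is known exactly.
Regional volumes follow a linear factor model:

v_ij = μ_j + β_age·(age_i − mean age) + β_gender·gender_i
       + Σ_f λ_jf(group_i)·z_if + μ_bg,j·z_bg,i + δ_j·[patient, atrophy ROI]
       + ε_ij

with z, z_bg, ε independent standard normals (ε scaled by `noise_sd`).

- **Design defaults** mirror the study design the pipeline targets:
  24 patients vs. 26 controls, 90 regions, ages uniform on [20, 60] years,
  92% male. The sex vector is redrawn until both levels appear in each arm,
  emulating sex-matched recruitment (and keeping the confound design full
  rank); the marginal male fraction is otherwise unchanged.
- **Modular covariance**: 6 equal blocks of 15 regions, block loading
  λ = 0.5, noise sd 0.7. Each region additionally loads on one shared
  background factor with strength drawn once per cohort from U(0.2, 0.6).
  The background factor matters: with exact-zero between-block
  correlations, the thousands of cross-block edges are statistical ties
  under proportional thresholding and nodal degree becomes dominated by
  tie-breaking noise that does not shrink with sample size — a regime no
  empirical grey-matter covariance matrix is in. With the graded background
  spectrum, within-block pairs correlate at ≈0.4–0.55 and cross-block pairs
  at ≈0.05–0.35, in the range reported for inter-regional GMV covariance,
  and edge rank is a stable property of a region pair.
- **Planted group effects**: a mean decrement δ = −0.5 (≈0.7 noise sd) on 3
  "atrophy" regions; a loading increment +0.4 on 10 designated regions of
  the first block, patients only (a covariance change invisible to
  mean-based tests); and a clinical score
  score = ρ·standardize(confound-free target signal) + √(1−ρ²)·noise with
  ρ = −0.5 against one atrophy region, so the expected age/gender-adjusted
  correlation equals ρ by construction.
- `null_cohort` zeroes both group-specific effects, making the two arms
  exchangeable draws from one distribution — the substrate for
  type-I-error calibration.

### What the generator does and does not emulate

It reproduces the *data structure* the pipeline assumes — two groups,
modular covariance, linear confounds, a covariance-only group difference, a
planted adjusted correlation — with known ground truth. It does not emulate
spatial autocorrelation of real parcellations, non-Gaussian volume
distributions, site/scanner effects, or total-intracranial-volume scaling
(no TIV adjustment is applied anywhere; the confound list is a config
extension point). Passing tests therefore demonstrate correctness and
calibration of the machinery, not field validity on any particular
clinical dataset.

## Problem sizes used in the test suite and reproduction script

The shipped studies use sizes chosen to make the full suite a
routine desk run while keeping Monte-Carlo error well inside the asserted
margins: type-I-error calibration uses 200 null cohorts × R = 200 in the
tests (100 × 100 in the reproduction script) against the exact binomial
interval; planted-correlation recovery uses 500 replicates;
perturbation-detection uses 50 replicates × R = 1000; oracle equivalence
uses 100 (tests) / 50 (script) random graphs. A production analysis would
use the R = 5000 default.

## Known limitations

- **Per-node covariance-perturbation detection at small n is underpowered
  by construction.** With the add-one permutation p, the smallest
  attainable p at R repetitions is 1/(R+1); after BH correction over the
  90-node family the smallest attainable q for a single node is
  90/(R+1) — 0.090 at R = 1000, 0.018 at R = 5000. Detecting a nodal
  effect at q < 0.05 with R = 1000 therefore requires two or more nodes
  simultaneously at the permutation floor. At n = 24/26 the sampling noise
  of a per-node degree-AUC difference (null sd ≈ 5 AUC units) is of the
  same order as the largest effect a within-module loading increment of
  +0.4 can produce even asymptotically (≈8 AUC units), so per-node z
  rarely exceeds ~2 and the power-study test documents this honestly
  rather than passing. Global-metric tests and the planted-correlation
  recovery are unaffected.
- Small-world σ is compared against degree-preserving rewired nulls only;
  lattice-referenced variants (ω) are not implemented.
- Weighted or directed network variants, Fisher z-transformation,
  modularity/rich-club analyses and bootstrap confidence intervals are out
  of scope.
- The permutation loop is serial; the counter-derived seed scheme is in
  place so a parallel executor would give worker-count-independent results,
  but none is shipped.
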