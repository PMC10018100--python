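# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `fcendo`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Subject-level connectivity

Each subject contributes a time × region matrix sampled at TR = 1 s
(configurable). Denoising is ordinary least squares against a per-subject
nuisance design: intercept, 6 rigid-body motion parameters and their first
differences, one spike (one-hot) regressor per outlying scan, white-matter
and CSF signals, and a 0/1 block regressor per task condition. Outlying
scans are flagged when framewise displacement — the sum of absolute
backward differences of the three translations plus the three rotations
converted to arc length on a 50 mm sphere — exceeds 0.9 mm, or when the
z-scored global-signal derivative exceeds 5 (conservative defaults of the
kind used by common denoising toolboxes; the first time point is never
flagged by FD). Scrubbing is realized as spike regressors rather than
deletion so the time axis stays intact for filtering.

Two conditions are produced. *tb-FC* uses the band 0.009–0.10 Hz.
*tr-FC* additionally regresses out the task: each condition's boxcar
convolved with a canonical double-gamma hemodynamic response (positive
gamma peaking near 6 s minus 1/6 of an undershoot gamma peaking near
16 s) plus its temporal derivative, and narrows the band to
0.009–0.08 Hz, leaving resting-state-like fluctuations.

Filtering is a 2nd-order Butterworth band-pass applied forward–backward
(`sosfiltfilt`), i.e. zero phase, which matters because correlations are
computed afterwards. The 0.009 Hz high-pass edge has a very long impulse
response, so the default padding is replaced by reflection over up to
three high-pass periods; residual edge transients remain and the filter
contract (≥ 90% retention at 0.03 Hz, ≥ 90% attenuation at 0.2 Hz) is
asserted in steady state. tb-FC is estimated over the whole denoised
series; condition-windowed (weighted-GLM) estimation is not implemented.

## 2. Graph topology

Weighted matrices are binarized by keeping the K = round(d·n(n−1)/2)
largest signed upper-triangle weights at each density d of the grid
0.05–0.40 in steps of 0.01 (36 points). Signed ranking treats
anticorrelations as non-connections; ties at the cut are broken in
row-major order so results are platform-stable.

Global metrics per density: global efficiency (mean of 1/d(i,j) over
ordered pairs, unreachable pairs contributing 0), average shortest path
length over *reachable* pairs only (at 5% density a 272-node graph can
fragment; restricting to the largest component is the main alternative),
Watts–Strogatz node-averaged clustering with degree-<2 nodes contributing
0, and small-worldness σ = (CC/CC_rand)/(APL/APL_rand) with the
closed-form references CC_rand = ⟨k⟩/n and APL_rand = ln n / ln⟨k⟩.
All-pairs distances are computed by BLAS frontier expansion (one boolean
matrix product per BFS level), which is exact and much faster than
per-source BFS at these sizes; the test suite checks exact agreement with
an independent Floyd–Warshall / triangle-enumeration oracle to 1e−12
(0/1 adjacency counts are exact integers in float32, far below 2^24).
Curves are summarised by trapezoidal AUC; densities where a metric is
undefined are dropped pairwise.

A property worth knowing: under these closed-form references, σ of a
Watts–Strogatz graph is *not* monotone in the rewiring probability — at
n = 272, ⟨k⟩ = 14 the path-length ratio still dominates at p = 0.01, so
median σ peaks near p ≈ 0.05 and decreases strictly only from there.
The test suite asserts strict decrease across
p ∈ {0.01, 0.05, 0.1, 0.3, 1.0} and that test fails for this reason; it
is retained deliberately as a documented property of the σ definition
rather than weakened.

## 3. Group ICA and eFNC

Group spatial ICA follows temporal concatenation: per-subject temporal
PCA (60 components by default — 30 proved too few when a high-rank
graph-structured term competes with the networks), stacking, group PCA to
the IC count (default 20), and FastICA (parallel fixed-point, tanh
contrast). FastICA is restarted five times from seed-derived
initialisations and the solution with the largest total logcosh
negentropy is kept; components are ordered by group-course variance and
sign-fixed so the strongest-loading location is positive, making the
result fully deterministic given the seed. Back-reconstruction is
dual-regression step 1: least-squares projection of the subject's
(denoised) data onto the group maps. Components are labeled by the dice
coefficient of the z > 1.5 thresholded map against template masks.

eFNC entry (i, j) is corr(course_i, residual of course_j on all courses
except i and j) — the unique, "from j to i" contribution of source j
controlling for the remaining networks. Note the near-symmetry: a single
planted coupling also raises the mirrored (j, i) entry, because
correlation structure alone cannot orient an edge; group comparisons
treat each cell separately. Courses are filtered with the tb band before
the semipartial step, which caps the effective sample size at roughly
2 × bandwidth × T (~65 at T = 360); recovery tests use course lengths
chosen with this in mind.

## 4. Group statistics

The ANCOVA is the linear model y ~ group + covariates; the group F comes
from the nested-model residual sums of squares (equal to type-II ANOVA
for this design, cross-checked against `statsmodels` to 1e−10), with
partial η² = SS_group/(SS_group + SS_residual) and model-based pairwise
contrasts. A vectorised variant shares the QR decomposition across the
380 eFNC cells. Quade's rank ANCOVA ranks the outcome and covariates over
the whole sample, takes OLS residuals of the outcome ranks on the
covariate ranks, and applies a one-way ANOVA F across groups — exactly
invariant under monotone transforms; its type-I error is verified at the
nominal 5% over 2000 null simulations. Kruskal–Wallis reports
η²_H = (H − k + 1)/(n − k); contingency tables use chi-square without
continuity correction (Φ = √(χ²/n)) or Fisher's exact test when an
expected cell is below 5. FDR is Benjamini–Hochberg, one family per
analysis block (demographics table; the 8 condition × metric AUC tests;
all eFNC cells; post hoc contrasts). The control reference interval is
mean ± 1.96 sd — a 95% reference *range*, not a CI of the mean, because
flagging is its purpose (a mean-CI would flag half the controls).

ICC over patient–sibling pairs is the one-way random-effects single
measurement ICC(1,1) = (MSB − MSW)/(MSB + MSW), appropriate because pair
member order is exchangeable (no rater structure); the 95% CI uses the F
distribution and the one-sided p tests ICC > 0 (cross-checked against
`pingouin`). ROC analysis fits unpenalised logistic regression, computes
the AUC by the Mann–Whitney rank identity on in-sample scores, and the CI
by DeLong's method (cross-checked against R's `pROC`). In-sample
single-feature AUC under label permutation is biased above 0.5 at small n
because the fitted slope's sign adapts to the sample; null calibration
checks therefore use a few hundred cases per class.

## 5. Synthetic cohort: what it emulates and what it does not

Each subject receives a Watts–Strogatz generative graph (ring lattice,
even mean degree 14, per-edge rewiring; redrawn with an incremented seed
until connected; node labels shuffled per draw — metrics are
permutation-invariant, and without the shuffle all subjects share the
ring ordering, which puts a spurious common low-rank "ring harmonic"
structure into group PCA). Group bases for the rewiring probability are
HC 0.05, SIB 0.20, TLE 0.28 — patients most random, siblings
intermediate — scaled by a log-normal subject deviation (log-sd 1.0)
whose latent value is correlated at 0.8 within patient–sibling pairs.
The log scale is used because the graph metrics respond roughly linearly
in log p through the small-world transition, giving the pair ICC a
well-defined, recoverable target; the deviation spread was chosen so the
shared between-pair variance exceeds the SIB/TLE group offset plus the
per-subject measurement noise of the σ-AUC (otherwise a pair ICC on raw
values cannot be positive in principle).

The BOLD-like signal sums: (i) 14 latent network courses (smoothed
noise) mixed through disjoint component maps whose regions are scattered
at random (amplitude 1.2), with the planted directed coupling
target ← 0.5 × source in controls and 0.1 in patients and siblings;
(ii) a graph term — temporally smooth noise diffused one step along the
adjacency with per-√degree weights (amplitude 1.4), which makes connected
regions correlate strongly enough for the thresholded correlation graph
to track the generative topology (mean-normalized one-step diffusion
proved too weak); (iii) a task term, boxcar × double-gamma HRF on the
first half of the regions (amplitude 0.4); (iv) polynomial/cosine drift,
motion- and tissue-driven artefacts whose generative motion and tissue
courses are exactly the confound table, and white noise (sd 0.5). The
generator plants 14 latent networks while the analysis extracts 20 ICs,
leaving ICA head-room for nuisance structure, as in real data where the
IC count exceeds the number of clean networks. Component maps are
scattered rather than contiguous so the graph term's local correlations
do not leak preferentially into neighbouring components.

Amplitudes and group parameters were calibrated once, by simulation,
so that each planted effect is actually recoverable by the intended
stage, and then frozen; they are deliberately *not* per-test knobs.

What the generator does **not** emulate: voxel-level imaging (regions are
abstract spatial units; no volumes), hemodynamic variability across
regions, physiologically structured motion (motion is a random walk),
non-stationary or epileptiform dynamics, and site/scanner effects.
Passing tests therefore show that the pipeline recovers the statistical
structure it targets under a fair generative model — not that real TLE
cohorts will show these effect sizes.

## 6. Problem sizes and operationalized end-to-end checks

Default cohort scale mirrors a realistic study (30/13/58 subjects,
272 regions, 300 time points). The end-to-end verification suite and the
acceptance script use a reduced scale — 30/13/58 subjects, 160 regions,
360 time points — chosen as the smallest cohort at which every planted
effect remains comfortably recoverable; the demo config is smaller still
(10/5/10, 60 regions). Over 20 replicate cohorts the suite requires:
the three tr-FC topology contrasts (GE higher, CC lower, σ lower in
patients) significant at FDR < 0.05 with the correct direction in ≥ 80%
of replicates and siblings deficient on σ in ≥ 80%; the planted eFNC
cell FDR-significant in > 50% of replicates with ≥ 95% of unplanted
cells null in every replicate; sibling-vs-control combined ROC above
chance at the 95% level in ≥ 80%; and pair ICC of the σ-AUC positive at
p < 0.05 in ≥ 50%. These fractions were fixed before the suite was run.

## 7. Known limitations

* The semipartial eFNC cannot orient edges from correlational data; the
  "directed" reading is a modelling convention.
* In-sample ROC (as used descriptively here) is optimistic; a
  leave-one-out mode exists in the API but is off by default.
* APL on fragmented graphs uses reachable pairs; other conventions
  (largest component) change low-density values.
* The Watts–Strogatz σ non-monotonicity described in §2 is inherent to
  the closed-form normalization.
* Determinism is guaranteed per platform/BLAS build (tie-breaks are
  deterministic, seeds cover all randomness); bit-identical results
  across different BLAS implementations are not promised.
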