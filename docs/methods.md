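# Methods notes

This document records the modeling and numerical choices behind
`dynmod`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Windowed connectivity

Edges are weighted Pearson correlations with the taper as observation
weights (weighted means, weighted covariance, weighted variances),
Fisher z-transformed (arctanh) with correlations clipped to
±(1 − 1e-7) before the transform.  The default taper is a rectangular
window convolved with a Gaussian of σ = 3 time points, truncated to the
window and max-normalized; a uniform taper reduces every window to
plain Pearson correlation and is used for the static (full-scan)
network.  Window geometry is 0-based and half-open: starts at
0, s, 2s, …; a window that would run past the series end is not
emitted, so the count is floor((T − L)/s) + 1.  With L = 156 and
s = 10 this yields 70 windows for an effective series of 846 time
points; for other T the count follows the formula rather than being
forced.  No detrending or filtering happens inside the package —
inputs are assumed pre-processed (band-passed, nuisance-regressed)
upstream.  A node that is constant within a window gets zero-weight
edges and a logged warning rather than NaNs.

## Signed modularity and Louvain

Fisher-z matrices contain negative edges, and the treatment of negative
weight in modularity is a genuine design choice.  The default is the
signed *asymmetric* quality

Q* = Q⁺ − (v⁻ / (v⁺ + v⁻)) Q⁻,

where Q± are resolution-parameterized Newman–Girvan terms computed on
the positive/negative parts separately and v± their total weights.
Positive within-module weight is rewarded at full strength; negative
within-module weight is penalized in proportion to its share of total
weight.  Note the sign convention this implies: on a purely negative
matrix a perfect "anti-community" partition (no negative weight inside
any module) scores *positive*, because the penalized term is entirely
avoided.  Two alternatives are selectable per call and recorded in
output manifests: `positive-only` (negative edges zeroed) and `plain`
(Newman formula applied to the raw signed matrix).  All sums include
the i = j null terms, so Q of the all-in-one partition equals
1 − Σk_i²/(2m)² on non-negative graphs.

Optimization is Louvain on the full modularity matrix B (so the same
code path serves all three variants): greedy sweeps in seed-shuffled
node order accepting moves with gain > 1e-10, then aggregation of B by
the community indicator, repeated until no aggregation shrinks the
graph (hard cap 100 passes).  Determinism: the sweep order is the only
stochastic element and is driven by a per-run seed; `best_partition`
runs seeds base…base+n_runs−1 and breaks quality ties by the lowest
seed.  Module ids are canonicalized by first appearance in node order
so serialized partitions compare bytewise.

On graphs small enough to enumerate (≤ 8 nodes), 100 restarts reach the
exhaustive optimum essentially always (the acceptance suite requires
≥ 99/100 instances).

## Resolution selection

The γ grid is 0.1…6.0 in steps of 0.1 (60 levels), rounded to one
decimal to avoid float drift.  Agreement between a subject's static
partition and the 17-network reference is mutual information in nats;
the default is *normalized* MI (arithmetic-mean-of-entropies
denominator) because raw MI grows with module count across a 60-level
sweep and would bias the argmax toward high γ; raw MI is available by
flag.  The 0/0 case of NMI is defined as 1 when both partitions are
single-module and 0 otherwise.  Ties along the agreement curve resolve
to the smallest γ.  Grid positions can be addressed either by γ value
or by explicit 0-based index (`GammaGrid.at_index`); the two are never
guessed from each other.

## Temporal dynamics and states

SD(Q) is the sample standard deviation (n−1 denominator) of the
window-wise Q values; the denominator convention is a package choice.
Extreme states use strict inequalities: Q strictly above M(1+f) or
strictly below M(1−f), f = 0.5 by default; a window exactly at a
threshold is not a state.  Under the individual convention M is the
subject's own trace mean, so counts are invariant to positive rescaling
of the trace.  Under the group convention M is computed by averaging
Q across subjects first and then across windows — the two-step order is
preserved even though it coincides with the grand mean for equal-length
traces.  Note that with f = 0.5 a group mean of 0.29 implies thresholds
0.435/0.145; threshold pairs like 0.36/0.22 correspond to f ≈ 0.24, not
0.5 — the package always derives thresholds from (M, f) and never takes
them as independent inputs.  The threshold sensitivity sweep evaluates
a fraction ladder (e.g. 0.05…0.95) and returns a long-format table;
counts are necessarily monotone in the fraction.

State-conditioned connectivity profiles pool windows across subjects:
element-wise means over all high-state and all low-state windows, their
difference, and a 7×7 network aggregation averaging each of the 28
unordered network-pair blocks (hemispheres merged, diagonal cells
excluded).

## Coclassification

The stability matrix is the time average of binary per-window
coclassification matrices, so every entry is an integer count divided
by the number of windows.  Network-specific stability averages the
entries of each of the 28 network-pair blocks; within-network blocks
exclude the self-pair diagonal (a node is trivially coclassified with
itself, and including it would inflate within-network scores — the
score is about connections).  The choice is switchable
(`include_diagonal=True`).  With diagonals excluded, the block-size-
weighted mean of the 28 scores exactly equals the off-diagonal grand
mean of the matrix (conservation, tested).

## Statistics

Partial Spearman: residualize x and y on the covariates plus intercept
by OLS, rank the residuals (average ranks on ties), Pearson-correlate
the ranks.  Residualize-then-rank is the default because the study's
residual scatterplots are of raw variables; rank-then-residualize is
available by flag (`rank_first=True`) and is the variant for which
invariance under monotone transforms holds exactly with covariates
present.  Two-sided p-values use the t approximation with
df = n − 2 − k, charging one degree of freedom per covariate; the
calibration test keeps the type-I error within [0.03, 0.07] at
α = 0.05, n = 100, k = 4.  Constant covariates (e.g. handedness in a
small all-right-handed cohort) are dropped with a warning before
residualization; genuinely collinear designs are an error.

Mann–Whitney contrasts report U, a tie-corrected normal-approximation
z (no continuity correction), and a p-value from exact enumeration when
n_a·n_b ≤ 400 with no ties, else from the normal approximation.  The z
sign follows the group order given (first group low ⇒ negative z).

Bonferroni over the 28 network scores gives 0.05/28 ≈ 0.0018
(reported at full precision and rounded to 4 decimals).

## Synthetic cohort generator

Each subject's signal is a latent block-factor model: unit-variance
global, per-module and per-node Gaussian factors combined so that
same-module nodes correlate at w (`base_within_cov`, default 0.6) and
different-module nodes at the time-varying coupling b(t)
(`base_between_cov` = 0.15 at rest).  b(t) is a sinusoid of period 200
time points (slow relative to the 156-point default window, so windows
resolve it) with subject-random phase and a per-subject amplitude drawn
uniformly from `stability_range` (default 0–0.15); b(t) is clipped to
[0, w).  High coupling mimics integrated (low-modularity) epochs, low
coupling segregated (high-modularity) epochs, so a larger planted
amplitude yields a larger downstream SD(Q).  A variance-preserving
AR(1) filter (coefficient 0.3) adds BOLD-like smoothness, and white
observation noise of SD `noise_sd` (default 0.5) is added last.
Defaults are 114 nodes in 7 planted modules aligned with the seven
canonical networks (the 17-network refinement splits each module's
block over its child systems, halves as hemispheres), 884 time points
at TR = 0.645 s.

The phenotype is IQ-scaled: fsiq = 100 + 15·(slope·z_amp +
noise_sd·ε)/√(slope² + noise_sd²), clipped to [55, 145], where z_amp
standardizes the amplitude by its theoretical uniform moments.  The
planted amplitude–phenotype Spearman correlation is therefore
approximately slope/√(slope² + noise_sd²) in magnitude.  Covariates are
independent of the phenotype (age ~ N(47, 15²) clipped to 18–85, sex
Bernoulli(0.35), handedness Bernoulli(0.875), mean FD ~ 0.10 ± 0.04 mm
clipped to 0.02–0.20) unless `fd_phenotype_r` requests an FD–phenotype
confound at a given correlation level.

What the generator does **not** emulate: hemodynamics, spatial
autocorrelation between neighboring parcels, head-motion artifacts,
scanner drift, non-sinusoidal or state-switching dynamics, and
heavy-tailed noise.  Passing tests therefore demonstrate that the
pipeline recovers planted covariance-level structure under Gaussian
assumptions — not that any specific empirical effect size would
replicate on real data.

Determinism: every draw comes from a SeedSequence keyed by
(seed, subject_index, stream), so cohorts are bit-identical across runs
and subjects can be generated independently in any order.  The pipeline
fans a master seed out the same way per (subject, stage), keeping
results independent of processing order.

## Problem sizes

Full-scale runs (114 nodes, 884 time points, 70+ windows, 60 γ levels,
100 restarts) are supported but deliberate: one subject's full γ sweep
is ~10⁵ Louvain runs.  The test and acceptance suites run the identical
code on reduced grids chosen as the smallest sizes at which the planted
effects are comfortably detectable: 42 nodes (6 per network),
384 time points, 128/64 windowing (5 windows), 20 restarts, fixed
γ = 1, cohorts of 100 subjects.  The generator's default condition
parameters (within/between covariance, stability range, noise, slope)
are never changed between test and demonstration runs.

## Known limitations

- Louvain is a heuristic; global optimality is only guaranteed where
  enumeration verifies it (small graphs).  Degenerate near-optimal
  partitions at high γ can make per-window Q noisy at small n_runs.
- The group state convention needs equal window counts across subjects.
- The signed-modularity variant used by any given prior study may
  differ; comparisons across toolboxes should pin the variant
  explicitly (it is recorded in every manifest).
- Partial Spearman p-values are approximate (t distribution); for very
  small cohorts a permutation scheme would be preferable and is out of
  scope.
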