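# Methods

## Data model

A cohort is a long-format table with one record per (subject, condition)
and eight numeric outcome measures. Exactly two condition levels are
supported (a two-arm crossover); missing values are rejected rather than
imputed, matching the complete-case setting the package targets. Every
measure carries a direction of improvement dₖ ∈ {+1, −1}; the default
battery fixes AMP, BERG, 6MWT, PEQ-amb and MFES as higher-is-better and
the timed FSST, 10MWT and TUG as lower-is-better. All variances and SDs
throughout the package use the sample (n−1) convention.

Standardization is an explicit object (per-measure mean and sample SD),
so the leakage-safe policy — fit on training rows only, apply to held-out
rows — is expressible; the inverse transform is exact.

## Autoencoder composite

The network is deliberately minimal for tiny-n batteries:
8 → dense(H, act) → dropout(0.4) → dense(1, linear) → dropout(0.4)
→ dense(H, act) → dense(8, linear), with encoder and decoder sharing H
and the activation. The bottleneck activation is the composite score.

Training choices, with rationale:

* **Full-batch Adam, lr 0.01, 2000 epochs.** The datasets are tens to a
  few hundred records; full-batch removes batch-order nondeterminism and
  the whole optimization takes well under a second. Optional plateau
  early stopping (patience 200 epochs, min-delta 1e-5 on the
  dropout-free training loss) trims converged runs.
* **Dropout only during training.** Scoring through a 0.4-dropout
  width-1 bottleneck would zero 40% of composites; inference is
  deterministic.
* **Loss trace records the dropout-free MSE** each epoch, so the trace is
  monotone-ish and early stopping is not driven by mask noise.
* **Initialization** is uniform fan-in scaling, U(±1/√fan_in), from a
  generator seeded per run; identical (data, architecture, config, seed)
  reproduce bit-identical weights.
* **Divergence** (non-finite loss) raises immediately with a suggestion
  to lower the learning rate.

Model quality: explained variance EV = 1 − mean_k s²ₖ / mean_k var_k
with s²ₖ the per-measure residual sample variance. The raw mean residual
variance is reported alongside, since on data standardized with the same
statistics the denominator is ≈ 1 and the two quantities are then
complementary.

Hold-out evaluation runs twice with completely disjoint test sets: one
seeded permutation supplies the first ⌈0.1·n⌉ indices to run 1 and the
next ⌈0.1·n⌉ to run 2 — the minimal construction that guarantees
disjointness. Splitting is at the record level (a subject's two
conditions may straddle the split); the scaler is refitted on each run's
training rows (`scaler_policy="all"` reproduces the pooled alternative).
With 9-subject cohorts the test sets hold two records, so per-replicate
test EV is extremely noisy (it can be strongly negative); conclusions in
the test suite are therefore drawn from medians over seeds.

The grid search covers {relu, tanh, sigmoid, linear} × {10, 12, 16, 24,
32} = 20 configurations, all evaluated on the same seeded splits, winner
by mean test EV, exact ties broken by list order.

## PCA composite

Eigendecomposition of the sample covariance of the already z-scored
battery (i.e. correlation-matrix PCA); variance fraction = eigenvalue /
trace; scores are centered projections. Loading signs are fixed against
the direction vector d, so PC1 of a health-factor battery loads
positively on higher-is-better measures. A stability check verifies that
PC1 is identical whether one or two components are extracted — true by
the nesting property of eigendecompositions — and flags, rather than
silently resolves, a (numerically) tied top eigenvalue pair, where the
component pair is rotationally degenerate. A converged width-1 *linear*
autoencoder spans the top principal subspace, so its training EV equals
the PC1 variance fraction; this equivalence is a standing regression test
tying the two methods together.

## Sign alignment and inference

A raw composite has an arbitrary sign. The alignment proxy is
pᵢ = mean_k(dₖ zᵢₖ); the composite is multiplied by −1 iff it correlates
negatively with p. Alignment is idempotent and undefined (an error) for
zero-variance scores.

The condition effect is tested by a two-level repeated-measures ANOVA
implemented through its exact paired-t reduction (F = t², identical
two-sided p, df (1, n−1)); incomplete pairs raise an error naming the
subject, and zero-variance differences are reported as degenerate rather
than yielding an infinite F. Per-measure paired t-tests (threshold 0.05,
no multiple-testing correction — the composite is the primary analysis,
and the report says so) accompany the composite test.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with the
published per-condition group summaries as default marginal calibration:

    h_ij  = √τ·a_i + √(1−τ)·u_ij + δ·1[j = better]        (latent health)
    z_ijk = ρ·d_k·h_ij + γ·c_k·(h_ij² − 1) + √(1−ρ²)·e_ijk
    x_ijk = mean_kj + sd_kj · (z_ijk − E z_kj)/SD(z_kj)

with a, u, e independent standard normal, c = d ∘ (+1, −1, …) the
alternating pattern orthogonal to d. Defaults: ρ = τ = 0.8, δ = 0,
γ = 0, n_subjects = 9.

Design choices:

* **Exact marginal calibration.** z is centered and scaled by its exact
  per-(measure, condition) population moments (closed forms in ρ, γ, δ)
  before the affine map, so marginal calibration and correlation
  structure are orthogonal knobs for every parameter setting.
* **δ = 0 by default**: the condition effect then enters only through
  the per-condition marginal means, avoiding double counting; δ > 0 adds
  a latent shift on top.
* **The nonlinear arm is a quadratic of the *same* latent factor,
  loading on the orthogonal pattern c.** This makes the signal a curved
  one-dimensional manifold: z = ρ·d·h + γ·c·(h²−1) + noise. A
  one-component PCA captures only the linear arm along d (population
  1-component EV ρ²/(1+2γ²)), while a width-1 nonlinear autoencoder can
  represent both arms from the single latent h (ideal EV
  (ρ²+2γ²)/(1+2γ²)). A quadratic of a *second*, independent factor would
  not work: loading it on d would leave it fully visible to PC1, and no
  single bottleneck can encode two independent factors — so this
  construction is the one that actually realizes a nonlinear advantage.
  The `table2-nonlinear` preset uses γ = 0.35 (≈ 20% of standardized
  variance on the quadratic arm; population ideal EVs ≈ 0.71 autoencoder
  vs ≈ 0.51 one-component PCA).
* **Factor-model caveat.** The real battery's joint correlation
  structure is unknown; the one-factor-plus-noise form is an explicit
  assumption. Passing tests show the pipeline recovers planted structure,
  not that real batteries have this structure. In particular, with
  ρ = τ = 0.8 each standardized measure's cross-condition correlation is
  ρ²τ ≈ 0.51, which is far noisier within-subject than typical repeated
  clinical measurements; single 9-subject replicates therefore often fail
  to reach p < 0.001 on the composite even though the direction of the
  effect is recovered in ≈ 98% of replicates. The generator also does not
  emulate dropout/withdrawal, floor/ceiling effects of bounded scales
  (BERG, MFES), or heteroscedastic measurement error.

A second, separate generator plants an exact two-factor linear spectrum:
x = √v1′·u1·f1 + √v2′·u2·f2 + √(r/8)·e with (v1′, v2′, r) solved from
v1′ + r/8 = v1, v2′ + r/8 = v2, v1′ + v2′ + r = 1, so the population
covariance's eigenvalue shares are exactly (v1, v2, r/8 ×6). Calibrated
to (0.673, 0.098) this gives v1′ = 0.634833, v2′ = 0.059833,
r = 0.305333; infeasible targets (any negative solution) are rejected.
u1 defaults to d/√8 and u2 to the alternating pattern c/√8.

## Problem sizes and determinism

Default problem sizes used by the test suite and the acceptance script:
100,000 records for spectrum recovery (sampling error of the PC1 share
well under one point), 10,000 subjects for marginal-moment recovery
(3 SE ≈ 0.3% of a mean), 100 seeds × 9 subjects for crossover sampling
distributions, 10 seeds × 200 records for the autoencoder-vs-PCA
held-out comparison. Every stochastic component takes an explicit seed;
derived child seeds come from a seed sequence and stay below 2³¹. There
is no global random state anywhere.

## Known limitations

* Only two-level crossover designs; no longitudinal (>2 timepoint) or
  >2-condition support, no mixed-effects modeling beyond the paired
  reduction.
* The autoencoder depth is fixed to the single-hidden-layer shape; no
  GPU or minibatch path (pointless at this scale).
* Explained variance is one specific ratio definition; other conventions
  (per-measure R² averaging, pooled-entry R²) differ on heteroscedastic
  residuals.
* The units field of a measure is free text and not validated.
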