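# composcore

Composite scoring of small clinical outcome batteries with a width-1
bottleneck autoencoder, compared against a PCA composite, for two-condition
crossover studies.

## The problem

Rehabilitation and prosthetics trials routinely collect a battery of
outcome measures — here the eight-measure lower-limb battery: Amputee
Mobility Predictor (AMP), Berg Balance Scale (BERG), 6-min walk test
(6MWT), Prosthesis Evaluation Questionnaire ambulation module (PEQ-amb),
Modified Falls Efficacy Scale (MFES), Four Square Step Test (FSST), 10-m
walk test (10MWT), Timed Up and Go (TUG) — on very few subjects. Each
measure is noisy and individually under-powered, but they all reflect one
underlying construct, overall functional health. `composcore` distills a
battery into a single score per (subject, condition) record and tests the
condition effect within subjects.

Two reduction methods are implemented over z-scored measures
*x* ∈ ℝ⁸:

* **Autoencoder composite.** A tied-shape encoder/decoder
  8 → dense(*H*, act) → dropout → dense(1, linear) → dropout →
  dense(*H*, act) → dense(8), trained full-batch with Adam
  (lr = 0.01) on the mean squared reconstruction error
  L = (1/N) Σ (x − x′)². The activation of the single central neuron,
  z = h₁(w₁x + b₁), is the composite; defaults are *H* = 24, relu,
  dropout 0.4, and a grid search over
  {relu, tanh, sigmoid, linear} × {10, 12, 16, 24, 32} is available.
* **PCA composite.** PC1 score of the sample covariance of the z-scored
  battery (correlation-matrix PCA), with the loading sign fixed against
  the direction-of-improvement vector *d* (dₖ = +1 if a higher raw score
  is better, −1 otherwise).

Model quality is the explained-variance fraction
EV = 1 − (mean per-measure residual variance s²ₖ) / (mean per-measure
total variance), with s²ₖ = 1/(n−1) Σᵢ (xᵢₖ − x′ᵢₖ)², estimated on two
hold-out runs with disjoint 10% test sets. Composites are sign-aligned so
that improvement in any measure raises the score, then the condition
effect is tested with a two-level repeated-measures ANOVA (exactly the
paired t-test: F = t²).

Because per-subject data of the motivating study are not public, the
package includes a calibrated synthetic cohort generator: a shared latent
health factor with within-subject correlation τ across conditions,
per-measure loadings ρ·dₖ, exact per-condition marginal (mean, SD)
calibration, and an optional quadratic arm of the latent factor that a
linear one-component reduction cannot capture.

## Worked example

```bash
composcore simulate --preset table2-linear --seed 1 --out cohort.csv
composcore compare --in cohort.csv --seed 1 --out report/
```

prints

```
ae: F=10.399 p=0.0122 sign=-1
pca: F=11.820 p=0.00885 sign=+1
wrote report bundle to report
```

and `report/report.json` contains, among other fields,

```
ae   train_explained_variance 0.554   group means MK -2.06 / MCK 0.97
pca  pc1_variance_fraction    0.496   group means MK -1.12 / MCK 1.12
```

Reading: on this simulated 9-subject crossover cohort the autoencoder
composite reconstructs 55% of the battery variance on its training
records versus 50% for PC1; after sign alignment (the autoencoder's raw
bottleneck happened to point the "wrong" way, hence `sign=-1`) both
composites are higher under the microprocessor-controlled knee (MCK) than
the mechanical knee (MK), and the within-subject condition effect is
significant at the 0.05 level for both (p = 0.012 and 0.009 on 1 and 8
degrees of freedom). Single 9-subject replicates vary widely; the test
suite characterizes the sampling distribution across 100 seeds.

The same pipeline runs on real data: any CSV with columns
`subject,condition,AMP,BERG,6MWT,PEQ_amb,MFES,FSST,10MWT,TUG`, two
condition labels, and one row per (subject, condition).

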