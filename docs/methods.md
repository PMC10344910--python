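# Methods

## The prediction model

The engine implements the SRK/T formula (Retzlaff–Sanders–Kraff, with the
published errata) exactly as a chain of closed-form steps: keratometry
from the corneal radius under the 1.3375 keratometric-index convention
(K = 337.5/r), the long-eye axial-length correction (quadratic above
24.2 mm), computed corneal width and corneal height, an A-constant-derived
estimated lens position, the retinal-thickness correction, and the
thin-lens vergence equation at a 12 mm vertex distance. All coefficients
live in one frozen `SRKTConstants` dataclass so published coefficient
variants can be swapped in a single place.

Two numerical choices deserve note. The corneal-height radicand
r² − Cw²/4 can go negative for extreme (mostly synthetic) eyes; we clamp
it to zero (H = r) and log a warning rather than raising, matching common
SRK/T implementations and keeping extreme eyes testable. And the long-eye
quadratic is *not* exactly continuous at the 24.2 mm breakpoint: the gap
is 0.0227 mm with the published coefficients. The tests assert the
measured gap rather than assuming continuity.

Power selection quantizes to the manufacturing grid (5.0–30.0 D in 0.5 D
steps), breaking ties toward the higher power — the clinical convention of
preferring a slightly myopic over a hyperopic surprise.

## The refinement layer

An ε-insensitive SVR with an RBF kernel predicts the achieved MRSE from
six features: the SRK/T prediction plus AXL, CR, ACD, LT and WTW. Because
the features mix diopters and millimetres, they are standardized (zero
mean, unit variance on the training set) before the kernel; a single γ is
meaningless otherwise. Zero-variance features get unit scale with a
warning. The target is the MRSE directly; predicting the SRK/T residual
instead is available as a config option and is equivalent up to
reparameterization, since the SRK/T prediction is itself a feature.

Hyperparameters: C ∈ {0.1, 1, 10, 100, 1000} × γ ∈ {0.001, 0.01, 0.1, 1}
by default, ε = 0.1 D, chosen by 5-fold inner cross-validated MSE on the
training set only (the evaluation fold never leaks into model selection).
Ties break deterministically in grid order. Fit cost grows steeply with C
and n (an RBF SVR at n ≈ 3800 takes seconds at C ≤ 10 but minutes at
C = 1000), so two presets exist: `RefinerConfig.fast()` (C ∈ {1, 10},
γ ∈ {0.01, 0.1}, 3 inner folds) for repeated medium-size runs, and
`RefinerConfig.fixed(c, gamma)` which pins the hyperparameters and skips
the search — used for full-size (4800-eye) cross-validation and for the
learning-curve comparisons below. Fitting uses scikit-learn; the stored
model keeps the support vectors, dual coefficients and intercept
explicitly, predicts via the plain RBF kernel expansion, and round-trips
through JSON bit-identically.

## The synthetic cohort

No clinical data ship with the package; the generator emulates a large
East-Asian pseudophakic population so every downstream stage is testable.

Biometry: five correlated truncated normals (Gaussian copula over exact
truncated-normal marginals) with means/SDs/bounds of AXL 24.0/1.5 mm
[20.5, 30.5], CR 7.63/0.26 mm [6.72, 8.54], ACD 3.11/0.40 mm [1.75, 4.62],
LT 4.53/0.46 mm [3.0, 6.0], WTW 11.7/0.4 mm [10.0, 13.5]. The LT and WTW
bounds are wide physiological ranges chosen here. Correlations (invented,
physiologically signed, configurable): corr(AXL, ACD) = 0.4,
corr(AXL, CR) = 0.3, corr(AXL, LT) = −0.3, corr(ACD, LT) = −0.4, others 0.
Because the AXL bounds are asymmetric about the mean, the generator
re-centers the pre-truncation location so the post-truncation mean equals
the configured mean; without this the sampled AXL mean sits ~0.04 mm high.

IOLs: a 17-entry catalogue of models with A-constants spanning
118.26–119.60, sampled by realistic market-share weights; exactly one
hydrophilic plate-haptic model, at A = 118.26 — every other model is
open-loop. Target refractions are truncated normal with mean −0.20 D,
SD 0.6 D (our choice; the spread gives a realistic myopic tail) on
[−7.42, 1.13] D, and the implanted power is the grid power whose SRK/T
prediction is closest to the target.

Outcome: MRSE = SRK/T prediction + b(x) − 0.10·1[plate] + N(0, 0.35²),
with the smooth systematic deviation

b(x) = 0.05 + 0.36·(AXL−24)²/4 − 0.45·(ACD−3.11) + 0.25·(LT−4.53)  [D].

The coefficients are calibrated so the raw SRK/T prediction error has SD
≈ 0.50 D against the 0.35 D irreducible noise floor — the regime where a
learnable systematic component is large enough for refinement to visibly
help and small enough that the task is not trivial. The plate-haptic term
is a *hyperopic prediction-error offset*: plate-haptic eyes end 0.10 D
more myopic than predicted (capsule contraction displacing the optic), so
the error (predicted − MRSE) of that subgroup shifts positive.

What the generator does **not** model: biometer measurement error,
age/sex structure, bilateral-eye correlation, posterior corneal power,
corneal asphericity, and any IOL-model effect beyond the A-constant and
the haptic offset. Passing tests therefore demonstrate that the pipeline
recovers structure *of this kind* — smooth biometry-dependent bias plus a
subgroup offset — not that it reproduces any particular clinic's numbers.

## The experiment

Five-group rotation: a uniformly random permutation is dealt round-robin
into five groups (sizes differ by at most one); each group is evaluated
once by a model trained on the other four, so the evaluated-record count
equals the dataset size and the training size is 4/5 of it (3840 at 4800
eyes; 60 at 75). Halving runs 4800 → 2400 → 1200 → 600 → 300 → 150 → 75.
Subsampling across sizes is nested by default (each half is a prefix of
one fixed permutation), isolating the size effect from resampling noise;
an independent-draw mode exists for sensitivity checks. Groups are
re-partitioned at every size, and this is recorded in provenance.

Subgroups, boundaries taken literally: long eyes AXL > 26.0 mm; normal
22.0–26.0 mm inclusive; short (< 22.0 mm) excluded but counted.
A-constant bins are right-closed: (−∞, 119.0], (119.0, 119.2],
(119.2, 119.4], (119.4, 119.6]; values above the last edge are excluded
with a warning. Empty subgroups are reported as undefined, never
fabricated.

### Problem sizes and replication

The replicate-based properties use sizes chosen to keep a full run in
minutes on one CPU while preserving the comparisons of interest:

- *Refinement recovery*: 20 replicate 600-eye cohorts; at sizes 150 and
  300 the full default grid is searched, at 600 the fast preset. Held-out
  RMSE of the refined prediction is compared with raw SRK/T RMSE on the
  same eyes.
- *Dataset-size trend*: 20 replicate 4800-eye cohorts, comparing the
  full cohort with its nested 75-eye subset. Hyperparameters are held
  constant across the two sizes (fixed C = 10, γ = 0.1) so the comparison
  isolates the training-set-size effect; letting the grid search re-adapt
  at n = 75 partially compensates for the small training set and dilutes
  the within-±0.25 D comparison, while the SD effect survives either way.
- *Single-draw full-size analyses* (plate-haptic subgroup) use one
  4800-eye cohort with the fixed configuration.

The dataset-size runner itself supports any per-size configuration; these
are the defaults used by the acceptance script and tests.

## Statistics

Error summaries report mean, sample SD (n − 1), median absolute error,
median signed error, and inclusive threshold proportions (|e| ≤ t counts
as "within ±t"); MedAE of an even-length list is the mean of the central
pair. The test battery wraps scipy/statsmodels: one-way ANOVA, Holm
step-down adjustment, Pearson χ² on 2×2 proportion tables without
continuity correction, a two-sided variance-ratio F test, the Welch
(unequal-variance) t test by default with a pooled option, and Tukey HSD.
The variance-ratio test treats subset-vs-full SDs as independent samples
even though the subset's eyes are a subset of the full set — a documented
simplification that mirrors how such comparisons are usually reported.
Identical-group degenerate inputs return null results (statistic 0,
p = 1) rather than NaN.

All tests are cross-checked in the suite against independent
textbook-formula oracles (sums of squares, pooled variances, expected
counts, studentized range) to 1e-8 on random datasets.

## Known limitations

- The synthetic outcome model is a stylized stand-in; absolute error
  magnitudes depend on its calibration, so only directions of effect and
  internal consistency are meaningful claims.
- The SVR refits from scratch at every fold and size; there is no warm
  starting, so very large grids at full size are slow by design honesty
  rather than impossibility.
- Only SRK/T is implemented; refining other vergence formulas would need
  their own engines.
- Eyes with a history of refractive surgery, toric targets, and
  single-IOL-model analyses are out of scope.
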