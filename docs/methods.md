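# Methods

This note documents the statistical machinery, the defaults and the design
choices of `morphuniq`, in the order the pipeline applies them.

## Superimposition

Configurations are centred, scaled to unit centroid size and rotated onto
the running consensus by the closed-form orthogonal fit with the rotation
determinant constrained positive — reflections are never used, because the
two mandible views the package was designed around (left/lingual and
right/occlusial) are analysed separately and a mirror match would be a
digitisation error, not a biological similarity. The consensus is the mean
of the aligned set re-scaled to unit size each iteration; the residual sum
of squares is non-increasing across iterations and iteration stops when the
consensus RMS displacement falls below `tol = 1e-8` (chosen well below any
landmark digitisation noise; `max_iter = 100`). After convergence the whole
set is rotated so the consensus principal axes coincide with the coordinate
axes, with signs fixed by the largest-magnitude coordinates, making outputs
bit-reproducible across runs and platforms. Centroid sizes are computed
from the raw (physical-unit) coordinates before any scaling, so they are
untouched by alignment.

## Shape variables

The bending-energy matrix uses the TPS kernel U(r) = r² log r² (natural
log, 0 on the diagonal) evaluated on consensus inter-landmark distances,
as the upper-left block of the inverse bordered system `[[K, P], [Pᵀ, 0]]`
with `P = [1 | x | y]`. Its null space is exactly the affine functions, so
k landmarks give k − 3 principal warps; each contributes an x and a y
score, and two uniform components complete the tangent space: 2k − 4 shape
variables (18 for k = 11).

The uniform basis is built by the orthogonal-complement construction:
the two affine displacement fields of the consensus generated by symmetric
traceless 2×2 matrices (pure stretch and pure shear), orthogonalised
against the similarity fields (translations, rotation, scaling) and
orthonormalised. Any convention for the uniform pair differs from another
by at most a rotation within that 2-D subspace; total variance and every
downstream statistic (relative warps, MU, MANOVA) are invariant to that
choice.

A deliberate numerical caveat: unit-centroid-size aligned specimens deviate
from the consensus with a second-order component along the consensus
(scale) direction, which the 2k − 4 basis excludes by construction. Shape
variables therefore preserve total deviation variance only to O(ρ⁴) in the
Procrustes distance ρ — exact to ~1e-8 at the small shape amplitudes the
generator produces, and irrelevant to any comparative statistic.

Relative warps are the principal components of the (optionally
size-corrected) shape variables without eigenvalue weighting (α = 0),
computed from the sample covariance (ddof = 1); loadings signs are fixed by
making each component's largest-magnitude loading positive.

## Size correction

The transform decision applies Shapiro–Wilk at α = 0.05 to raw and
log sizes: log is adopted only when raw fails and log passes (the study
preset fixes log for the lingual view, identity for the occlusial, mirroring
the published decisions; the emulated 189-specimen pooled sample is a
two-component size mixture and can fail both tests, in which case identity
is kept with a warning).

Size correction fits shape ~ sex + size + sex×size with effect-coded sex
and tests the interaction with Wilks' Λ on all shape variables. When the
interaction is non-significant (p > 0.05) a single common slope serves both
sexes; otherwise sex-specific slopes are used. In both cases **only the
size term is subtracted**, so group shape differences survive into the
residuals.

The common slope is, by default, estimated with sex in the model
(`method="common_within"`, the pooled within-group slope). This matters:
size is strongly sex-separated, so a size-only regression
(`method="pooled_simple"`, provided for completeness) confounds the sex
mean shift with allometry — it removes roughly half of any sex shape
difference and, worse, injects within-group size variance back into the sex
direction of the residuals, capping the achievable residual separation at
about 2.5 within-group SDs regardless of how large the true dimorphism is.
The within-group estimate has neither pathology and is the convention of
the standard morphometrics packages. Residuals from the default path are
exactly orthogonal to the size covariate after sex is partialled out of it;
residuals from `pooled_simple` are exactly orthogonal to raw size. Both
paths are idempotent.

## Morphological Uniqueness

Along one relative warp, each group's scores become a Gaussian kernel
density (Silverman's rule per group by default — 0.9·min(sd, IQR/1.349)·n^(−1/5);
a Sheather–Jones-style plug-in is selectable). Both densities are evaluated
on one uniform 512-point grid and renormalised to integrate to 1 on that
grid, which guarantees overlap ∈ [0, 1] under either range rule:

- `union_extended` (default): grid spans the union of both groups' ranges
  extended by 3× the larger bandwidth — no density mass is clipped;
- `largest_group`: grid restricted to the larger group's observed
  range, the verbatim published convention, which can truncate the smaller
  group's tails.

Uniqueness is one minus the trapezoidal integral of the pointwise minimum;
per-warp values are weighted by eigenvalue proportions wᵢ = λᵢ/Σλ and
summed. For multi-level factors the per-warp value is the unweighted mean
over all level pairs (pair-size weighting is not applied), levels with
n < 3 are dropped with a warning, and zero-variance groups raise rather
than being silently jittered.

Significance re-assigns specimens to groups of the original sizes — with
replacement by default (`bootstrap_labels`, the published description) or
by permutation (`permute_labels`, the conventional exchangeability null;
both are calibrated, with the bootstrap mode mildly conservative).
Bandwidths and grids are re-fitted for every resample; p = (#null ≥
observed + 1)/(R + 1), so the smallest attainable p is 1/(R + 1). The null
computation is vectorised across resamples with kernel sums in float32 —
the KDE's statistical error is orders of magnitude above float32 rounding —
which keeps a 500-resample null under ~0.2 s per axis.

Small-sample note: KDE overlap is biased downward (uniqueness upward) at
small n, and the bias is larger for factors with many small levels. In
dominance tables this favours multi-level factors (population) on warps
where nothing is happening; the overall weighted MU ranking is much less
affected. This mirrors the behaviour of the statistic as published, and is
why the resampling test — which carries the same bias under the null — is
the inferential instrument, not the raw MU value.

## Mixture clustering

An Autoclass-style analysis: diagonal-covariance Gaussian mixtures fitted
by EM, with each cluster/variable variance floored at a per-variable error
term (default 1e-3 × that variable's SD over all specimens, emulating fixed
measurement-error terms). Restarted from random fractional
responsibilities (library default 50 restarts; the analysis drivers use 12,
which the selection experiments show is ample for these data sizes);
convergence requires every parameter to move < 2.5e-3 over 10 consecutive
iterations, mirroring the published convergence rule at a desk-scale budget
instead of millions of iterations. The in-sample objective is monitored for
EM monotonicity (floors can produce sub-nat dips, which are logged).

Model selection maximises a Cheeseman–Stutz approximation to the log
marginal likelihood: CS = log p(X|θ̂) + log m(X, ẑ) − log p(X, ẑ|θ̂) with
fractional assignments ẑ, a symmetric Dirichlet(1) on weights and a
unit-information normal–inverse-gamma prior per cluster/variable anchored
at the overall data moments (κ₀ = 1, ν₀ = 1, scale = data variance). The
unit-information anchoring keeps the Occam factor near ½·log n per
parameter; a much vaguer mean prior over-penalises well-separated
two-cluster solutions. BIC is selectable as a fallback score. Probability
ratios between classifications are exp(Δ log score). No claim of
numerical equivalence with Autoclass-C is made — its prior specification
is not public in comparable form; the selection behaviour (homogeneous
data → K = 1, separated sexes → K = 2 with confident posteriors) is the
validated surface.

## MANOVA

Type-III tests by explicit model comparison on effect-coded (sum-to-zero)
designs: for each term, H is the residual-SSCP difference between the model
without that term and the full model, E the full-model residual SSCP;
Λ = |E|/|E + H| with Rao's F approximation and its standard degrees of
freedom. Effect coding plus type-III comparison is what accommodates the
unbalanced cell counts of the emulated design. Partial η² = 1 − Λ^(1/s)
with s = min(m, df_h) (so single-df effects give exactly 1 − Λ), and
observed power is computed from the noncentral F with λ = F·df₁ — the
post-hoc convention of the commercial packages whose output the tables
mirror. Nested designs code the inner factor within each outer level
(Σ(levels − 1) columns); an inner factor with one level per outer level has
zero df and is reported as undefined rather than silently dropped.

The trajectory comparison between groups reports the angle between their
leading principal axes (arccos of |dot|, in [0°, 90°]) with a bootstrap
null built from the angle between two independent re-estimates of one
group's axis — the null therefore carries the same two sources of axis
error as the observed statistic, which a one-sided "wander" null does not.
This is a principled simplification of ordered-axes analysis, not a
reimplementation of it.

## Gene flow

The influence index is (proportion of focal-population area under the
alternate host + same for the adjacent population) / distance between
them; the published per-population values are consumed as inputs. Shape
dispersion per population is the SEM of RW1–RW3 scores (per-RW regressions
and the mean-SEM variant are both computed, since the published wording is
ambiguous); ordinary least squares against influence gives slope, r² and a
two-sided p.

## Synthetic data generator

The generator emulates the study's structure, not its biology. Effects are
injected in the shape-variable space of an 11-landmark mandible-like
template (so magnitudes read as Procrustes distances): a sex effect of
0.06 split ±half between the sexes, per-population offsets of 0.015, host
and rearing effects of 0.010, an allometric slope of 0.05 per unit
log-size, and isotropic Gaussian landmark noise of SD 0.0075 — placing the
within-group shape variance (≈ 2k·σ² ≈ 1e-3) an order of magnitude above
the squared smallest effect, so secondary effects are detectable but not
trivial. Centroid sizes are lognormal with the published female/male
moments (992.67 ± 64.84 µm vs 876.75 ± 50.83 µm) for the lingual preset
(normal for the occlusial), and each specimen is hidden behind a random
rotation, translation and size-scaling that the pipeline must undo. The
design table reproduces the published lingual cell counts (189 specimens;
141 M / 48 F).

What the generator does **not** emulate: anisotropic or correlated
within-group landmark covariance, digitisation/orientation error structure,
left–right asymmetry, or any real host-specific deformation pattern.
Passing end-to-end tests therefore demonstrates that the chain recovers a
known factor structure through superimposition, correction and inference —
not that the real data would show the same effect sizes.

## Problem sizes and determinism

The analysis drivers and acceptance script run the full chain on one
emulated dataset (n = 189, 18 variables, 1000 MU resamples, K ≤ 3–4 with
12 restarts) in well under a minute; the test suite's calibration
experiments use 500 replicate null datasets × 500 resamples and 50
generator seeds. All stochastic stages draw from generators seeded by the
run seed (the pipeline derives per-stage substreams by hashing the stage
name), so identical configurations reproduce identical artifacts, checksums
included.

## Known limitations

- MU is univariate per axis; joint (multi-dimensional) overlap is out of
  scope, so correlated group differences spread over many low-variance
  axes are under-weighted.
- The KDE small-sample bias makes raw MU values comparable only between
  factors with similar group-size profiles; use the resampling test for
  inference.
- Observed (post-hoc) power is reported because the original tables report
  it; it is a deterministic transform of the observed F and should not be
  read as a design-stage quantity.
- The Cheeseman–Stutz score is an approximation; ties within a few nats
  between K and K+1 should be treated as unresolved rather than decided.
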