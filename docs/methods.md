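# Methods

`paleomorph` implements the morphometric inference chain by which a
fragmentary primate femur — the motivating case is Trinil 5703, a partial
left femur preserving the proximal end and part of the shaft — is
attributed to one of four Southeast Asian primate clades: small apes
(Hylobatidae), langurs, odd-nosed monkeys and macaques. Three independent
lines of evidence are computed from two kinds of raw data:

1. **allometric length estimation** from linear calliper measurements,
2. **size-free shape ordination and discriminant classification** from the
   same measurements,
3. **shaft-curvature comparison** from 3-D landmark chains.

This note documents the models, their assumptions, the tunable parameters,
and the design choices made where the procedure was genuinely open.

## Measurement protocol

Nine linear variables in mm: two neck lengths (LNW, UNW), antero-posterior
neck width (ANW), minimum proximo-distal neck height (NH), antero-posterior
and medio-lateral shaft widths just below the lesser trochanter (ATW, MTW),
maximum antero-posterior shaft width and its medio-lateral counterpart
(ADW, MDW), and total length (TL). A fossil with a broken shaft preserves
the first eight but not TL; that eight-variable set is therefore the default
subset for all shape analyses, so the fossil is always projectable. Validation
enforces positivity, TL exceeding every other measurement, and the rule that
fossil records never enter any model fit.

## Allometric length estimation

Within each clade, ordinary least squares on natural logs:

    ln TL = a + b·ln NH + ε,   ε ~ N(0, σ²)

Reported per model: n, slope b with t-based 95% CI, intercept a with 95% CI,
Pearson r of the log pair, and SEE = √(RSS/(n−2)). The fossil's length is
`exp(a + b·ln NH)` with the multiplicative one-SEE band
`exp(a + b·ln NH ± SEE)` — asymmetric in mm, as a log-scale band must be.
The reference coefficient table publishes its y/x labels in the inverted
order relative to the estimates it prints; this package fits TL as the
response, which is the direction that reproduces the published fossil
estimates (177 mm small apes, 132 mm macaques at NH = 9.86 mm). The
published langur coefficients give 166.5 mm, not the 171 mm printed beside
them; the package reports the value its coefficients actually produce and
flags the discrepancy rather than patching it. No odd-nosed model is
fitted by default: the fossil falls outside that clade's morphometric
range, so a prediction from it would be unsupported extrapolation.

The platymeric index is `100·MTW/ATW` (percent, rounded only at display);
values well below 100 mark antero-posteriorly deep shafts. For the fossil's
measurements (ATW 11.15, MTW 9.97) it is 89.4.

## Log-shape ratios

Size is removed by the Darroch–Mosimann transform: each value becomes
`ln xᵢ − mean_k(ln x_k)` over the declared subset, i.e. the log of the
measurement over the geometric mean. The transform is exactly invariant to
uniform rescaling and the vector sums to zero by construction. Natural
logs throughout. The zero-sum constraint makes p ratios rank p−1, which
downstream code must respect.

## Ordination and classification

**PCA** is fitted on the comparative specimens only; fossils are projected
onto the fitted axes afterwards, so a specimen cannot shape the space it is
judged in. Variance fractions come from the covariance eigenvalues and sum
to 1.

**LDA** uses classical canonical variates: generalized eigenvectors of the
between-group scatter against the pooled within-group scatter, scaled to
unit pooled within-group variance, so Euclidean distance in score space is
Mahalanobis distance under the pooled covariance. Axis variance fractions
are the discriminant eigenvalues over their sum. Because the shape vectors
are zero-sum, the last ratio is dropped before fitting — an invertible
reparametrization that leaves the scores unchanged — and loadings are
reported on the retained variables.

Classification (used identically for cross-validation and the fossil
hold-out) is nearest group mean in canonical space shifted by the log
prior. Priors default to **equal** across the four clades: clade sample
sizes in museum collections are collection artifacts, not prevalences.
Proportional priors are available as a switch. Exact ties break to the
lowest clade in canonical order (small apes, langurs, odd-nosed,
macaques). Uncertainty is reported as the cross-validated confusion matrix
(leave-one-out by default — the classical choice at n ≈ 100; k-fold is
available), tabulated as row percentages with raw counts alongside; the
display matrix is rounded to whole percent. The fossil is scored by
post-multiplying its centred shape vector by the discriminant loadings and
assigned by the same rule.

## Shaft curvature

Each specimen contributes ten ordered 3-D landmarks along the anterior
shaft, proximal to distal. The chain is flattened by a per-specimen PCA
(projection onto its own first two principal axes), then registered by the
unique similarity transform — rotation, translation, uniform scaling, no
reflection — sending landmark 1 to (0,0) and landmark 10 to (1,0). After
registration, x marks comparable stations along the shaft and y carries
the curvature signal in baseline units.

PCA axes have arbitrary sign, so orientation is normalized: the first axis
points proximal→distal, and the second is chosen so the summed off-chord
coordinate of the interior landmarks is ≥ 0 (anterior bow positive).
Without this rule, distances would be flip-ambiguous.

Curve distance is the mean Euclidean distance between corresponding
registered landmarks over the eight interior points; both coordinates are
used by default (a y-only mode exists, since y is the designated shape
variable). Endpoints are pinned by construction and excluded from the
mean by default; including them simply rescales d by 8/10 and is provided
as a switch because either denominator convention is defensible. The
fossil is ranked against per-taxon **mean curves** by default (one distance
per taxon); a pairwise mode averages over individuals instead.

`estimate_kappa` summarizes a registered shape as its mid-chord bow: a
quadratic is fitted to the ten registered landmarks and evaluated at
x = 1/2. For a noiseless quadratic arc this recovers the generating
sagitta/chord ratio exactly, even though no landmark sits at the apex
itself (ten evenly spaced stations straddle mid-chord).

## Synthetic data generator

The generator defines the testing conditions for the whole chain when the
original specimen spreadsheets are not available.

**Measurements** are multivariate log-normal per clade: a correlated
Gaussian on the log scale, exponentiated. This guarantees positivity and
makes the log-shape ratios exactly multivariate normal. Calibration is by
moment matching to the published per-clade means and standard deviations:
log-sd ≈ sd/mean (the coefficient of variation) and
log-mean ≈ ln(mean) − log_sd²/2. The published tables give no
inter-measurement correlations, so an exchangeable correlation of **0.7**
(a strong common size factor, typical of mammalian linear measurements) is
the default, overridable per spec. TL is generated from the clade's
published allometry given the drawn NH. The odd-nosed clade has no
published allometric model, so the generator uses isometry (slope 1.0)
with intercept matched to the clade's mean TL/NH ratio and residual sd
0.07, slightly under the clade's raw TL coefficient of variation. Default
sample sizes are the published clade sizes (49/18/6/28).

**Curves** are ten points evenly spaced along the chord of a quadratic arc
with mid-chord bow κ·scale (default chord 100 mm), perturbed by isotropic
Gaussian noise (default 0.5 mm) and rigidly posed in 3-D. Pipeline-demo
defaults give the clades bows of 0.010/0.015/0.030/0.050 (small apes
straightest, macaques most bowed) and the synthetic fossil 0.012.

What the generator does **not** emulate: phylogenetic covariance between
species within a clade, age structure (all records are adults),
taphonomic missing-measurement patterns beyond an optional drop-TL flag,
calliper measurement error as a separate component, and any
non-exchangeable correlation structure. Consequently, passing tests show
the chain is correct and well-calibrated under these idealized
conditions; they do not show that real femora satisfy them.

A calibration caveat worth recording: the published macaque regression
prints r = 0.94 together with SEE = 0.234, but given the published NH
spread for macaques, that SEE implies r ≈ 0.6. The generator follows the
printed SEE (which governs the scatter the estimates actually carry), so
refits on synthetic data recover the published slopes but show lower r
than the printed values for that clade.

## Numerical choices

- Sample (n−1) standard deviations throughout descriptive statistics.
- Missing cells read/written as `-`; never coerced to zero.
- Degenerate inputs are errors, not silent results: zero variance in
  ln NH, all-coincident landmark chains, coincident baseline endpoints,
  clades emptied by a CV fold, singular within-group covariance.
- Registered endpoints are set to exactly (0,0)/(1,0) after the complex
  similarity transform, so the endpoint invariant holds bit-exactly.
- Seeds: every stochastic routine takes an explicit integer seed; the
  pipeline derives per-stage seeds from one master seed via a seed
  sequence, and a fixed seed yields a byte-identical serialized report.
- Log-shape zero-sum is enforced to 1e-10 relative; end-to-end curvature
  similarity invariance holds to 1e-8; noiseless bow recovery to better
  than 1e-6.

## Problem sizes in the test suite

Property checks use the published clade sizes for pipeline realism
(n = 101 comparative specimens), n = 2000 for moment-recovery checks,
500 replicates at n = 49 for allometric slope-CI coverage, and 200
synthetic hold-outs per clade for classification recovery. Classification
recovery at the published calibration plateaus around 65–85% per clade —
consistent with the overlap the published cross-validated confusion matrix
itself reports (diagonal 71/88/72/33%) — so attribution of a single
specimen should always be read jointly with the confusion matrix, which is
exactly how the pipeline reports it.

## Known limitations

- The pipeline treats landmark placement as an upstream acquisition
  concern; no resampling or semilandmark sliding is performed.
- No phylogenetic comparative correction of allometry or discriminants.
- No Procrustes (generalized least-squares) superimposition; two-point
  baseline registration concentrates all registration variance on the
  interior landmarks by design.
- The confusion matrix quantifies risk under the four-clade closed world;
  a fossil from none of the four clades will still be assigned to one.
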