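# Methods

## Signal model

The acquisition being emulated is a composite pulse sequence: a CPMG echo
train (echo half-spacing τ1, n refocusing loops, total transverse evolution
2 n τ1) followed by a 90° storage pulse and a delay τ2 before readout. The
instrument's microscopic details (off-resonance effects, B1 inhomogeneity,
diffusion during the echo train, phase cycling) are outside the model's
scope; each oil is reduced to a small set of discrete relaxation components
(aᵢ, T1ᵢ, T2ᵢ) and the normalized signal is

    f(τ1, n; τ2) = Σᵢ aᵢ e^(−2 n τ1 / T2ᵢ) e^(−τ2 / T1ᵢ) / Σᵢ aᵢ .

Assumptions worth making explicit:

- **Mono-exponential decay per component.** Each proton pool relaxes
  independently with a single T2 during the echo train and a single T1
  during the storage delay; cross-relaxation and exchange are neglected.
- **Echo-spacing convention.** The total transverse evolution is taken as
  2 n τ1 (τ1 is the half-spacing). If an instrument's convention treats the
  programmed delay as the full spacing, its schedules should be halved on
  import; the conversion is a pure relabelling of τ1.
- **Storage-delay form.** The trailing 90° pulse + τ2 is modelled as a
  multiplicative longitudinal factor e^(−τ2/T1) — magnetization stored
  along z decays toward equilibrium and the recovered fraction is not
  refocused. Other storage/recovery forms would change only this factor;
  the law is isolated in `simulate_signal` so alternatives are pluggable.
- **Normalization.** Division by the single-pulse intensity Σ aᵢ puts every
  surface on a common [0, 1] scale; consequently noiseless surfaces of a
  binary mixture combine exactly affinely in the volume fraction, which is
  the algebraic basis of both the adulteration axis and the straight-line
  calibration.

Classical inversion-recovery and CPMG experiments are simulated with the
matching multi-component laws (IR: Σ aᵢ (1 − 2 e^(−t/T1ᵢ)) / Σ aᵢ), and
`fit_monoexponential` performs the standard single-component least-squares
fits used to show that bulk T1/T2 values barely separate the species.

## The synthetic panel

The generator reproduces a realistic benchtop study design rather than any
particular instrument's output:

| parameter | default | rationale |
|---|---|---|
| τ1 schedule | 100, 150, 200, 250, 300, 400, 500 μs | spans weak to strong T2 weighting on a 0.5 T benchtop magnet |
| n schedule | 3 … 2500 (18 log-spaced values) | total echo times from ~1 ms to 2.5 s, bracketing all oil T2s |
| τ2 | 100 ms | comparable to oil T1s (120–300 ms), so the T1 factor is informative |
| noise σ | 1e-3 (normalized units) | an SNR regime where the ~1e-2 fingerprint contrasts stay resolvable |
| brands/species | SO 4, PO 4, CO 5, OL 5, FO 5, SFO 5 | the 28-specimen study inventory |
| brand jitter CV | 0.03 | few-percent compositional variation between commercial brands |
| mixtures | FO+SO at 10–90% (calibration), 20–80% (validation) by volume | binary adulteration series from two designated parent bottles |

The species component tables are **invented** (no per-species component
values are published for this protocol): 2–3 pools per species with
T2 ∈ [40, 200] ms and T1 ∈ [120, 300] ms. They were designed once, before
the statistical tests were frozen, with two goals: (i) bulk mono-exponential
fits similar across species, and (ii) T1 and T2 contrasts decoupled
(OL short-T2/long-T1, CO long-T2/short-T1, PO with a heavy long-T2 tail,
SFO with a weak tail) so the six identifiers spread in all three (B, E, G)
dimensions rather than along a single fast-vs-slow axis. An early draft
that varied species only in overall relaxation rate produced collinear,
elongated clusters — the redesign is what makes the ellipsoids disjoint.

Brand variation multiplies every amplitude, T1 and T2 by independent
lognormal factors with unit median and the configured CV, re-clipping
T2 ≤ T1; measurement noise is i.i.d. Gaussian per grid cell. All
randomness flows from one top-level seed through named substreams
(CRC32-hashed stage names into the seed sequence), so adding a pipeline
stage never perturbs the draws of existing stages, and identical
config + seed reproduce artifacts byte-for-byte.

What the generator does **not** emulate: instrument drift between runs,
temperature sensitivity, paramagnetic-impurity variation within a brand,
non-Gaussian receiver noise, and any deviation of real oils from discrete
mono-exponential pools. Passing tests therefore demonstrate that the
*method* behaves as claimed under its own model of the data, not that a
particular spectrometer will reproduce specific numbers.

## Fingerprints, regions, identifiers

The reference surface is the cell-wise mean of one designated surface per
species (the first brand of each), built once and frozen; mixtures and
held-out samples are fingerprinted against the same reference. A
`smooth` mode also fits a separable cubic polynomial in (log τ1, log n) to
that mean — the curved-surface picture — but the pointwise mean is the
default because subtraction against it is exactly self-consistent (the six
source fingerprints cancel cell-wise). Grid identity is required exactly;
there is no interpolation between grids.

Region geometry is configurable JSON; the default tiles the 7×18 grid into
a 2×4 arrangement (τ1 split low/high at index 3; n split at indices 4, 9,
14), labelled A–D across the n bands at low τ1 and E–H at high τ1.
Features are region *means* (not sums), so they are invariant to mask size
and linear in the fingerprint. The identifier is the (B, E, G) triple: B
responds mainly to mid-T2 content, E (short total echo time, full T1
weighting) to T1, and G (long echo times) to the slow-T2 tail.

## Chemometrics

- **PCA** is correlation-matrix PCA: columns centred and scaled to unit
  variance (ddof = 1), axes from the SVD of the scaled matrix, explained
  fractions σₖ²/Σσ². "Mean centering" and "correlation matrix" are in
  tension as a description of one procedure; scaling to unit variance is
  what makes the eigenvectors those of the correlation matrix, so that is
  the primary mode, with covariance-PCA behind `scale=False`. Loading signs
  are fixed (largest-magnitude entry positive) for reproducibility.
- **Ellipsoids** are Gaussian cluster tolerance regions: sample mean,
  sample covariance (n−1), squared Mahalanobis radius χ²(level, 3) —
  7.8147 at 95%. This is the convention that reproduces the qualitative
  finding that ≥10% mixtures fall outside both parent ellipsoids. It is
  *not* a prediction region for small n: with 4–5 brands per cluster the
  χ² boundary covers new draws of the same species far below nominal
  (the radius ignores estimation error in mean and covariance). For
  membership questions about new specimens, `fit_ellipsoid(...,
  small_sample=True)` substitutes the scaled-F radius
  3(n−1)(n+1)/(n(n−3)) · F(level; 3, n−3); the held-out-brand test uses it,
  together with a 10-brand training panel.
- **Classification**: inside exactly one ellipsoid → that species; inside
  several → smallest squared Mahalanobis distance; inside none →
  "unassigned", the adulteration/unknown flag. The boundary is inclusive.
  The full distance table is always returned.
- **Ellipsoid disjointness** is decided by minimizing the Mahalanobis
  distance to one ellipsoid over the interior of the other (a convex
  program, solved with SLSQP); the sets are disjoint iff the minimum
  exceeds the radius.
- **Adulteration axis**: the segment joining two cluster centres,
  parameterized t = 0 → base, t = 1 → adulterant. Because features are
  affine in the mixing fraction for noiseless mixtures, orthogonal
  projection onto this axis returns v exactly in the ideal limit, and a
  useful model-free estimate otherwise.

## Quantification

Univariate models regress the **ratio on the intensity** (v = slope·x + b)
for each of B, E, G — the stated variable roles of the protocol — while
the inverse parameterization (x as a function of v, the way calibration
plots are conventionally drawn, with negative slopes for decreasing
regions) is reported alongside. Predictions outside [0, 1] are reported
unclipped with a warning. Validation quality regresses *predicted on
actual*; RMSEC/RMSEP use plain 1/n denominators.

PLS1: X autoscaled, y centred; each factor's weight vector is the
normalized cross-covariance Xᵀy of the deflated matrix (for a single
response, the dominant singular direction of Xᵀy is its normalization),
scores t = Xw, loadings by least squares on t, X deflated by the rank-one
t pᵀ; the model collapses to one coefficient vector on the original
feature scale. The factor count minimizes leave-one-out PRESS (smallest
count on ties); candidate counts are capped at the numerical rank of the
autoscaled calibration matrix, since a noiseless mixture panel is exactly
rank 1 in v and higher factor counts are degenerate by construction. Both
the raw minimum PRESS and its root-mean form √(PRESS/n) are reported.

Study conditions for the quantification tests are deliberately split:

- *Exactness*: with zero noise and zero brand jitter, all four models must
  recover every validation ratio to numerical tolerance — a consequence of
  feature linearity in v.
- *Noise sensitivity*: with σ = 1e-3 and a jitter-free panel, ten seeded
  replicates bound RMSEP and the predicted-vs-actual slope. Brand jitter
  is excluded here on purpose: the pure validation brands would otherwise
  contribute irreducible compositional error that measures the panel, not
  the calibration numerics. The full default panel (jitter included) is
  what the acceptance script reports, and its RMSEP of a few percent is
  the realistic operating figure.

## Numerical choices

- Surfaces and fingerprints round-trip CSV at 17 significant digits
  (bit-exact for IEEE doubles, `float_precision="round_trip"` on read);
  tables use 12 significant digits.
- The smooth reference fit standardizes (log τ1, log n) before building the
  tensor polynomial basis, for conditioning.
- Mono-exponential fits seed from a log-linear slope (CPMG) or the
  zero-crossing ≈ T1 ln 2 (IR) and tighten `curve_fit` tolerances to 1e-14;
  non-convergence raises a fit-failure error with the inputs' size and the
  starting point.
- Units are seconds internally everywhere; configs may declare μs/ms and
  are converted on load. Validation rejects unknown keys anywhere in a
  config before any stage runs.

## Known limitations

- Region geometry, like the species library, is a design choice; a real
  deployment would re-derive discriminative regions from measured
  fingerprints of authentic samples.
- The classifier is closed-world over the configured species library plus
  an "unassigned" flag; it identifies *that* a sample is not a pure known
  oil, not *what* the adulterant is.
- Mixtures are binary and assume equal proton density per unit volume
  (volume fraction = amplitude fraction); multi-component mixtures and
  density corrections are out of scope.
- With 4–5 brands per species, cluster covariances are estimated at the
  edge of identifiability in 3D; the pipeline refuses clusters with fewer
  than 4 points rather than regularizing silently.
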