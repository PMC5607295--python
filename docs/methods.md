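# Methods

## The measurement model

A six-fibre probe carries a linear micro-polariser on each distal fibre
tip: two horizontal (H1, H2), two vertical (V1, V2), two at −45° (B1,
B2).  Because the polarisers sit at the tip, fibre bending cannot change
the polarisation delivered to or analysed at the tissue — it only
modulates intensity coupling.  Nine illuminate/collect pairs (H1H2,
H1V2, H1B1, V2H1, V2V1, V2B1, B1H1, B1V2, B1B2) then determine the
linear 3×3 Mueller matrix of the sample.

The detected intensity of a pair is a bilinear form: with the
illumination channel's normalized exit Stokes triplet `s = [1, Q, U]`
and the collection channel's analyzer row `a = ½[1, Q, −U]`,

    I = gain · a · M_sample · s .

The sign flip on the collection-side U arises because the exit Stokes
vectors are characterized for light travelling *out* of the probe; light
travelling *into* the same polariser sees its axis at 180° − θ in its own
frame.  The collection fibre itself never changes the *total* intensity
(it is non-depolarising and non-diattenuating with unit transmittance),
which the test suite verifies against a full-chain evaluation through a
random unit-transmittance fibre matrix.

Stacking the nine bilinear forms gives `y = ½ Z m`, where `m` is the
row-major element vector m11…m33 and row (i→c) of the **system matrix**
`Z` is the Kronecker product `kron([I_c, Q_c, −U_c], [I_i, Q_i, U_i])`.
`Z` depends only on the channels' exit states, so it is measured once per
probe.  Reconstruction solves `m = 2 Z⁺ (c ∘ y)` by least squares (equal
to the inverse for a well-posed 9×9 system, and unchanged in API if
redundant rows are ever added).  With ideal cardinal channels
cond(Z) ≈ 5.8; a warning is raised above 10⁶ (a double-precision safety
margin — the choice is ours) and a rank-deficient Z raises an error.

### Why all composition is 4×4

Every optical element is composed in the full 4×4 Mueller calculus and
the 3×3 linear block extracted only at the measurement interface.  The
linear block of a retarder is not orthogonal (it drops the linear↔
circular coupling through V), so composing 3×3 blocks pass-by-pass gives
`cos²δ` in m22 of a 45°-axis double pass where the correct answer is
`cos 2δ`.  A regression test pins this failure mode.

### Reflection geometry

The mirror is `diag(1, 1, −1, −1)`: U and V flip with the helicity when
propagation reverses.  An element traversed again on the return pass is
seen at axis 180° − θ.  These two rules are the *only* frame handling in
the package.

## Synthetic data

No deposited measurements exist for this kind of instrument, so the
probe module doubles as the data generator.  Defaults mirror the study
conditions of the hardware the model describes:

| parameter | default | meaning |
|---|---|---|
| source DOP | 0.15 | residual polarisation of the seed laser; modulates per-channel exit intensity by `1 + p·cos 2(a − a_s)` (normalized to 1 for an unpolarised source), never exit polarisation purity |
| couplings | 1 per pair (tests: log-normal, σ = 0.25) | true per-pair gains; the log-normal spread matches the ~1.1 ± 0.3 scatter of real calibration coefficients |
| fibre core / NA | 400 µm / 0.39 | multimode delivery fibres |
| pitch | 900 µm | centre-to-centre spacing: 400 µm core + ~500 µm printed holder wall |
| calibration angles | 0°, 30°, 60° | external-polariser orientations |
| noise | multiplicative Gaussian CV + constant dark floor, clamped at 0 | detector model; the study-condition noise level used in tests is CV = 1% |

Gains are defined per measurement pair (nine values) because the
calibration coefficients are per-pair; per-fibre configurations are
accepted and expanded to pairs by products.  Tissue-like samples are
composed in 4×4 as depolariser ∘ retarder ∘ weak diattenuator (with a
mirror double pass in reflection mode) with recorded ground-truth
parameters; retardance defaults are drawn from 10–170°, depolariser
factors from 0.3–1 — tissue-plausible ranges.

What the generator does **not** emulate: volumetric multiple scattering
(sampling-volume effects), holder-translucency cross-talk between
channels, source drift, and fibre-bend intensity dynamics over time.
Passing tests therefore demonstrate the correctness of the algebra,
calibration and decomposition under the stated noise model — not
robustness to those unmodelled physical effects.

## Calibration

The calibration sample is the external polariser double pass
`P(180° − θ) · M_mirror · P(θ)` at each session angle; the mirror is
always ideal, and independently measured 3×3 polariser matrices can
replace the ideal ones.  The nine coefficients minimize the mean
absolute element difference between the m11-normalized reconstruction
and the m11-normalized target over all angles.  Numerically this is a
smoothed-L1 (soft_l1) least-squares problem started at c = 1 with bounds
[0.1, 10]; it is deterministic, and at least two distinct angles are
required (one angle leaves nine unknowns under nine constraints with a
free normalization — underdetermined).

Normalization makes the objective invariant under global scaling of c,
so the gauge is fixed to mean(c) = 1 after the fit.  Any other gauge
yields identical normalized reconstructions; coefficient values are
therefore only comparable within a gauge.  Noiseless recovery is exact:
c comes out proportional to the reciprocal effective per-pair gains
(log-correlation 1 to machine precision), and a held-out sample then
reconstructs to solver precision.

## Polar decomposition (3×3)

Factor order is `M = M_Δ · M_R · M_D`, diattenuator extracted first from
the first row (`d = √(m12² + m13²)/m11`, 2×2 part
`√(1−d²) I + (1−√(1−d²)) D̂D̂ᵀ`).  After removing it,
`M′ = (M/m11)·M_D⁻¹` has first row `[1, 0, 0]`; its first column is the
polarizance (assigned to the depolariser) and its 2×2 block `N` carries
retarder and depolariser.

`N` is separated as `N = D·B` with `D = diag(a, b)` and
`B = cos δ·I + (1 − cos δ)·n n̂ᵀ`, the exact linear truncation of a
retarder (axis θ, retardance δ).  This is four equations in four
unknowns; substituting `t = 1 − cos δ`, `p = t sin²2θ`, `q = t cos²2θ`,
`u = t sin 2θ cos 2θ` reduces it to a quadratic in `u` with candidate
solutions validated by reconstruction residual.  For `D = I` this
reproduces the familiar closed forms
`δ = arccos(√((n11+n22)² + (n21−n12)²) − 1)` and
`θ = ¼·atan2(n12+n21, n11−n22)`, which are retained as the fallback for
matrices outside the exact model class (e.g. noisy measurements); there
the depolariser absorbs the residual, via a pseudo-inverse with
symmetrization when the retarder block is singular (|cos δ| < 1e−8).
arccos arguments are clamped to [−1, 1] with a warning when the excess
exceeds 1e−6.

Degenerate inputs: when the retarder axis is a multiple of 45° the block
`N` is diagonal and `(a, b, δ)` are not jointly identifiable.  Committed
conventions: two non-negative entries → a pure depolariser (δ = 0); one
negative entry → an isotropic depolariser times a retarder (this
reproduces the textbook reading of `diag(1, 1, −0.5)` as a 120°
measured retardance with no depolarisation).

Reported quantities: `δ_meas ∈ [0°, 180°]`; axis in `[0°, 90°)` with an
always-true ambiguity flag (a 0° and a 90° quarter-wave plate share one
3×3 block — the degeneracy is inherent, never silently resolved);
depolarisation `100·(1 − (|λ₁| + |λ₂|)/2)` from the eigenvalues of the
depolariser's 2×2 block (absolute values tolerate reflection-mode sign
structure); and `δ_phys = 180° − δ_meas`, the correction for the
geometric retardance contributed by the helicity flip.  That rule is
derived for retarders with fast or slow axis vertical or horizontal;
results carry a `delta_phys_applicable` flag (axis within 5° of a
cardinal direction) rather than extrapolating it to oblique axes.

## Numerical and design choices

* Angles are degrees everywhere, including on disk; axes canonicalized
  to [0°, 180°), B channels stored at 135° with a "−45" display alias.
* Generator closed forms are tested at 1e−12 absolute; reconstruction
  round trips at 1e−10; decomposition recovery at 1e−6.
* Forward-model intensities are clamped at 0 (a detector cannot report
  negative counts), so "random sample" properties use physically
  realizable matrices from the tissue generator.
* Matrix comparisons against the known polariser double pass are made on
  the convention where that sample has m11 = 0.50 (the raw double-pass
  scale), the scale on which real-probe element spreads of ±0.02 are
  quoted.
* Every stochastic path takes an explicit seed; CLI manifests echo it.
* Problem sizes in the property suites — 100 round-trip samples, 50
  calibration gain draws, 100 decomposition recoveries, 40-replicate
  noise Monte Carlo — were chosen to exercise the parameter space
  densely while keeping the full suite in the tens of seconds.

## Known limitations

* Only the linear 3×3 formalism is implemented: circular retardance /
  diattenuation and V-coupled effects are invisible, and the axis
  ambiguity modulo 90° cannot be lifted without quarter-wave channels.
* The depolariser factor is restricted to diagonal-plus-polarizance form
  in the exact branch; fully general symmetric depolarisers are only
  representable through the fallback path.
* No physical-realizability filtering of noisy Mueller estimates is
  applied before decomposition.
* The footprint model is a first-order NA cone on a fixed ring layout;
  it ignores refraction at the holder, polariser thickness and
  volumetric scattering.
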