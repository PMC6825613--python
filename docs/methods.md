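# Methods

`fibrepol` simulates and inverts the computational chain of a holographic
fibrescope: a multi-core imaging fibre (MCF) whose transmission matrix (TM)
is characterised in parallel by exploiting its near-diagonal structure, a
single-camera intensity detection scheme from which dual-polarisation
complex fields are reconstructed, Fresnel refocusing of the recovered
fields, and Bayesian inference of five per-pixel polarimetric parameters.
Everything runs against a synthetic fibre, so results quantify the
*computational* chain under controlled conditions.

## Optical model and units

All lengths are micrometres internally; the vacuum wavelength is stored in
nanometres (default 852 nm). Fields are sampled dual-polarisation complex
amplitudes on square grids whose coordinates are pixel centres with the
origin at the grid centre; polarisation component 0 is horizontal.

Free-space propagation uses the transfer-function evaluation of the Fresnel
diffraction integral: the spatial spectrum is multiplied by
`exp(i k z) exp(-i π λ z (fx² + fy²))`. This propagator is unitary at every
spatial frequency, hence conserves energy exactly and is inverted exactly by
propagating over `-z` — the property digital refocusing relies on. The
quadratic spectral phase must be adequately sampled: `|z| ≤ pitch · L / λ`
with `L` the grid side; violations raise an error naming the pitch (or
padding) required. Vectorial (high-NA) diffraction and partial coherence are
out of scope.

Polarisation states used for calibration and illumination are elliptical,
`(1, e^{iψ})/√2`, so both fibre polarisation channels carry equal power;
the default triple ψ ∈ {0, 2π/3, 4π/3} stacks into a perfectly conditioned
3×2 state matrix (condition number 1).

## Synthetic fibre

The fibre is a square lattice of single-mode cores: pitch 4.4 µm, core
diameter ≈ 2.9 µm, NA 0.35, 24 cores across by default (576 cores, a
desk-scale stand-in for the instrument's ≈ 6000; everything is
configurable). Each core carries a Gaussian fundamental mode (1/e radius
1.3 µm, from the standard V-parameter estimate at this geometry) and a
random unitary 2×2 Jones block: retardance ~ Normal(0, 0.5 rad), axis ~
Uniform(−π/2, π/2], global phase ~ Uniform(0, 2π). The distribution of
per-core birefringence in real fibres is not well characterised; this
sampling model is a stand-in that scrambles phase completely and
polarisation moderately. Nearest-neighbour cores optionally receive a
coupling amplitude (default 0.05, i.e. 0.25 % power per neighbour — "low
inter-core coupling"). The TM is assembled as `A = M B Mᴴ` with `M` the
unit-normalised mode-sampling matrix on a 2.25 µm pixel grid and `B` the
per-core blocks plus coupling. The grid pitch is one quarter of the 9 µm
calibration step so every calibration sample point coincides with a pixel
centre, and roughly half the core pitch.

Per row of `A`, at least 99 % of squared-magnitude mass falls within a
68.2 µm square window centred on the row's own coordinate (near-diagonality)
— the property the parallelised characterisation exploits.

Detection noise enters at the camera as additive Gaussian intensity noise,
expressed as a fraction of the frame's peak intensity and clipped at zero,
because the instrument records intensities; no field-level noise is added.

## Holographic acquisition (11 frames)

A full complex dual-polarisation image costs 11 intensity frames:

- **Through-focus stack (7 frames, H arm).** The V arm is diverted; the H
  field is recorded at seven defocus planes {−3…3} × 100 µm (symmetric
  ladder; the instrument's parabolic-mask strengths are not published, so
  the increment was chosen to give visibly distinct frames within the
  propagation sampling limit). Phase retrieval is serial multi-plane
  Gerchberg–Saxton: propagate plane-to-plane, replace amplitudes with
  measurements; initialisation is the in-focus amplitude with zero phase;
  stop at relative intensity residual < 1e-6, stagnation, or 200 sweeps.
  On noiseless core-structured fields the residual decreases monotonically
  and the recovered field correlates with truth to |ρ| ≈ 1.
- **Phase-shifting interferometry (4 frames).** Both arms pass a 45°
  analyser with V-arm phase steps {0, π/2, π, 3π/2}. The H–V phase is
  `atan2(I₃π/₂ − I_π/₂, I₀ − I_π)`; the V amplitude comes from the DC term
  `|V|² = I₀ + I_π − |H|²`, which avoids dividing by dim H pixels (the
  modulation-depth estimator degrades the noisy-field correlation by
  several points). Pixels with negligible H amplitude or modulation are
  flagged: the V phase is undefined there.

The recovered field carries an arbitrary piston; the gauge fixes the
brightest H pixel to zero phase. Slow inter-frame phase drift is corrected
by a dedicated *static* reference spot held in a facet corner throughout the
calibration sequence: one reference-only measurement is recorded, every
frame's global phase is aligned on the reference window, and the reference
contribution is subtracted before further processing. A drifted-and-
corrected calibration reproduces the drift-free metrics exactly.

## Parallelised TM characterisation

The calibration schedule translates an array of spots (default 12, on a 3×4
rectangular lattice at 68.2 µm spacing — the published count and spacing;
the lattice arrangement is our choice) through a 9×9 grid of 9 µm steps in
the 3 elliptical states: 243 raw measurements. Spots are Gaussian-apodised
separable sinc profiles (first zero at 4.5 µm, aperture σ 9 µm); the sinc
zeros fall on the translation lattice, so each distal sample position is
excited by exactly one (translation, state) triple per spot. Because spot
windows do not interact, each measurement splits into one characterisation
image per spot (nearest-spot window partition of side 68.2 µm, with a
warning flag when >10 % of a window's energy sits on its border): 12 × 243 =
2916 effective characterisation images resolving 12 × 81 = 972 distal
positions. The 9 µm step is kept as the default even though the core pitch
would support 4.5 µm, trading resolution for a 4× smaller problem.

Each row of the inverse TM (one distal position × polarisation) is recovered
independently: proximal samples (taken on a 4.5 µm sub-grid) within the
68.2 µm window around the row's coordinate form `Y_sub`, and

    min ‖a‖₁  subject to  ‖x_r − Y_subᵀ a‖₂ < δ

is solved by complex basis pursuit denoising, with δ = 0.05 ‖x_r‖₂ by
default (the residual weight is not published; 5 % matches the noiseless
simulation's model-mismatch floor). The solver (`fibrepol.sparse`) runs
FISTA with complex soft thresholding on the penalised subproblem, geometric
continuation in the penalty weight (warm-started, following the sparse
regularisation path), bisection onto the residual bound, and a final
least-squares debias on the recovered support — debiasing can only lower
the residual, so the bound still holds, and on noiseless sparse problems
the result equals least squares on the true support to 1e-6. Rows are
solved independently per polarisation; the 68.2 µm window takes precedence
over the slightly larger 72 µm scan span where they disagree.

With the spec-default δ the solver stops at the bound (median residual
≈ 0.02); driving δ to 1e-3 on noiseless data is feasible because the
windowed problems are underdetermined.

## Image recovery, refocusing, resolution

A measured proximal field is sampled at the inverse matrix's proximal
coordinates and multiplied through: the result lives on the scattered
resolvable distal positions. Single-spot schedules yield a regular 9 µm
grid, placed exactly; general scatterings are gridded nearest-neighbour for
metrics (no smoothing bias) and bilinearly for display only.

Refocusing places each recovered sample at its exact physical coordinate on
a fine odd-sized grid (half the sampling step), interpolates with an ideal
low-pass at the original sampling band, and back-propagates with the Fresnel
propagator. (An earlier spectral-zero-padding upsampler misaligned the DC
bin for odd-to-even sizes, laterally shifting refocused images — the
coordinate-exact placement removes the whole class of bug.)

Resolution uses three-bar targets: per bar group, the intensity profile is
averaged along the bars over a ±18 µm band, read at the expected bar and
gap centres (nearest pixel), and the contrast `(I_bar − I_gap)/(I_bar +
I_gap)` is **signed**: contrast-reversed bars — the phase-reversal
pseudo-resolution familiar from coherent defocus — count as zero, not as
resolved structure. Recovered intensities are flat-fielded by the known
illumination envelope before reading. The resolution is the bar width at
the first downward crossing of contrast 0.3, linearly interpolated in bar
width, with half the bracketing-width spacing as its uncertainty; a curve
that never crosses is "beyond the measured range". The bar ladder
{13.5, 12, 10.5, 9, 7.5, 6} µm fits the 72 µm field of view scanned by one
spot.

Study conditions for the scaled resolution experiment: 576-core fibre at
the nominal pitch/NA, single-spot 9×9/9 µm schedule (the parallelisation
count does not affect resolution and the desk-scale facet cannot host the
12-spot array), Gaussian illumination of 60 µm waist on a 257² grid,
noiseless ideal detection. Measured: 7.2 µm at contact, 12.6 µm uncorrected
at 250 µm working distance, 9.3 µm refocused at 1 mm; refocused resolution
stays within one 9 µm sampling step of the contact value across 0.25–1 mm.
The uncorrected-degradation monotonicity property is probed at working
distances ≤ 300 µm, before coherent contrast reversals invalidate the
scalar crossing.

## Polarimetric inference

Each sample pixel is an elliptical retarder followed by a partial linear
polariser, `J = A_pol(D, θ_D) · A_ret(φ, θ_φ, δ)`, with ranges θ_φ, θ_D ∈
(−π/2, π/2], φ, δ ∈ (−π, π], D ∈ [−1, 1]. Measurements in n ≥ 2 states
(default 3) are modelled as `v_k ~ CN(J u_k, σ² I)` with one unknown global
phase per pixel profiled out analytically, so the posterior is invariant
under a global phase of the measurement set — the piston left over from
acquisition is harmless. σ is fixed at 0.4 during inference (relative to
unit-norm illumination states) rather than inferred, for speed. Priors:
flat (von Mises κ → 0; "broadest possible" is read as the flat limit, since
κ → ∞ would be the narrowest) for θ_D, θ_φ, φ; von Mises κ = 1 for δ to
damp over-fitting of circularity; truncated Gaussian (mean 0, variance 5)
on [−1, 1] for D.

MAP estimation is bounded L-BFGS from eight deterministic starts — the
degeneracy-class members of a closed-form initialiser obtained by least
squares for J followed by polar decomposition (`A_pol` from the Hermitian
factor, the retarder parameters from the unitary factor), exact for
noiseless in-class data. The decomposition has an exact 8-fold degeneracy;
`canonicalise` returns the class member closest to the reference point
(θ_φ = π/4, φ = π, δ = 0, D = 1, θ_D = π/4), with circular distances
(period π for axes, 2π for φ and δ) and absolute distance for D. Quarter-
wave retarders sit exactly between two class members in this metric, so
spatially uniform regions remain uniform but the representative an image
region lands on is tie-dependent; comparisons in tests are class-aware.

**Misalignment correction.** A small angular misalignment between the two
polarisation arms imprints a linear phase ramp on one measured component;
for a birefringent sample whose axes are not aligned with the arms this
masquerades as spatially varying retardance. Joint inference over a
neighbourhood of R = 15 pixels (5×3 tiles) shares two quantities across
the neighbourhood: the retardance-axis angle θ̂_φ (the rotated basis in
which the sample retarder is diagonal, taking the place of θ_φ; the
circularity δ drops out of the rotated model) and the common inter-arm ramp
slope (2 parameters, rad/µm). Sharing the axis alone was implemented first
and measured to reduce the injected-ramp artefact only ≈ 2×: the rotated
parameterisation cannot represent a one-arm ramp, which is an axis-aligned
retarder multiplying from the left. Estimating the common ramp jointly —
which is the physical description of the misalignment — removes the
artefact to numerical precision while leaving tilt-free data untouched
(the ramp estimate returns to zero and the joint result matches per-pixel
inference). Per (θ̂_φ, ramp) candidate the remaining (D, θ_D, φ) are fitted
per pixel by a closed-form grid/least-squares fit plus an L-BFGS polish,
and the per-pixel log posteriors are summed (the factorised-posterior
approximation); among candidates within 2 log units of the maximum the one
minimising the spatial tilt of the retardance is selected. For φ → 0 the
axis posterior flattens (circular spread > 1 rad), as expected for a
vanishing retarder.

**Recovery-error conditions.** Synthetic recovery experiments draw ground
truth from the inference priors restricted to the identifiable regime:
|D| ≤ 0.7 (a near-complete polariser extinguishes one axis and hides the
retarder behind it), |φ| ∈ [0.4, 2.7] (a vanishing retarder has an
undefined axis; φ ≈ π sits on the wrap boundary), axes 0.2 rad from range
edges, δ from its prior. At σ = 0.4 with n = 3, measured over 500 pixels:
RMS ΔD = 0.185 and median Δφ = 0.26 rad; the Δφ *RMS* is 0.43 because the
posterior at this noise level has heavy tails (verified not to be an
optimiser artefact: no pixel's MAP fell below the true-class posterior).
The monitoring test therefore bounds RMS ΔD ≤ 0.2, median Δφ ≤ 0.4 and RMS
Δφ ≤ 0.55. Using three states instead of two reduces the median recovery
error (probed at σ = 0.2, where the effect is well resolved). Noiseless
recovery is tested in the likelihood-dominated configuration (small σ, flat
priors) and is exact to < 1e-2 after canonicalisation.

## What the synthetic study does and does not show

The generator reproduces the geometry, sampling, frame budget and noise
entry point of the instrument, so passing tests validate the algorithms and
their interactions at desk scale. It does not emulate: real per-core
birefringence statistics, bending dynamics, SLM hologram-generation
artefacts (distal fields are specified directly), detector nonlinearity or
shot noise, mode-resolved waveguide physics, or stitching of translated
tiles. Quantities that depend on the physical instrument — absolute phase
error, the 36 µm polarimetric resolution, acquisition timings — are outside
what this simulation can certify; the polarimetric error bands above are
monitored for order-of-magnitude consistency only.

## Known limitations

- The full-chain recovery at 1 % camera noise is bounded by the 11-frame
  budget: the PSI-derived V component reaches |ρ| ≈ 0.91, and inverse-TM
  application amplifies the structured acquisition error (full-chain
  |ρ| ≈ 0.6). Noise-robust imaging would need more frames or regularised
  inversion.
- The single-scalar MTF-0.3 resolution is unreliable in the defocus
  contrast-reversal regime (uncorrected working distances ≳ 300 µm at this
  geometry); the signed contrast estimator suppresses pseudo-resolution but
  cannot restore a meaningful ordering there.
- Joint polarimetric inference assumes the misalignment ramp is common to a
  neighbourhood and the retardance axis locally constant; structure finer
  than the 15-pixel tile is low-pass filtered, which is the mechanism by
  which polarimetric resolution falls below field-recovery resolution.
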