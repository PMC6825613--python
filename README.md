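# fibrepol

Simulation and reconstruction toolkit for a **holographic fibrescope**:
quantitative phase and polarisation-resolved imaging through a multi-core
imaging fibre (MCF), for researchers in computational endoscopy and
wavefront shaping who want to study the reconstruction chain without the
optical bench.

Flexible imaging fibres scramble the phase and polarisation of light, so
conventional fibre endoscopes are amplitude-only. The scrambling is linear:
a transmission matrix (TM) `A` maps the field at the distal facet to the
proximal facet, `y = A x`. For an MCF, `A` is *near-diagonal* in a pixel
basis — light stays within its core neighbourhood — and this package
implements the full computational chain built on that structure:

- **Parallelised sparse TM characterisation.** An array of spots is scanned
  over a 9×9 grid of 9 µm steps in 3 elliptical polarisation states (243
  measurements); near-diagonality lets every frame be split into one
  characterisation image per spot (12 × 243 = 2916) resolving 972 distal
  positions. Each row `a_r` of `A⁻¹` is recovered independently from
  samples inside a 68.2 µm locality window by basis pursuit denoising,
  `min ‖a_r‖₁ s.t. ‖x_rᵀ − Y_subᵀ a_rᵀ‖₂ < δ` (complex FISTA +
  continuation solver in `fibrepol.sparse`).
- **Single-camera complex-field acquisition.** 11 intensity frames per
  image: a 7-frame through-focus stack with multi-plane iterative phase
  retrieval for one polarisation arm, then 4-step phase-shifting
  interferometry through a 45° analyser for the other, plus static-
  reference phase-drift correction.
- **Fresnel refocusing.** The recovered distal field is numerically
  back-propagated (unitary transfer-function propagator) to correct
  working-distance defocus; resolution is quantified by the bar-target
  MTF with a contrast-0.3 threshold.
- **Bayesian polarimetry.** Per pixel, the sample Jones matrix is
  decomposed as an elliptical retarder followed by a partial polariser,
  `J = A_pol(D, θ_D) · A_ret(φ, θ_φ, δ)`, and the five parameters are
  MAP-estimated under a complex-Gaussian likelihood `v ~ CN(Ju, σ²I)` with
  von Mises / truncated-Gaussian priors. The decomposition's exact 8-fold
  degeneracy is canonicalised, and joint inference over 15-pixel
  neighbourhoods removes the inter-arm misalignment artefact.

A synthetic 576-core fibre (4.4 µm pitch, NA 0.35, 852 nm) with random
per-core unitary Jones blocks stands in for the hardware, so the whole
chain runs end to end from nothing. See `docs/methods.md` for the model,
parameter choices and limitations.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```sh
$ python examples/03_tm_calibration.py
full schedule bookkeeping: 243 raw inputs, 2916 characterisation fields, 972 distal samples
scaled run: {'raw_inputs': 75, 'characterisation_fields': 75, 'distal_samples': 25}, median row residual 0.019 (bound 0.05 ||x_r||)
forward -> inverse recovery correlation |rho| = 0.9998
```

The bookkeeping line is the exact parallelisation arithmetic of the full
schedule; the scaled run characterises the synthetic fibre with a single
spot on a 5×5 grid, and the final line shows that forward imaging followed
by the recovered inverse reproduces distal fields essentially perfectly on
the resolvable sampling.

```sh
$ python examples/05_polarimetry.py
clean quarter-wave plate at 45 deg, MAP estimate (canonicalised):
  theta_phi +0.785  phi +1.571  delta +0.000  D -0.000  theta_D +1.546 rad
injected arm tilt 0.02 rad/µm:
  per-pixel retardance gradient 0.0035 rad/µm (artefact)
  joint inference gradient      0.000000 rad/µm, estimated ramp [0.02 0.  ] rad/µm
```

The retarder parameters (axis π/4, retardance π/2) are recovered exactly
(θ_D is undefined at D = 0 and lands on an arbitrary value); the injected
arm-misalignment ramp produces a spurious retardance gradient in per-pixel
fits which the joint neighbourhood inference removes while estimating the
ramp itself.

`examples/04_refocusing_resolution.py` calibrates the fibre and measures
bar-target resolution at the facet (≈ 7.2 µm at MTF 0.3) and at 1 mm
working distance, where defocus destroys the bars and numerical refocusing
of the recovered complex field restores ≈ 9.3 µm.

A thin CLI wraps the pipeline: `fibrepol simulate`, `fibrepol calibrate`,
`fibrepol image`, `fibrepol run-all --config cfg.yaml --out report.json`.

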