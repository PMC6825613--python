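"""Recovering the dual-polarisation complex proximal field from intensities.

One full complex, dual-polarisation image costs 11 camera frames: a 7-frame
through-focus stack of the H arm (multi-plane iterative phase retrieval
recovers the H field up to a piston) followed by 4 phase-shifting
interferometry frames in which the V arm is stepped against the H arm through
a 45° analyser (recovering the V amplitude and the H–V phase relationship).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import OpticalField, fresnel_propagate
from .fibre import camera_frame

__all__ = ["ThroughFocusStack", "PsiFrameSet", "simulate_stack",
           "phase_retrieve", "psi_combine", "correct_phase_drift",
           "acquire_field", "FRAME_BUDGET", "DEFAULT_DEFOCUS_STEP"]

#: Camera frames per full amplitude/phase/polarisation image: 7 + 4.
FRAME_BUDGET = 11

#: Default defocus increment (µm) between adjacent through-focus frames.
DEFAULT_DEFOCUS_STEP = 100.0


def default_defocus_coeffs(step: float = DEFAULT_DEFOCUS_STEP) -> np.ndarray:
    """Seven symmetric propagation distances {-3..3} * step (µm)."""
    return np.arange(-3, 4) * step


@dataclass
class ThroughFocusStack:
    """K defocused intensity frames of one polarisation arm."""

    frames: np.ndarray            # (K, ny, nx), >= 0
    defocus: np.ndarray           # (K,) propagation distances, µm
    pixel_pitch: float
    wavelength_nm: float
    arm: str = "H"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.defocus = np.asarray(self.defocus, dtype=float)
        if self.frames.ndim != 3 or len(self.frames) != len(self.defocus):
            raise ValueError("frames and defocus coefficients disagree")
        if len(self.frames) < 2:
            raise ValueError("a through-focus stack needs at least 2 frames")
        if (self.frames < 0).any():
            raise ValueError("intensities must be non-negative")
        if len(np.unique(self.defocus)) != len(self.defocus):
            raise ValueError("defocus coefficients must be distinct")


@dataclass
class PsiFrameSet:
    """Four analyser-mixed intensity frames at known phase steps."""

    frames: np.ndarray            # (4, ny, nx)
    steps: np.ndarray = dc_field(
        default_factory=lambda: np.array([0.0, np.pi / 2, np.pi,
                                          3 * np.pi / 2]))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.steps = np.asarray(self.steps, dtype=float)
        if self.frames.shape[0] != 4 or self.steps.shape != (4,):
            raise ValueError("PSI requires exactly 4 frames and 4 steps")
        d = np.sort(self.steps % (2 * np.pi))
        if (np.diff(d) < 1e-9).any():
            raise ValueError("phase steps must be distinct modulo 2*pi")


def _pad_field(field: OpticalField, pad_to: int) -> OpticalField:
    ny, nx = field.shape
    if pad_to < max(ny, nx):
        raise ValueError("pad size smaller than field")
    out = np.zeros((2, pad_to, pad_to), dtype=complex)
    oy, ox = (pad_to - ny) // 2, (pad_to - nx) // 2
    out[:, oy:oy + ny, ox:ox + nx] = field.data
    return OpticalField(out, field.pixel_pitch, field.wavelength_nm,
                        field.origin)


def simulate_stack(proximal: OpticalField, defocus=None,
                   noise_sigma: float = 0.0, seed: int = 0, arm: str = "H",
                   pad_to: int | None = None) -> ThroughFocusStack:
    """Record a through-focus stack of one polarisation arm.

    The other arm is diverted (contributes nothing).  The field is embedded
    in a larger camera window (``pad_to``, default 2x grid rounded up to a
    multiple of 32) so defocused light stays inside the frame.
    """
    if defocus is None:
        defocus = default_defocus_coeffs()
    defocus = np.asarray(defocus, dtype=float)
    ny, nx = proximal.shape
    if pad_to is None:
        pad_to = int(np.ceil(2 * max(ny, nx) / 32)) * 32
    padded = _pad_field(proximal, pad_to)
    frames = []
    for k, dz in enumerate(defocus):
        at_z = fresnel_propagate(padded, dz)
        frames.append(camera_frame(at_z, {"analyser_deg": None, "arm": arm},
                                   noise_sigma, seed + 1000 * k))
    return ThroughFocusStack(np.stack(frames), defocus, proximal.pixel_pitch,
                             proximal.wavelength_nm, arm)


def phase_retrieve(stack: ThroughFocusStack, max_iter: int = 200,
                   tol: float = 1e-6) -> dict:
    """Multi-plane iterative projection phase retrieval.

    Serial Gerchberg–Saxton-type sweeps: starting from the in-focus amplitude
    with zero phase, the estimate is propagated plane-to-plane and its
    amplitude replaced by the measured one at each plane.  Stops when the
    relative intensity residual falls below ``tol`` or after ``max_iter``
    sweeps.  The returned field is referred to the z = 0 plane and re-phased
    so its brightest pixel has zero phase (piston gauge).

    Returns dict with ``field`` (complex ndarray), ``residual``, ``history``
    (per-sweep residuals, non-increasing for noiseless data) and
    ``converged``.
    """
    amps = np.sqrt(np.clip(stack.frames, 0.0, None))
    K = len(amps)
    order = np.argsort(stack.defocus)
    lam = stack.wavelength_nm * 1e-3

    def prop(f, z):
        wrapped = OpticalField(np.stack([f, np.zeros_like(f)]),
                               stack.pixel_pitch, stack.wavelength_nm)
        return fresnel_propagate(wrapped, z).data[0]

    k0 = order[np.argmin(np.abs(stack.defocus[order]))]
    f = amps[k0].astype(complex)
    z_cur = stack.defocus[k0]
    history = []
    converged = False
    total = float((amps ** 2).sum())
    for sweep in range(max_iter):
        resid = 0.0
        for k in list(order) + list(order[::-1][1:]):
            z_next = stack.defocus[k]
            f = prop(f, z_next - z_cur)
            z_cur = z_next
            mag = np.abs(f)
            resid += float(((mag ** 2 - amps[k] ** 2) ** 2).sum())
            phase = np.where(mag > 0, f / np.where(mag > 0, mag, 1.0), 1.0)
            f = amps[k] * phase
        resid = np.sqrt(resid / (2 * K - 1)) / max(total / K, 1e-300)
        history.append(resid)
        if resid < tol:
            converged = True
            break
        if len(history) > 5 and resid > 0.999 * history[-2]:
            break     # stagnated (noisy data)
    f = prop(f, -z_cur)
    peak = np.unravel_index(np.argmax(np.abs(f)), f.shape)
    f = f * np.exp(-1j * np.angle(f[peak]))
    return {"field": f, "residual": history[-1] if history else np.inf,
            "history": np.array(history), "converged": converged}


def psi_combine(retrieved_h: np.ndarray, frames: PsiFrameSet,
                min_h_fraction: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the dual-polarisation field from 4-step PSI frames.

    With steps {0, pi/2, pi, 3pi/2} and camera intensity
    ``I_s = |E_H + E_V e^{is}|^2 / 2`` the relative phase is
    ``Delta = atan2(I_{3pi/2} - I_{pi/2}, I_0 - I_pi)`` (phase of H* V); the
    V amplitude comes from the DC term, ``|E_V|^2 = I_0 + I_pi - |E_H|^2``,
    which avoids dividing by dim H pixels.

    Returns ``(field, flags)`` where ``field`` has shape (2, ny, nx) and
    ``flags`` marks pixels whose H amplitude (hence the recovered V phase
    reference) or modulation depth is negligible; V keeps its DC amplitude
    there but its phase is undefined and set to the H phase.
    """
    steps_ref = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    if not np.allclose(np.sort(frames.steps % (2 * np.pi)), steps_ref):
        raise ValueError("psi_combine expects steps {0, pi/2, pi, 3pi/2}")
    idx = [int(np.argmin(np.abs((frames.steps - s + np.pi) % (2 * np.pi)
                                - np.pi))) for s in steps_ref]
    i0, i1, i2, i3 = (frames.frames[i] for i in idx)
    delta = np.arctan2(i3 - i1, i0 - i2)
    amp_h = np.abs(retrieved_h)
    amp_v = np.sqrt(np.clip(i0 + i2 - amp_h ** 2, 0.0, None))
    modulation = 0.5 * np.hypot(i0 - i2, i3 - i1)   # = |E_H||E_V|
    small = (amp_h < min_h_fraction * max(amp_h.max(), 1e-300)) | \
            (modulation < (min_h_fraction * max(amp_h.max(), 1e-300)) ** 2)
    e_v = amp_v * np.exp(1j * (np.angle(retrieved_h)
                               + np.where(small, 0.0, delta)))
    return np.stack([retrieved_h, e_v]), small


def simulate_psi(proximal: OpticalField, noise_sigma: float = 0.0,
                 seed: int = 0) -> PsiFrameSet:
    """Record the 4 phase-shifting frames through the 45° analyser."""
    steps = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    frames = [camera_frame(proximal, {"analyser_deg": 45.0, "phase_V": s},
                           noise_sigma, seed + 2000 * k)
              for k, s in enumerate(steps)]
    return PsiFrameSet(np.stack(frames), steps)


def acquire_field(proximal: OpticalField, noise_sigma: float = 0.0,
                  seed: int = 0, defocus=None, max_iter: int = 200) -> dict:
    """Full 11-frame holographic acquisition of a proximal field.

    Simulates the 7-frame through-focus stack (H arm), retrieves the H phase,
    then simulates the 4 PSI frames and assembles the dual-polarisation
    field.  Returns dict with ``field`` (OpticalField on the original grid),
    ``n_frames``, ``flags`` and the phase-retrieval diagnostics.
    """
    ny, nx = proximal.shape
    stack = simulate_stack(proximal, defocus, noise_sigma, seed, arm="H")
    pr = phase_retrieve(stack, max_iter=max_iter)
    pad = stack.frames.shape[-1]
    oy, ox = (pad - ny) // 2, (pad - nx) // 2
    h_rec = pr["field"][oy:oy + ny, ox:ox + nx]
    psi = simulate_psi(proximal, noise_sigma, seed + 17)
    data, flags = psi_combine(h_rec, psi)
    field = OpticalField(data, proximal.pixel_pitch, proximal.wavelength_nm,
                         proximal.origin)
    return {"field": field, "n_frames": len(stack.frames) + len(psi.frames),
            "flags": flags, "phase_retrieval": pr}


def correct_phase_drift(measurements, reference_region,
                        min_power: float = 1e-12):
    """Align the global phase of a measurement sequence on a static reference.

    ``reference_region`` is a boolean mask (or index tuple) selecting pixels
    whose true field is constant across the sequence (e.g. a calibration spot
    held fixed).  Every measurement is multiplied by the unit phase that
    aligns its reference inner product with the first measurement; the first
    measurement is returned unchanged.
    """
    if not measurements:
        return []
    ref0 = measurements[0].data[:, reference_region] \
        if isinstance(reference_region, np.ndarray) \
        else measurements[0].data[(slice(None),) + tuple(reference_region)]
    if float(np.sum(np.abs(ref0) ** 2)) < min_power:
        raise ValueError("reference region carries no power")
    out = [measurements[0].copy()]
    for m in measurements[1:]:
        ref = m.data[:, reference_region] \
            if isinstance(reference_region, np.ndarray) \
            else m.data[(slice(None),) + tuple(reference_region)]
        if float(np.sum(np.abs(ref) ** 2)) < min_power:
            raise ValueError("reference region carries no power")
        inner = np.vdot(ref0, ref)
        corr = m.copy()
        corr.data *= np.exp(-1j * np.angle(inner))
        out.append(corr)
    return out
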