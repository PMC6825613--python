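"""Synthetic multi-core fibre: ground-truth transmission matrix, test targets
and raw camera frames.

The simulated fibre is a square lattice of single-mode cores (pitch 4.4 µm,
core diameter ~2.9 µm, NA ~0.35 at 852 nm).  Each core carries a random
unitary 2x2 Jones block — a retarder with normally distributed retardance and
uniform axis — times a uniform random global phase, so the fibre preserves
approximate image geometry while scrambling phase and polarisation.  Optional
nearest-neighbour amplitude coupling makes the matrix slightly less diagonal.
Pixel-basis sampling uses a grid pitch of 2.25 µm, one quarter of the 9 µm
calibration translation step, so calibration sample points land exactly on
grid pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import tifffile

from .fields import OpticalField, fresnel_propagate, jones_apply, identity_jones_map
from .transmission import TransmissionMatrix, sample_field_at, values_to_field

__all__ = ["FibreSpec", "SampleMap", "build_fibre_tm", "make_target",
           "image_sample", "camera_frame", "inject_arm_tilt",
           "DEFAULT_PIXEL_PITCH"]

#: Grid pitch (µm) used for facet sampling: 9 µm / 4, ~half the core pitch.
DEFAULT_PIXEL_PITCH = 2.25


@dataclass
class FibreSpec:
    """Geometry and statistics of the synthetic multi-core fibre."""

    core_pitch: float = 4.4            # µm
    core_diameter: float = 2.9         # µm
    n_cores_across: int = 24           # square lattice side (desk scale)
    numerical_aperture: float = 0.35
    wavelength_nm: float = 852.0
    coupling_fraction: float = 0.05    # amplitude leaked to each neighbour
    birefringence_scale: float = 0.5   # rad, std of per-core retardance
    mode_field_radius: float = 1.3     # µm, fundamental-mode 1/e radius
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.core_pitch > self.core_diameter > 0):
            raise ValueError("need core_pitch > core_diameter > 0")
        if not (0 < self.numerical_aperture < 1):
            raise ValueError("NA must be in (0, 1)")
        if not (0 <= self.coupling_fraction < 0.5):
            raise ValueError("coupling_fraction must be in [0, 0.5)")

    @property
    def facet_half_span(self) -> float:
        return self.n_cores_across * self.core_pitch / 2

    def core_positions(self) -> np.ndarray:
        n = self.n_cores_across
        axis = (np.arange(n) - (n - 1) / 2) * self.core_pitch
        xx, yy = np.meshgrid(axis, axis)
        return np.column_stack([xx.ravel(), yy.ravel()])


def _facet_grid(spec: FibreSpec, pixel_pitch: float, margin: float):
    half = spec.facet_half_span + margin
    n = int(np.ceil(2 * half / pixel_pitch))
    n += (n + 1) % 2      # odd pixel count keeps a pixel centred at origin
    axis = (np.arange(n) - (n - 1) / 2) * pixel_pitch
    return axis, n


def build_fibre_tm(spec: FibreSpec, pixel_pitch: float = DEFAULT_PIXEL_PITCH,
                   margin: float = 2.25) -> TransmissionMatrix:
    """Ground-truth forward transmission matrix on a facet pixel grid.

    ``A = M B M^H`` where ``M`` maps per-core mode amplitudes to grid pixels
    (Gaussian fundamental mode, unit-normalised columns) and ``B`` holds the
    per-core unitary Jones blocks plus nearest-neighbour amplitude coupling.
    Deterministic under ``spec.seed``.  The returned matrix carries the mode
    matrix and core data in ``meta`` for structural tests.
    """
    rng = np.random.default_rng(spec.seed)
    cores = spec.core_positions()
    n_cores = len(cores)
    axis, n = _facet_grid(spec, pixel_pitch, margin)
    xx, yy = np.meshgrid(axis, axis)
    pix = np.column_stack([xx.ravel(), yy.ravel()])

    # scalar mode-coupling matrix M (n_pix x n_cores), Gaussian modes
    w = spec.mode_field_radius
    rows, cols, vals = [], [], []
    cut = 3.0 * w
    for c, (cx, cy) in enumerate(cores):
        d2 = (pix[:, 0] - cx) ** 2 + (pix[:, 1] - cy) ** 2
        idx = np.flatnonzero(d2 <= cut * cut)
        amp = np.exp(-d2[idx] / (2 * w * w))
        amp = amp / np.linalg.norm(amp)
        rows.extend(idx)
        cols.extend([c] * len(idx))
        vals.extend(amp)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(len(pix), n_cores))

    # per-core random unitary Jones block x global phase
    retard = rng.normal(0.0, spec.birefringence_scale, n_cores)
    axis_ang = rng.uniform(-np.pi / 2, np.pi / 2, n_cores)
    phase = rng.uniform(0.0, 2 * np.pi, n_cores)
    jones = np.empty((n_cores, 2, 2), dtype=complex)
    for c in range(n_cores):
        ca, sa = np.cos(axis_ang[c]), np.sin(axis_ang[c])
        R = np.array([[ca, sa], [-sa, ca]])
        Dp = np.diag([np.exp(1j * retard[c] / 2), np.exp(-1j * retard[c] / 2)])
        jones[c] = np.exp(1j * phase[c]) * (R @ Dp @ R.T)

    # core-to-core amplitude coupling (4-neighbour square lattice)
    cf = spec.coupling_fraction
    K = sp.identity(n_cores, format="lil", dtype=complex)
    if cf > 0:
        nc = spec.n_cores_across
        for c in range(n_cores):
            iy, ix = divmod(c, nc)
            nbrs = [(iy + dy, ix + dx) for dy, dx in
                    ((1, 0), (-1, 0), (0, 1), (0, -1))
                    if 0 <= iy + dy < nc and 0 <= ix + dx < nc]
            K[c, c] = np.sqrt(max(1 - cf * cf * len(nbrs), 0.0))
            for (jy, jx) in nbrs:
                K[c, jy * nc + jx] = cf
    K = K.tocsr()

    # B: (2 n_cores x 2 n_cores) block matrix, K applied after per-core Jones
    J_block = sp.block_diag([sp.csr_matrix(j) for j in jones], format="csr")
    K2 = sp.kron(K, sp.identity(2, format="csr"), format="csr")
    B = (K2 @ J_block).tocsr()

    M2 = sp.kron(M, sp.identity(2, format="csr"), format="csr")
    A = (M2 @ B @ M2.conj().T).tocsr()
    A.eliminate_zeros()

    meta = {"pixel_pitch": pixel_pitch, "grid_n": n}
    tm = TransmissionMatrix(A, pix, pix, "forward", meta=meta)
    tm.mode_matrix = M
    tm.core_blocks = B
    tm.core_positions = cores
    tm.grid_shape = (n, n)
    tm.pixel_pitch = pixel_pitch
    tm.wavelength_nm = spec.wavelength_nm
    return tm


# ---------------------------------------------------------------------------
# Test targets
# ---------------------------------------------------------------------------

@dataclass
class SampleMap:
    """Per-pixel ground-truth Jones matrix plus scalar transmittance."""

    jones: np.ndarray          # (ny, nx, 2, 2)
    transmittance: np.ndarray  # (ny, nx) in [0, 1]
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.jones = np.asarray(self.jones, dtype=complex)
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        if self.jones.shape[:2] != self.transmittance.shape:
            raise ValueError("jones and transmittance grids differ")
        if (self.transmittance < 0).any() or (self.transmittance > 1).any():
            raise ValueError("transmittance must lie in [0, 1]")
        if not np.all(np.isfinite(self.jones)):
            raise ValueError("non-finite Jones entries")

    def effective_jones(self) -> np.ndarray:
        return self.jones * self.transmittance[..., None, None]

    def to_tiff(self, path: str) -> None:
        """Write |J| entries and transmittance as image planes."""
        planes = np.concatenate([
            np.abs(self.jones).reshape(self.jones.shape[:2] + (4,)),
            self.transmittance[..., None]], axis=-1)
        tifffile.imwrite(path, planes.astype(np.float32).transpose(2, 0, 1))


def _bar_mask(shape, pixel_pitch, bar_width, n_bars=3, orientation="vertical",
              center=(0.0, 0.0)):
    """Boolean foreground mask of n_bars bars of given width (µm), period
    2*bar_width, bars running along y for 'vertical' orientation."""
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2) * pixel_pitch - center[0]
    y = (np.arange(ny) - (ny - 1) / 2) * pixel_pitch - center[1]
    u = x if orientation == "vertical" else y
    span = (2 * n_bars - 1) * bar_width
    rel = u + span / 2
    in_group = (rel >= 0) & (rel < span)
    bar = (np.floor(rel / bar_width).astype(int) % 2 == 0) & in_group
    mask1d = bar
    if orientation == "vertical":
        return np.broadcast_to(mask1d[None, :], shape).copy()
    return np.broadcast_to(mask1d[:, None], shape).copy()


def make_target(kind: str, shape: tuple[int, int],
                pixel_pitch: float = DEFAULT_PIXEL_PITCH,
                bar_width: float = 9.0, n_bars: int = 3,
                orientation: str = "vertical", center=(0.0, 0.0),
                phi0: float = np.pi / 2, theta0: float = 0.0,
                background_transmittance: float = 0.0) -> SampleMap:
    """Construct a synthetic polarimetric test target.

    Kinds
    -----
    ``bars``
        Amplitude-only contrast: transmittance 1 on the bars,
        ``background_transmittance`` elsewhere; identity Jones.
    ``birefringent_bars``
        Uniform retarder of retardance ``phi0`` everywhere; retardance axis
        0° on the bars, 45° in the background (contrast only in theta_phi).
    ``diattenuation_bars``
        Ideal polariser (D = 1) everywhere; axis 0° on the bars, 90° in the
        background (contrast only in theta_D).
    ``flat_slide``
        Identity Jones, unit transmittance.
    ``waveplate``
        Uniform retarder (phi0, axis theta0).
    """
    from .polarimetry import PolarimetricParams, jones_forward

    trans = np.ones(shape)
    jones = identity_jones_map(shape)
    if kind == "bars":
        mask = _bar_mask(shape, pixel_pitch, bar_width, n_bars, orientation,
                         center)
        trans = np.where(mask, 1.0, background_transmittance)
    elif kind == "birefringent_bars":
        mask = _bar_mask(shape, pixel_pitch, bar_width, n_bars, orientation,
                         center)
        j_fg = jones_forward(PolarimetricParams(0.0, phi0, 0.0, 0.0, 0.0))
        j_bg = jones_forward(PolarimetricParams(np.pi / 4, phi0, 0.0, 0.0, 0.0))
        jones = np.where(mask[..., None, None], j_fg, j_bg)
    elif kind == "diattenuation_bars":
        mask = _bar_mask(shape, pixel_pitch, bar_width, n_bars, orientation,
                         center)
        j_fg = jones_forward(PolarimetricParams(0.0, 0.0, 0.0, 1.0, 0.0))
        j_bg = jones_forward(PolarimetricParams(0.0, 0.0, 0.0, 1.0, np.pi / 2))
        jones = np.where(mask[..., None, None], j_fg, j_bg)
    elif kind == "flat_slide":
        pass
    elif kind == "waveplate":
        jw = jones_forward(PolarimetricParams(theta0, phi0, 0.0, 0.0, 0.0))
        jones = np.broadcast_to(jw, shape + (2, 2)).copy()
    else:
        raise ValueError(f"unknown target kind: {kind!r}")
    return SampleMap(jones, trans, pixel_pitch)


# ---------------------------------------------------------------------------
# Forward imaging and detection
# ---------------------------------------------------------------------------

def image_sample(tm: TransmissionMatrix, sample: SampleMap,
                 illumination: OpticalField,
                 working_distance: float = 0.0) -> OpticalField:
    """Noise-free forward model: proximal field ``y = A x``.

    The illumination passes through the sample (per-pixel Jones times
    transmittance), propagates ``working_distance`` µm to the distal facet,
    is sampled at the transmission matrix's distal coordinates, and is mapped
    through the fibre.  Returns the proximal field on the facet grid.
    """
    if not np.isclose(sample.pixel_pitch, illumination.pixel_pitch):
        raise ValueError("sample and illumination pixel pitch differ")
    if sample.jones.shape[:2] != illumination.shape:
        raise ValueError("sample and illumination grids differ")
    modulated = jones_apply(sample.effective_jones(), illumination)
    at_facet = fresnel_propagate(modulated, working_distance)
    x = sample_field_at(at_facet, tm.distal_coords)
    y = tm.apply(x)
    shape = getattr(tm, "grid_shape", None)
    if shape is None:
        raise ValueError("transmission matrix lacks grid metadata")
    return values_to_field(y, tm.proximal_coords, shape, tm.pixel_pitch,
                           illumination.wavelength_nm)


def camera_frame(proximal: OpticalField, analyser_chain: dict | None = None,
                 noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Simulated camera intensity after the analyser/SLM chain.

    ``analyser_chain`` keys (all optional):

    - ``analyser_deg``: linear polariser angle in degrees (default 45);
      ``None`` records total intensity of both components.
    - ``phase_H`` / ``phase_V``: phase shifts (rad) applied per arm.
    - ``arm``: 'both' (default), 'H' or 'V' — a diverted arm contributes
      nothing.

    Additive Gaussian noise of std ``noise_sigma`` x peak intensity is
    applied and the result clipped at zero.  Deterministic under ``seed``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    chain = dict(analyser_chain or {})
    e_h = proximal.data[0] * np.exp(1j * chain.get("phase_H", 0.0))
    e_v = proximal.data[1] * np.exp(1j * chain.get("phase_V", 0.0))
    arm = chain.get("arm", "both")
    if arm == "H":
        e_v = np.zeros_like(e_v)
    elif arm == "V":
        e_h = np.zeros_like(e_h)
    ang = chain.get("analyser_deg", 45.0)
    if ang is None:
        intensity = np.abs(e_h) ** 2 + np.abs(e_v) ** 2
    else:
        a = np.deg2rad(ang)
        intensity = np.abs(np.cos(a) * e_h + np.sin(a) * e_v) ** 2
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        peak = intensity.max() if intensity.size else 0.0
        intensity = intensity + rng.normal(0.0, noise_sigma * peak,
                                           intensity.shape)
    return np.clip(intensity, 0.0, None)


def inject_arm_tilt(proximal: OpticalField, tilt: float) -> OpticalField:
    """Apply a linear phase ramp to the V component only.

    ``tilt`` is the phase slope in rad per pixel along the x (column) axis,
    emulating a small angular misalignment between the two polarisation arms.
    """
    if abs(tilt) >= np.pi / 4:
        raise ValueError("tilt must satisfy |tilt| < pi/4 per pixel")
    out = proximal.copy()
    cols = np.arange(out.shape[1])
    out.data[1] *= np.exp(1j * tilt * cols)[None, :]
    return out
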