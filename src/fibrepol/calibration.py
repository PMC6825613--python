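"""Parallelised transmission-matrix characterisation.

A rigid array of spots is translated over a small grid (9x9 positions at
9 µm, by default) in several elliptical polarisation states; because the
fibre matrix is near-diagonal, each recorded proximal field can be split into
one characterisation image per spot, multiplying the effective measurement
count by the number of spots.  Each row of the inverse matrix couples one
distal sample point to proximal samples inside a small locality window and is
recovered independently by basis pursuit denoising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp

from .fields import OpticalField, default_calibration_states
from .sparse import bpdn
from .transmission import TransmissionMatrix, sample_field_at

__all__ = ["CalibrationSchedule", "CalibrationSet", "SolverConfig",
           "make_spot_array", "split_spots", "solve_inverse_row",
           "assemble_inverse_tm", "run_calibration"]


@dataclass
class CalibrationSchedule:
    """Spot-array geometry and scan schedule.

    Defaults reproduce the full schedule: 12 spots on a 3x4 rectangular grid
    at 68.2 µm spacing, translated through a 9x9 grid of 9 µm steps, each
    position projected in 3 elliptical polarisation states — 243 raw inputs,
    2916 characterisation images, 972 resolvable distal positions.
    """

    n_spots_x: int = 3
    n_spots_y: int = 4
    spot_spacing: float = 68.2          # µm, equals the locality window
    grid_size: tuple[int, int] = (9, 9)
    step: float = 9.0                   # µm
    states: np.ndarray = dc_field(default_factory=default_calibration_states)
    spot_sinc_scale: float = 4.5        # µm, first zero of the sinc profile
    spot_aperture_sigma: float = 9.0    # µm, Gaussian apodisation of lobes

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=complex))
        if self.n_spots < 1 or self.step <= 0:
            raise ValueError("need at least one spot and step > 0")
        if self.states.shape[0] < 1 or self.states.shape[1] != 2:
            raise ValueError("states must be (n_states, 2)")

    @property
    def n_spots(self) -> int:
        return self.n_spots_x * self.n_spots_y

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def n_translations(self) -> int:
        return self.grid_size[0] * self.grid_size[1]

    @property
    def n_raw_inputs(self) -> int:
        return self.n_translations * self.n_states

    @property
    def n_characterisation(self) -> int:
        return self.n_spots * self.n_raw_inputs

    def spot_bases(self) -> np.ndarray:
        """(n_spots, 2) rest positions of the spot array (µm)."""
        bx = (np.arange(self.n_spots_x) - (self.n_spots_x - 1) / 2)
        by = (np.arange(self.n_spots_y) - (self.n_spots_y - 1) / 2)
        xx, yy = np.meshgrid(bx * self.spot_spacing, by * self.spot_spacing)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def translation_offset(self, t_index: int) -> np.ndarray:
        gx, gy = self.grid_size
        if not (0 <= t_index < gx * gy):
            raise ValueError(f"translation index {t_index} outside grid")
        ty, tx = divmod(t_index, gx)
        return np.array([(tx - (gx - 1) / 2) * self.step,
                         (ty - (gy - 1) / 2) * self.step])

    def spot_positions(self, t_index: int) -> np.ndarray:
        return self.spot_bases() + self.translation_offset(t_index)

    def distal_positions(self) -> np.ndarray:
        """All (n_spots * n_translations, 2) resolvable distal positions."""
        return np.vstack([self.spot_positions(t)
                          for t in range(self.n_translations)])

    def enumerate_inputs(self):
        """Yield (t_index, state_index) over the raw measurement schedule."""
        for t in range(self.n_translations):
            for s in range(self.n_states):
                yield t, s

    def spot_profile(self, dx, dy) -> np.ndarray:
        """Scalar spot amplitude at offset (dx, dy) µm from the spot centre.

        Gaussian-apodised separable sinc: zero crossings at multiples of the
        sinc scale, side lobes attenuated by the aperture Gaussian.
        """
        s, sig = self.spot_sinc_scale, self.spot_aperture_sigma
        return (np.sinc(np.asarray(dx) / s) * np.sinc(np.asarray(dy) / s)
                * np.exp(-(np.asarray(dx) ** 2 + np.asarray(dy) ** 2)
                         / (2 * sig * sig)))


def make_spot_array(schedule: CalibrationSchedule, t_index: int,
                    state_index: int, grid_shape: tuple[int, int],
                    pixel_pitch: float, wavelength_nm: float) -> OpticalField:
    """Distal illumination: the translated spot array in one polarisation state."""
    pos = schedule.spot_positions(t_index)
    ny, nx = grid_shape
    x = (np.arange(nx) - (nx - 1) / 2) * pixel_pitch
    y = (np.arange(ny) - (ny - 1) / 2) * pixel_pitch
    if (np.abs(pos[:, 0]) > x.max()).any() or (np.abs(pos[:, 1]) > y.max()).any():
        raise ValueError("spot position falls outside the field grid")
    xx, yy = np.meshgrid(x, y)
    scalar = np.zeros(grid_shape)
    for (px, py) in pos:
        scalar += schedule.spot_profile(xx - px, yy - py)
    state = schedule.states[state_index]
    data = scalar[None, :, :] * state[:, None, None]
    return OpticalField(data, pixel_pitch, wavelength_nm)


def split_spots(measurement: OpticalField, schedule: CalibrationSchedule,
                t_index: int, edge_fraction: float = 0.1):
    """Split a multi-spot measurement into per-spot windowed fields.

    Each output copies the square window (side = spot spacing) centred on the
    spot's nominal translated position and zeroes everything else; the
    windows tile the spot-array area.  A warning is emitted (and the flag
    set) when more than ``edge_fraction`` of a window's energy sits within
    one pixel of the window border, indicating a spot that strayed onto the
    boundary.  Returns (fields, flags).
    """
    pos = schedule.spot_positions(t_index)
    half = schedule.spot_spacing / 2
    if len(pos) > 1:
        from scipy.spatial.distance import pdist
        d = pdist(pos, metric="chebyshev")
        if (d < schedule.spot_spacing - 1e-9).any():
            raise ValueError("spot windows overlap: schedule invalid")
    xx, yy = np.meshgrid(measurement.x_coords, measurement.y_coords)
    fields, flags = [], []
    pitch = measurement.pixel_pitch
    # true partition: pixels on a shared border belong to the nearest spot
    cheb = np.stack([np.maximum(np.abs(xx - px), np.abs(yy - py))
                     for (px, py) in pos])
    owner = np.argmin(cheb, axis=0)
    for j, (px, py) in enumerate(pos):
        inside = (np.abs(xx - px) <= half) & (np.abs(yy - py) <= half) \
            & (owner == j)
        out = measurement.copy()
        out.data = np.where(inside[None], out.data, 0)
        border = inside & ((np.abs(np.abs(xx - px) - half) <= pitch)
                           | (np.abs(np.abs(yy - py) - half) <= pitch))
        e_in = float(np.sum(np.abs(out.data) ** 2))
        e_border = float(np.sum(np.abs(measurement.data[:, border]) ** 2))
        flag = e_in > 0 and e_border > edge_fraction * e_in
        if flag:
            warnings.warn(
                f"spot at ({px:.1f}, {py:.1f}) µm carries "
                f"{100 * e_border / e_in:.1f}% of its window energy at the "
                "window border", stacklevel=2)
        fields.append(out)
        flags.append(flag)
    return fields, flags


@dataclass
class SolverConfig:
    """Row-solver settings.

    ``bpdn_tolerance`` is the residual bound of the basis-pursuit problem,
    expressed as a fraction of ||x_r|| when ``relative`` is true.  ``window``
    is the side of the square locality window (µm) from which proximal
    samples are drawn.
    """

    bpdn_tolerance: float = 0.05
    relative: bool = True
    max_iter: int = 400
    window: float = 68.2

    def __post_init__(self) -> None:
        if self.bpdn_tolerance < 0:
            raise ValueError("bpdn_tolerance must be >= 0")


class CalibrationSet:
    """Paired calibration inputs/outputs after spot splitting.

    Columns are indexed by (spot, translation, state).  Output fields are
    stored as a sparse matrix over the proximal sampling coordinates; input
    values are evaluated analytically from the schedule's spot profile.
    """

    def __init__(self, schedule: CalibrationSchedule,
                 proximal_coords: np.ndarray):
        self.schedule = schedule
        self.proximal_coords = np.asarray(proximal_coords, dtype=float)
        self._cols = []          # (spot, t_index, state)
        self._coldata = []       # sparse column vectors (2*n_prox,)
        self._Y = None

    def add_measurement(self, proximal: OpticalField, t_index: int):
        """Split a raw measurement (one translation x state) into columns."""
        fields, flags = split_spots(proximal, self.schedule, t_index)
        state_index = getattr(proximal, "state_index", None)
        if state_index is None:
            raise ValueError("measurement must carry .state_index")
        for j, f in enumerate(fields):
            vec = sample_field_at(f, self.proximal_coords)
            self._cols.append((j, t_index, state_index))
            self._coldata.append(sp.csc_matrix(vec.reshape(-1, 1)))
        self._Y = None
        return flags

    @property
    def n_columns(self) -> int:
        return len(self._cols)

    @property
    def Y(self) -> sp.csc_matrix:
        if self._Y is None:
            self._Y = sp.hstack(self._coldata, format="csc")
        return self._Y

    def input_row(self, position: np.ndarray, pol: int) -> np.ndarray:
        """x_r: input field value at a distal position, across all columns.

        Column (j, t, s) holds the single-spot field of spot j at translation
        t in state s; its value at ``position`` is the spot profile offset
        times the state's component ``pol``.
        """
        sched = self.schedule
        vals = np.empty(self.n_columns, dtype=complex)
        bases = sched.spot_bases()
        for c, (j, t, s) in enumerate(self._cols):
            centre = bases[j] + sched.translation_offset(t)
            prof = sched.spot_profile(position[0] - centre[0],
                                      position[1] - centre[1])
            vals[c] = prof * sched.states[s][pol]
        return vals


def solve_inverse_row(calset: CalibrationSet, row_coord: np.ndarray, pol: int,
                      cfg: SolverConfig | None = None):
    """Recover one sparse row of the inverse transmission matrix.

    Selects proximal samples within the locality window centred on
    ``row_coord``, solves ``min ||a||_1  s.t.  ||x_r - Y_sub^T a|| < delta``
    and returns ``(row, residual)`` with ``row`` a sparse (1, 2*n_prox)
    matrix embedded at the window indices.
    """
    cfg = cfg or SolverConfig()
    coords = calset.proximal_coords
    half = cfg.window / 2
    inwin = np.flatnonzero(
        (np.abs(coords[:, 0] - row_coord[0]) <= half)
        & (np.abs(coords[:, 1] - row_coord[1]) <= half))
    if inwin.size == 0:
        raise ValueError("locality window contains no proximal samples")
    flat = np.stack([2 * inwin, 2 * inwin + 1], axis=1).ravel()

    x_r = calset.input_row(np.asarray(row_coord, dtype=float), pol)
    Y_sub = calset.Y[flat, :]                     # (n_unknown, P)
    A = np.asarray(Y_sub.T.todense())             # (P, n_unknown)

    keep = (np.abs(A).sum(axis=1) > 0) | (np.abs(x_r) > 0)
    A = A[keep]
    b = x_r[keep]

    delta = cfg.bpdn_tolerance * (np.linalg.norm(x_r) if cfg.relative else 1.0)
    result = bpdn(A, b, delta, max_iter=cfg.max_iter)

    row = sp.csr_matrix(
        (result.x, (np.zeros(flat.size, dtype=int), flat)),
        shape=(1, 2 * len(coords)))
    row.eliminate_zeros()
    return row, result.residual


def assemble_inverse_tm(rows: dict, distal_positions: np.ndarray,
                        proximal_coords: np.ndarray,
                        window: float = 68.2) -> TransmissionMatrix:
    """Stack per-(position, pol) rows into the inverse transmission matrix.

    ``rows`` maps (position_index, pol) -> sparse (1, 2*n_prox) row.  Raises
    with the list of gaps if any row is missing.
    """
    distal_positions = np.asarray(distal_positions, dtype=float)
    n_pos = len(distal_positions)
    missing = [(i, p) for i in range(n_pos) for p in (0, 1)
               if (i, p) not in rows]
    if missing:
        raise ValueError(f"missing inverse rows for (position, pol): "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    stacked = sp.vstack([rows[(i, p)] for i in range(n_pos) for p in (0, 1)],
                        format="csr")
    return TransmissionMatrix(stacked, distal_positions, proximal_coords,
                              direction="inverse", locality_window=window)


def run_calibration(tm: TransmissionMatrix, schedule: CalibrationSchedule,
                    cfg: SolverConfig | None = None,
                    proximal_stride: int = 2,
                    detection: str = "ideal", noise_sigma: float = 0.0,
                    seed: int = 0, drift_rng=None, progress: bool = False):
    """Characterise a simulated fibre and return its inverse matrix.

    Projects the full schedule through the forward matrix ``tm``; detection
    is either ``"ideal"`` (the proximal field is taken as-is) or
    ``"holographic"`` (11-frame through-focus + PSI acquisition per
    measurement).

    When ``drift_rng`` is given, a random global piston is applied to every
    raw measurement, emulating slow phase drift between frames, and removed
    again by the drift-correction step: a dedicated *static* spot is added at
    a corner of the facet (outside the scanned area), its fibre output is
    recorded once in a reference-only measurement, every frame's phase is
    aligned on the reference window, and the reference contribution is then
    subtracted before splitting.  The facet must be large enough to keep the
    reference window clear of the scanned spot windows.

    Returns dict with ``inverse`` (TransmissionMatrix), ``counts`` and
    ``residuals`` (per-row).
    """
    from .acquisition import acquire_field, correct_phase_drift

    cfg = cfg or SolverConfig()
    grid_shape = tm.grid_shape
    pitch = tm.pixel_pitch
    wl = tm.wavelength_nm
    n = grid_shape[0]
    idx = np.arange(n)
    centre = (n - 1) // 2
    sel = idx[(idx - centre) % proximal_stride == 0]
    xs = (sel - (n - 1) / 2) * pitch
    px, py = np.meshgrid(xs, xs)
    prox_coords = np.column_stack([px.ravel(), py.ravel()])

    calset = CalibrationSet(schedule, prox_coords)

    from .transmission import values_to_field

    def project(illum_field):
        x = sample_field_at(illum_field, tm.distal_coords)
        return values_to_field(tm.apply(x), tm.proximal_coords, grid_shape,
                               pitch, wl)

    def detect(prox, k):
        if detection == "holographic":
            return acquire_field(prox, noise_sigma=noise_sigma,
                                 seed=seed + 31 * k)["field"]
        if detection != "ideal":
            raise ValueError(f"unknown detection mode: {detection!r}")
        return prox

    # static drift-reference spot at the facet corner, clear of all windows
    ref_prox = None
    if drift_rng is not None:
        span = np.abs(np.vstack([schedule.spot_positions(t)
                                 for t in (0, schedule.n_translations - 1)]))
        extent = span.max() + schedule.spot_spacing  # scanned windows + ref win
        ref_pos = np.array([-extent - 2.0, -extent - 2.0])
        axis_max = (grid_shape[0] - 1) / 2 * pitch
        if extent + 2.0 + schedule.spot_spacing / 2 > axis_max:
            raise ValueError(
                "facet too small to host the static drift-reference spot "
                f"(needs half-span {extent + 2 + schedule.spot_spacing / 2:.0f}"
                f" µm, grid has {axis_max:.0f} µm)")
        xg = (np.arange(grid_shape[1]) - (grid_shape[1] - 1) / 2) * pitch
        xxg, yyg = np.meshgrid(xg, xg)
        ref_scalar = schedule.spot_profile(xxg - ref_pos[0], yyg - ref_pos[1])
        ref_state = schedule.states[0]
        ref_illum = OpticalField(ref_scalar[None] * ref_state[:, None, None],
                                 pitch, wl)
        ref_prox = detect(project(ref_illum), -1)
        ref_mask = (np.abs(xxg - ref_pos[0]) <= schedule.spot_spacing / 2) \
            & (np.abs(yyg - ref_pos[1]) <= schedule.spot_spacing / 2)

    raw = []
    for t, s in schedule.enumerate_inputs():
        illum = make_spot_array(schedule, t, s, grid_shape, pitch, wl)
        if ref_prox is not None:
            illum.data = illum.data + ref_illum.data
        prox = project(illum)
        if drift_rng is not None:
            prox.data = prox.data * np.exp(1j * drift_rng.uniform(0, 2 * np.pi))
        prox = detect(prox, len(raw))
        prox.state_index = s
        prox.t_index = t
        raw.append(prox)

    if drift_rng is not None:
        corrected = correct_phase_drift([ref_prox] + raw, ref_mask)[1:]
        for c, r in zip(corrected, raw):
            c.data = c.data - ref_prox.data   # remove the static reference
            c.state_index = r.state_index
            c.t_index = r.t_index
        raw = corrected

    n_raw = len(raw)
    for prox in raw:
        calset.add_measurement(prox, prox.t_index)

    distal_pos = schedule.distal_positions()
    rows, residuals = {}, {}
    for i, pos in enumerate(distal_pos):
        for pol in (0, 1):
            row, res = solve_inverse_row(calset, pos, pol, cfg)
            rows[(i, pol)] = row
            residuals[(i, pol)] = res
        if progress and i % 50 == 0:
            print(f"  row block {i}/{len(distal_pos)}", flush=True)

    inverse = assemble_inverse_tm(rows, distal_pos, prox_coords, cfg.window)
    inverse.meta.update({"proximal_stride": proximal_stride,
                         "distal_step": schedule.step})
    inverse.pixel_pitch = pitch
    inverse.wavelength_nm = wl
    counts = {"raw_inputs": n_raw,
              "characterisation_fields": calset.n_columns,
              "distal_samples": len(distal_pos)}
    return {"inverse": inverse, "counts": counts,
            "residuals": residuals, "calset": calset}
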