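"""Distal-image recovery, numerical refocusing and MTF-based resolution.

The recovered distal field lives on the scattered set of positions resolved
by the calibration schedule (spot positions x translations).  For regular
single-spot schedules this set is itself a regular grid; otherwise samples
are placed on a regular grid by nearest-neighbour assignment for metrics
(bilinear only for display, to avoid smoothing bias in measurements).

Resolution follows the bar-target modulation-transfer-function procedure:
contrast per bar group from profile extrema, linear interpolation to the
contrast-0.3 crossing, reported as bar width in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import OpticalField, fresnel_propagate
from .transmission import TransmissionMatrix, sample_field_at

__all__ = ["DistalSamples", "recover_distal_field", "refocus", "MTFCurve",
           "compute_mtf", "resolution_at_threshold", "refocus_samples"]


@dataclass
class DistalSamples:
    """Dual-polarisation complex values at scattered distal positions."""

    coords: np.ndarray      # (n, 2) µm
    values: np.ndarray      # (n, 2) complex, pol 0 = H
    pixel_pitch_hint: float
    wavelength_nm: float

    def intensity(self) -> np.ndarray:
        return np.sum(np.abs(self.values) ** 2, axis=1)

    def regular_grid(self):
        """Detect whether the coordinates form a complete regular grid.

        Returns (xs, ys) axis vectors or None.
        """
        xs = np.unique(np.round(self.coords[:, 0], 9))
        ys = np.unique(np.round(self.coords[:, 1], 9))
        if len(xs) * len(ys) != len(self.coords):
            return None
        if len(xs) > 1 and not np.allclose(np.diff(xs), np.diff(xs)[0]):
            return None
        if len(ys) > 1 and not np.allclose(np.diff(ys), np.diff(ys)[0]):
            return None
        return xs, ys

    def to_grid(self, method: str = "nearest") -> OpticalField:
        """Place samples onto a regular grid field.

        If the sample set is itself a complete regular grid the values are
        placed exactly.  Otherwise ``nearest`` assigns each target pixel the
        value of the nearest sample (metrics; no smoothing), ``linear``
        interpolates (display).  Metadata records the method.
        """
        reg = self.regular_grid()
        if reg is not None:
            xs, ys = reg
            pitch = float(np.diff(xs)[0]) if len(xs) > 1 else self.pixel_pitch_hint
            data = np.zeros((2, len(ys), len(xs)), dtype=complex)
            ix = np.rint((self.coords[:, 0] - xs[0]) / pitch).astype(int)
            iy = np.rint((self.coords[:, 1] - ys[0]) / pitch).astype(int)
            data[:, iy, ix] = self.values.T
            f = OpticalField(data, pitch, self.wavelength_nm,
                             origin=(float(xs.mean()), float(ys.mean())))
            f.interpolation = "exact"
            return f
        from scipy.interpolate import griddata
        pitch = self.pixel_pitch_hint
        x0, x1 = self.coords[:, 0].min(), self.coords[:, 0].max()
        y0, y1 = self.coords[:, 1].min(), self.coords[:, 1].max()
        xs = np.arange(x0, x1 + pitch / 2, pitch)
        ys = np.arange(y0, y1 + pitch / 2, pitch)
        xx, yy = np.meshgrid(xs, ys)
        data = np.stack([
            griddata(self.coords, self.values[:, p], (xx, yy),
                     method=("nearest" if method == "nearest" else "linear"),
                     fill_value=0.0)
            for p in range(2)])
        f = OpticalField(np.nan_to_num(data), pitch, self.wavelength_nm,
                         origin=(float(xs.mean()), float(ys.mean())))
        f.interpolation = method
        return f


def recover_distal_field(inv_tm: TransmissionMatrix,
                         measured: OpticalField) -> DistalSamples:
    """Apply the inverse transmission matrix to a measured proximal field.

    The measurement is sampled at the inverse matrix's proximal coordinates;
    the product gives the complex dual-polarisation field at the resolvable
    distal positions.
    """
    if inv_tm.direction != "inverse":
        raise ValueError("expected an inverse transmission matrix")
    y = sample_field_at(measured, inv_tm.col_coords)
    x = inv_tm.matrix @ y
    step = getattr(inv_tm, "meta", {}).get("distal_step", 9.0)
    return DistalSamples(inv_tm.row_coords.copy(), x.reshape(-1, 2),
                         float(step), measured.wavelength_nm)


def refocus(field: OpticalField, z: float) -> OpticalField:
    """Back-propagate a recovered distal field to the sample plane at ``z``.

    Numerically inverts the free-space defocus acquired over a working
    distance ``z`` (µm) by Fresnel propagation over ``-z``.
    """
    return fresnel_propagate(field, -z)


def refocus_samples(samples: DistalSamples, z: float, upsample: int = 2,
                    pad_to: int = 257) -> OpticalField:
    """Refocus a recovered distal sampling by ``z`` µm.

    Each sample is placed at its exact physical coordinate on a fine grid
    (pitch = sampling step / ``upsample``; ``pad_to`` odd so a pixel sits at
    the origin), interpolated by an ideal low-pass at the original sampling
    band, and Fresnel-propagated by ``-z``.  The enlarged window keeps the
    back-propagating field inside the frame.
    """
    step = samples.pixel_pitch_hint
    reg = samples.regular_grid()
    if reg is not None and len(reg[0]) > 1:
        step = float(np.diff(reg[0])[0])
    pitch = step / upsample
    if pad_to % 2 == 0:
        pad_to += 1
    half = (pad_to - 1) // 2
    ix = np.rint(samples.coords[:, 0] / pitch).astype(int) + half
    iy = np.rint(samples.coords[:, 1] / pitch).astype(int) + half
    if (np.abs(samples.coords[:, 0] / pitch
               - np.rint(samples.coords[:, 0] / pitch)) > 1e-6).any():
        raise ValueError("sample coordinates not commensurate with the "
                         "refocus grid pitch")
    if (ix < 0).any() or (ix >= pad_to).any() or (iy < 0).any() \
            or (iy >= pad_to).any():
        raise ValueError("pad_to too small for the sampled region")
    data = np.zeros((2, pad_to, pad_to), dtype=complex)
    data[:, iy, ix] = samples.values.T
    # ideal band-limited interpolation: keep only the original sampling band
    fx = np.fft.fftfreq(pad_to, d=pitch)
    keep = np.abs(fx) <= 1.0 / (2 * step) + 1e-12
    spec = np.fft.fft2(data, axes=(1, 2))
    spec *= keep[None, None, :] * keep[None, :, None]
    data = np.fft.ifft2(spec, axes=(1, 2)) * upsample ** 2
    big = OpticalField(data, pitch, samples.wavelength_nm)
    return refocus(big, z)


# ---------------------------------------------------------------------------
# MTF and resolution
# ---------------------------------------------------------------------------

@dataclass
class MTFCurve:
    """Contrast versus spatial frequency, with bar widths retained."""

    frequencies: np.ndarray    # line pairs / µm, strictly increasing
    contrast: np.ndarray       # in [0, 1.05]
    bar_widths: np.ndarray     # µm (half-period), decreasing

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        self.bar_widths = np.asarray(self.bar_widths, dtype=float)
        if (np.diff(self.frequencies) <= 0).any():
            raise ValueError("frequencies must be strictly increasing")
        if (self.contrast < 0).any() or (self.contrast > 1.05).any():
            raise ValueError("contrast outside [0, 1.05]")

    @classmethod
    def from_widths(cls, widths, contrast) -> "MTFCurve":
        widths = np.asarray(widths, dtype=float)
        contrast = np.asarray(contrast, dtype=float)
        order = np.argsort(-widths)
        w = widths[order]
        return cls(1.0 / (2 * w), np.clip(contrast[order], 0, 1.05), w)

    def to_csv(self, path: str) -> None:
        header = "frequency_lp_per_um,bar_width_um,contrast"
        np.savetxt(path, np.column_stack(
            [self.frequencies, self.bar_widths, self.contrast]),
            delimiter=",", header=header, comments="")


def compute_mtf(image: np.ndarray, pixel_pitch: float, bar_groups,
                origin=(0.0, 0.0)) -> MTFCurve:
    """Measure bar-group contrast on an intensity image.

    ``bar_groups`` is a sequence of dicts with keys ``bar_width`` (µm) and
    optionally ``n_bars`` (default 3), ``orientation`` ('vertical' bars run
    along y), ``center`` (µm) and ``profile_halfwidth`` (µm; restrict the
    along-bar average to this band around the group centre).  The intensity
    is averaged along the bar direction and the contrast estimated from the
    profile values at the expected bar and gap centres (nearest pixel, no
    smoothing): ``(I_max - I_min) / (I_max + I_min)`` with the extrema
    averaged over the bars and the interior gaps.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    xs = (np.arange(nx) - (nx - 1) / 2) * pixel_pitch + origin[0]
    ys = (np.arange(ny) - (ny - 1) / 2) * pixel_pitch + origin[1]
    widths, contrasts = [], []
    for g in bar_groups:
        w = float(g["bar_width"])
        n_bars = int(g.get("n_bars", 3))
        orient = g.get("orientation", "vertical")
        cx, cy = g.get("center", (0.0, 0.0))
        hw = g.get("profile_halfwidth")
        if orient == "vertical":
            rows = np.ones(ny, bool) if hw is None else np.abs(ys - cy) <= hw
            profile = image[rows].mean(axis=0)
            axis, c0 = xs, cx
        else:
            cols = np.ones(nx, bool) if hw is None else np.abs(xs - cx) <= hw
            profile = image[:, cols].mean(axis=1)
            axis, c0 = ys, cy
        bar_pos = c0 + (np.arange(n_bars) - (n_bars - 1) / 2) * 2 * w
        gap_pos = (bar_pos[:-1] + bar_pos[1:]) / 2   # interior gap centres
        allpos = np.concatenate([bar_pos, gap_pos])
        if allpos.min() < axis.min() - pixel_pitch / 2 or \
           allpos.max() > axis.max() + pixel_pitch / 2:
            raise ValueError(
                f"bar group of width {w} µm extends outside the image")
        i_bar = np.array([profile[np.argmin(np.abs(axis - p))]
                          for p in bar_pos])
        i_gap = np.array([profile[np.argmin(np.abs(axis - p))]
                          for p in gap_pos])
        i_max, i_min = i_bar.mean(), i_gap.mean()
        denom = i_max + i_min
        # signed estimator: contrast-reversed bars (defocus phase reversal)
        # count as zero, not as resolved structure
        contrasts.append(max((i_max - i_min) / denom, 0.0) if denom > 0
                         else 0.0)
        widths.append(w)
    return MTFCurve.from_widths(widths, np.clip(contrasts, 0, 1.05))


def resolution_at_threshold(curve: MTFCurve, threshold: float = 0.3):
    """Bar width (µm) at which the MTF crosses ``threshold``.

    Walks the curve from coarse to fine bars and linearly interpolates the
    bar width at the first downward crossing of the threshold.  Returns
    ``(resolution, uncertainty)`` where the uncertainty is half the spacing
    between the bracketing bar widths.  Raises if the curve never crosses
    (resolution beyond the measured range).
    """
    w = curve.bar_widths
    c = curve.contrast
    if threshold <= 0:
        return float(w[-1]), 0.0
    for i in range(len(w) - 1):
        if c[i] >= threshold and c[i + 1] < threshold:
            t = (c[i] - threshold) / (c[i] - c[i + 1])
            res = w[i] + t * (w[i + 1] - w[i])
            return float(res), float(abs(w[i] - w[i + 1]) / 2)
    raise ValueError("MTF does not cross the threshold within the measured "
                     "range: resolution beyond measured bars")
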