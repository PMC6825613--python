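"""Dual-polarisation optical fields, Jones algebra and free-space propagation.

All lengths are micrometres internally; the vacuum wavelength is stored in
nanometres and converted once.  A field lives on a regular 2-D grid whose
coordinates are pixel centres, with the origin at the grid centre (plus an
optional physical offset).  Polarisation component 0 is horizontal.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import h5py
import numpy as np

__all__ = [
    "OpticalField",
    "fresnel_propagate",
    "jones_apply",
    "jones_compose",
    "make_polarisation_state",
    "identity_jones_map",
]


@dataclass
class OpticalField:
    """Sampled complex optical field in two polarisation components.

    Parameters
    ----------
    data : ndarray, shape (2, ny, nx), complex
        Complex amplitude; axis 0 indexes polarisation (0 = H, 1 = V).
    pixel_pitch : float
        Sample spacing in µm (> 0, square pixels).
    wavelength_nm : float
        Vacuum wavelength in nm.
    origin : (float, float)
        Physical (x, y) offset of the grid centre, µm.
    """

    data: np.ndarray
    pixel_pitch: float
    wavelength_nm: float
    origin: tuple[float, float] = dataclass_field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3 or self.data.shape[0] != 2:
            raise ValueError(
                f"field data must have shape (2, ny, nx), got {self.data.shape}"
            )
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field contains non-finite values")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def x_coords(self) -> np.ndarray:
        nx = self.data.shape[2]
        return (np.arange(nx) - (nx - 1) / 2) * self.pixel_pitch + self.origin[0]

    @property
    def y_coords(self) -> np.ndarray:
        ny = self.data.shape[1]
        return (np.arange(ny) - (ny - 1) / 2) * self.pixel_pitch + self.origin[1]

    # -- physics ------------------------------------------------------------

    @property
    def power(self) -> float:
        """Total power Σ|E|² over both polarisations (arbitrary units)."""
        return float(np.sum(np.abs(self.data) ** 2))

    def copy(self) -> "OpticalField":
        return OpticalField(
            self.data.copy(), self.pixel_pitch, self.wavelength_nm, self.origin
        )

    def congruent(self, other: "OpticalField") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_pitch, other.pixel_pitch)
            and np.isclose(self.wavelength_nm, other.wavelength_nm)
        )

    # -- IO ------------------------------------------------------------------

    def to_hdf5(self, target) -> None:
        """Write to an h5py Group/File or a path (datasets /field/H, /field/V)."""
        if isinstance(target, (str, bytes)):
            with h5py.File(target, "w") as fh:
                self.to_hdf5(fh)
            return
        grp = target.require_group("field")
        for key in ("H", "V"):
            if key in grp:
                del grp[key]
        grp.create_dataset("H", data=self.data[0])
        grp.create_dataset("V", data=self.data[1])
        grp.attrs["pixel_pitch_um"] = self.pixel_pitch
        grp.attrs["wavelength_nm"] = self.wavelength_nm
        grp.attrs["origin_um"] = np.asarray(self.origin, dtype=float)

    @classmethod
    def from_hdf5(cls, source) -> "OpticalField":
        if isinstance(source, (str, bytes)):
            with h5py.File(source, "r") as fh:
                return cls.from_hdf5(fh)
        grp = source["field"]
        data = np.stack([grp["H"][()], grp["V"][()]])
        origin = tuple(grp.attrs.get("origin_um", (0.0, 0.0)))
        return cls(data, float(grp.attrs["pixel_pitch_um"]),
                   float(grp.attrs["wavelength_nm"]), origin)


class SamplingError(ValueError):
    """Propagation sampling (anti-aliasing) condition violated."""


def _transfer_function(shape, pitch, wavelength_um, z):
    ny, nx = shape
    fx = np.fft.fftfreq(nx, d=pitch)
    fy = np.fft.fftfreq(ny, d=pitch)
    fx2, fy2 = np.meshgrid(fx**2, fy**2, sparse=True)
    k = 2 * np.pi / wavelength_um
    # Fresnel transfer function: exp(ikz) exp(-i pi lambda z f^2)
    return np.exp(1j * (k * z - np.pi * wavelength_um * z * (fx2 + fy2)))


def fresnel_propagate(field: OpticalField, z: float) -> OpticalField:
    """Propagate a field a distance ``z`` (µm) in free space.

    Uses the transfer-function (angular-spectrum) evaluation of the Fresnel
    diffraction integral: multiply the spatial spectrum by
    ``exp(ikz) exp(-i π λ z (fx²+fy²))``.  The propagator is unitary for every
    spatial frequency, so energy is conserved exactly and propagation by ``-z``
    is the exact inverse.

    Anti-aliasing condition
    -----------------------
    The quadratic phase of the transfer function must be sampled finely enough:
    ``|z| <= pitch * L / λ`` where ``L`` is the grid side length.  Violations
    raise :class:`SamplingError` naming the pitch that would be required.
    Negative ``z`` back-propagates.
    """
    if z == 0:
        return field.copy()
    lam = field.wavelength_um
    ny, nx = field.shape
    side = min(nx, ny) * field.pixel_pitch
    z_max = field.pixel_pitch * side / lam
    if abs(z) > z_max:
        need = np.sqrt(abs(z) * lam / min(nx, ny))
        raise SamplingError(
            f"|z|={abs(z):.1f} µm exceeds the transfer-function sampling limit "
            f"{z_max:.1f} µm for pitch {field.pixel_pitch:.3g} µm; increase the "
            f"pitch to >= {need:.3g} µm (or pad the grid)."
        )
    H = _transfer_function(field.shape, field.pixel_pitch, lam, z)
    out = np.fft.ifft2(np.fft.fft2(field.data, axes=(1, 2)) * H, axes=(1, 2))
    return OpticalField(out, field.pixel_pitch, field.wavelength_nm, field.origin)


def jones_apply(j_map: np.ndarray, field: OpticalField) -> OpticalField:
    """Apply a per-pixel 2x2 Jones matrix map to a field.

    ``j_map`` has shape (ny, nx, 2, 2) congruent with the field grid; the
    output polarisation vector at each pixel is ``J @ (E_H, E_V)``.
    """
    j_map = np.asarray(j_map, dtype=np.complex128)
    if j_map.shape != field.shape + (2, 2):
        raise ValueError(
            f"Jones map shape {j_map.shape} does not match field grid "
            f"{field.shape + (2, 2)}"
        )
    out = np.einsum("yxij,jyx->iyx", j_map, field.data)
    return OpticalField(out, field.pixel_pitch, field.wavelength_nm, field.origin)


def jones_compose(j2: np.ndarray, j1: np.ndarray) -> np.ndarray:
    """Pixelwise product ``J2 @ J1`` of two Jones maps."""
    return np.einsum("...ij,...jk->...ik", j2, j1)


def identity_jones_map(shape: tuple[int, int]) -> np.ndarray:
    j = np.zeros(shape + (2, 2), dtype=np.complex128)
    j[..., 0, 0] = 1.0
    j[..., 1, 1] = 1.0
    return j


def make_polarisation_state(kind: str, psi: float | None = None) -> np.ndarray:
    """Unit Jones vector for an illumination polarisation state.

    ``kind`` is 'H', 'V' or 'elliptical'; the elliptical state with phase
    ``psi`` is ``(1, e^{i psi})/sqrt(2)``: both components carry equal power so
    both fibre polarisation channels are driven at full strength (linear states
    would leave one channel dark).
    """
    if kind == "H":
        return np.array([1.0, 0.0], dtype=np.complex128)
    if kind == "V":
        return np.array([0.0, 1.0], dtype=np.complex128)
    if kind == "elliptical":
        if psi is None:
            raise ValueError("elliptical state requires psi")
        return np.array([1.0, np.exp(1j * psi)], dtype=np.complex128) / np.sqrt(2)
    raise ValueError(f"unknown polarisation state kind: {kind!r}")


#: Default calibration triple of elliptical states: phases equally spaced on
#: the circle, giving a perfectly conditioned 3x2 state matrix.
DEFAULT_STATE_PHASES = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


def default_calibration_states() -> np.ndarray:
    """The three default elliptical states stacked as a (3, 2) matrix."""
    return np.stack(
        [make_polarisation_state("elliptical", p) for p in DEFAULT_STATE_PHASES]
    )
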