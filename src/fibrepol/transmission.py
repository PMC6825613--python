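"""Sparse transmission matrices over (spatial sample, polarisation) indices.

A :class:`TransmissionMatrix` maps a vectorised dual-polarisation field sampled
at one set of spatial coordinates to a field sampled at another set.  The
flattened index convention is ``2 * spatial_index + pol`` (pol 0 = H, 1 = V).
Multi-core fibre matrices are *near-diagonal*: almost all of each row's energy
lies within a small square window around the row's own coordinate, which is
what the parallelised characterisation scheme exploits.
"""

from __future__ import annotations

import h5py
import numpy as np
import scipy.sparse as sp

from .fields import OpticalField

__all__ = ["TransmissionMatrix", "sample_field_at", "values_to_field"]

#: Default locality window (µm): side of the square that captures a row's mass.
DEFAULT_LOCALITY_WINDOW = 68.2


def sample_field_at(field: OpticalField, coords: np.ndarray,
                    atol: float = 1e-6) -> np.ndarray:
    """Sample a field at physical (x, y) coordinates lying on its pixel grid.

    Returns a flat complex vector of length ``2 * len(coords)`` in the
    ``2*spatial + pol`` convention.  Coordinates must coincide with pixel
    centres to within ``atol`` (no interpolation: the calibration geometry is
    constructed so that sample points are grid points).
    """
    coords = np.asarray(coords, dtype=float)
    xs, ys = field.x_coords, field.y_coords
    ix = np.rint((coords[:, 0] - xs[0]) / field.pixel_pitch).astype(int)
    iy = np.rint((coords[:, 1] - ys[0]) / field.pixel_pitch).astype(int)
    if (ix < 0).any() or (iy < 0).any() or (ix >= xs.size).any() or (iy >= ys.size).any():
        raise ValueError("sample coordinates fall outside the field grid")
    if (np.abs(xs[ix] - coords[:, 0]) > atol).any() or \
       (np.abs(ys[iy] - coords[:, 1]) > atol).any():
        raise ValueError("sample coordinates do not lie on the field pixel grid")
    vals = field.data[:, iy, ix]            # (2, n)
    return vals.T.reshape(-1)               # interleave pol fastest


def values_to_field(vec: np.ndarray, coords: np.ndarray, shape: tuple[int, int],
                    pixel_pitch: float, wavelength_nm: float,
                    origin=(0.0, 0.0)) -> OpticalField:
    """Scatter a flat (2*spatial+pol) vector back onto a regular grid field."""
    vals = np.asarray(vec).reshape(-1, 2).T   # (2, n)
    out = np.zeros((2,) + tuple(shape), dtype=np.complex128)
    ny, nx = shape
    x0 = -(nx - 1) / 2 * pixel_pitch + origin[0]
    y0 = -(ny - 1) / 2 * pixel_pitch + origin[1]
    ix = np.rint((coords[:, 0] - x0) / pixel_pitch).astype(int)
    iy = np.rint((coords[:, 1] - y0) / pixel_pitch).astype(int)
    out[:, iy, ix] = vals
    return OpticalField(out, pixel_pitch, wavelength_nm, origin)


class TransmissionMatrix:
    """Sparse complex operator between two sampled dual-polarisation fields.

    Parameters
    ----------
    matrix : scipy sparse matrix, shape (2*n_rows, 2*n_cols)
        Complex coupling coefficients in the ``2*spatial + pol`` convention.
    row_coords, col_coords : ndarray (n, 2)
        Physical (x, y) positions (µm) of the row / column spatial samples.
        For a forward matrix ``y = A x`` rows are proximal and columns distal;
        for an inverse matrix the roles swap.
    direction : {"forward", "inverse"}
    locality_window : float
        Side (µm) of the square within which each row's mass concentrates.
    """

    def __init__(self, matrix, row_coords, col_coords, direction="forward",
                 locality_window: float = DEFAULT_LOCALITY_WINDOW, meta=None):
        self.matrix = sp.csr_matrix(matrix, dtype=np.complex128)
        self.row_coords = np.asarray(row_coords, dtype=float)
        self.col_coords = np.asarray(col_coords, dtype=float)
        if direction not in ("forward", "inverse"):
            raise ValueError("direction must be 'forward' or 'inverse'")
        self.direction = direction
        self.locality_window = float(locality_window)
        self.meta = dict(meta or {})
        if self.matrix.shape != (2 * len(self.row_coords), 2 * len(self.col_coords)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.row_coords)} row and {len(self.col_coords)} column "
                "spatial samples")

    # -- convenience --------------------------------------------------------

    @property
    def distal_coords(self) -> np.ndarray:
        return self.col_coords if self.direction == "forward" else self.row_coords

    @property
    def proximal_coords(self) -> np.ndarray:
        return self.row_coords if self.direction == "forward" else self.col_coords

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Matrix-vector product on a flat (2*spatial+pol) vector."""
        x = np.asarray(x, dtype=np.complex128).reshape(-1)
        if x.size != self.matrix.shape[1]:
            raise ValueError(
                f"vector length {x.size} does not match matrix columns "
                f"{self.matrix.shape[1]}")
        return self.matrix @ x

    # -- structure ----------------------------------------------------------

    def in_window_mass(self) -> np.ndarray:
        """Per-row fraction of squared-magnitude mass inside the locality window.

        The window is the square of side ``locality_window`` centred on the
        row's own spatial coordinate (Chebyshev distance <= window/2).
        """
        half = self.locality_window / 2
        csr = self.matrix
        fractions = np.ones(csr.shape[0])
        for r in range(csr.shape[0]):
            lo, hi = csr.indptr[r], csr.indptr[r + 1]
            if lo == hi:
                continue
            cols = csr.indices[lo:hi]
            vals = np.abs(csr.data[lo:hi]) ** 2
            d = np.abs(self.col_coords[cols // 2] - self.row_coords[r // 2])
            inside = (d <= half).all(axis=1)
            total = vals.sum()
            fractions[r] = vals[inside].sum() / total if total > 0 else 1.0
        return fractions

    def is_near_diagonal(self, threshold: float = 0.99) -> bool:
        return bool((self.in_window_mass() >= threshold).all())

    # -- IO ------------------------------------------------------------------

    def to_hdf5(self, target) -> None:
        if isinstance(target, (str, bytes)):
            with h5py.File(target, "w") as fh:
                self.to_hdf5(fh)
            return
        grp = target.require_group("tm")
        coo = self.matrix.tocoo()
        for name, data in (("row", coo.row), ("col", coo.col), ("val", coo.data),
                           ("row_coords", self.row_coords),
                           ("col_coords", self.col_coords)):
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=data)
        grp.attrs["shape"] = self.matrix.shape
        grp.attrs["direction"] = self.direction
        grp.attrs["locality_window_um"] = self.locality_window
        for k, v in self.meta.items():
            grp.attrs[f"meta_{k}"] = v

    @classmethod
    def from_hdf5(cls, source) -> "TransmissionMatrix":
        if isinstance(source, (str, bytes)):
            with h5py.File(source, "r") as fh:
                return cls.from_hdf5(fh)
        grp = source["tm"]
        shape = tuple(grp.attrs["shape"])
        mat = sp.coo_matrix(
            (grp["val"][()], (grp["row"][()], grp["col"][()])), shape=shape
        ).tocsr()
        meta = {k[5:]: grp.attrs[k] for k in grp.attrs if k.startswith("meta_")}
        return cls(mat, grp["row_coords"][()], grp["col_coords"][()],
                   str(grp.attrs["direction"]), float(grp.attrs["locality_window_um"]),
                   meta)
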