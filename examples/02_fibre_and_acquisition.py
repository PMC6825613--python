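"""Synthetic multi-core fibre and the 11-frame holographic acquisition.

Builds the 576-core fibre (4.4 µm pitch, NA 0.35 at 852 nm), checks the
near-diagonal structure of its transmission matrix, then reconstructs a
random dual-polarisation facet field from intensity-only camera frames:
a 7-frame through-focus stack (iterative phase retrieval for the H arm)
plus 4 phase-shifting frames against the V arm.
"""

import numpy as np

from fibrepol.fibre import FibreSpec, build_fibre_tm
from fibrepol.acquisition import acquire_field
from fibrepol.transmission import values_to_field

spec = FibreSpec()
tm = build_fibre_tm(spec)
frac = tm.in_window_mass()
print(f"fibre: {len(tm.core_positions)} cores, facet grid {tm.grid_shape}, "
      f"matrix nnz {tm.matrix.nnz}")
print(f"near-diagonality: min in-window row mass = {frac.min():.5f} "
      f"(window {tm.locality_window} µm)")

# random per-core complex amplitudes -> realistic speckled facet field
rng = np.random.default_rng(0)
n = tm.grid_shape[0]
a = rng.normal(size=2 * len(tm.core_positions)) \
    + 1j * rng.normal(size=2 * len(tm.core_positions))
vals = np.zeros(2 * n * n, complex)
for pol in range(2):
    vals[pol::2] = tm.mode_matrix @ a[pol::2]
field = values_to_field(vals, tm.row_coords, tm.grid_shape, tm.pixel_pitch,
                        tm.wavelength_nm)

for noise in (0.0, 0.01):
    out = acquire_field(field, noise_sigma=noise, seed=1)
    rec = out["field"].data
    rho = abs(np.vdot(rec, field.data)) / (np.linalg.norm(rec)
                                           * np.linalg.norm(field.data))
    print(f"camera noise {noise:4.0%}: {out['n_frames']} frames, "
          f"complex field correlation |rho| = {rho:.4f}")
print("-> intensity-only detection recovers the full complex, "
      "dual-polarisation field up to a global piston.")
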