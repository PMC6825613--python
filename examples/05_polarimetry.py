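"""Bayesian inference of the five polarimetric parameters per pixel.

Generates measurements of a quarter-wave retarder (axis 45 deg) in the three
elliptical illumination states, recovers (D, theta_D, phi, theta_phi, delta)
by MAP optimisation, then injects the inter-arm phase-ramp misalignment
artefact and shows that joint inference over a 15-pixel neighbourhood
removes the spurious retardance tilt that per-pixel fits exhibit.
"""

import numpy as np

from fibrepol.fields import default_calibration_states
from fibrepol.polarimetry import (PolarimetricParams, PriorSpec,
                                  jones_forward, infer_pixel, infer_joint)

U = default_calibration_states()
true = PolarimetricParams(theta_phi=np.pi / 4, phi=np.pi / 2, delta=0.0,
                          D=0.0, theta_D=0.0)
J = jones_forward(true)
prior = PriorSpec()

out = infer_pixel(U, U @ J.T, prior)
p = out["params"]
print("clean quarter-wave plate at 45 deg, MAP estimate (canonicalised):")
print(f"  theta_phi {p.theta_phi:+.3f}  phi {p.phi:+.3f}  delta {p.delta:+.3f}"
      f"  D {p.D:+.3f}  theta_D {p.theta_D:+.3f} rad")

# inter-arm misalignment: linear phase ramp on the V component
t = 0.02  # rad/µm
xs, ys = np.meshgrid(np.arange(5) * 9.0, np.arange(3) * 9.0)
coords = np.column_stack([xs.ravel(), ys.ravel()])
U_list, V_list, phis = [], [], []
for (x, y) in coords:
    V = U @ (np.diag([1.0, np.exp(1j * t * x)]) @ J).T
    U_list.append(U)
    V_list.append(V)
    phis.append(infer_pixel(U, V, prior)["params"].phi)
A = np.column_stack([coords, np.ones(len(coords))])
sol, *_ = np.linalg.lstsq(A, np.unwrap(phis), rcond=None)
g_pp = float(np.hypot(sol[0], sol[1]))

joint = infer_joint(U_list, V_list, coords, prior)
print(f"injected arm tilt {t} rad/µm:")
print(f"  per-pixel retardance gradient {g_pp:.4f} rad/µm (artefact)")
print(f"  joint inference gradient      {joint['tilt']:.6f} rad/µm, "
      f"estimated ramp {np.round(joint['ramp'], 4)} rad/µm")
print("-> tying the retardance axis and the common arm ramp across the "
      "neighbourhood removes the misalignment artefact.")
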