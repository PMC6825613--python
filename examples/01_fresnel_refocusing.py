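"""Free-space propagation: Gaussian-beam spreading and exact back-propagation.

Builds a 10 µm-waist Gaussian beam at 852 nm, propagates it 300 µm with the
unitary Fresnel transfer-function propagator, measures its 1/e^2 radius
against the analytic w(z) = w0 sqrt(1 + (z/zR)^2), and back-propagates to
verify the operation inverts exactly.
"""

import numpy as np

from fibrepol import OpticalField, fresnel_propagate

w0, wavelength_nm, pitch, n = 10.0, 852.0, 1.5, 192
lam = wavelength_nm * 1e-3
z_r = np.pi * w0 ** 2 / lam

ax = (np.arange(n) - (n - 1) / 2) * pitch
xx, yy = np.meshgrid(ax, ax)
amp = np.exp(-(xx ** 2 + yy ** 2) / w0 ** 2)
beam = OpticalField(np.stack([amp, np.zeros_like(amp)]), pitch, wavelength_nm)

z = 300.0
out = fresnel_propagate(beam, z)
intens = np.abs(out.data[0]) ** 2
w_meas = 2 * np.sqrt((intens * (xx ** 2 + yy ** 2)).sum() / intens.sum() / 2)
w_theory = w0 * np.sqrt(1 + (z / z_r) ** 2)

back = fresnel_propagate(out, -z)
rms = np.sqrt(np.mean(np.abs(back.data - beam.data) ** 2))

print(f"beam waist w0 = {w0} µm, Rayleigh range zR = {z_r:.0f} µm")
print(f"measured 1/e^2 radius after {z:.0f} µm: {w_meas:.2f} µm "
      f"(analytic {w_theory:.2f} µm)")
print(f"power change through propagation: "
      f"{abs(out.power - beam.power) / beam.power:.1e} (unitary propagator)")
print(f"round-trip +z then -z RMS error: {rms:.1e}")
print("-> diffraction spreading matches the closed form and the propagator "
      "is exactly invertible, which is what digital refocusing relies on.")
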