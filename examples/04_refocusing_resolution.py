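"""Bar-target resolution and computational refocusing through the fibre.

Calibrates the 576-core fibre with the single-spot 9x9/9 µm schedule, images
bar ladders through it at the facet and at 1 mm working distance, and reads
the MTF-0.3 resolution before and after numerical back-propagation of the
recovered complex field.  Takes a few minutes.
"""

import numpy as np

from fibrepol.fibre import FibreSpec, build_fibre_tm
from fibrepol.calibration import run_calibration
from fibrepol.pipeline import single_spot_schedule, resolution_study
from fibrepol.recon import resolution_at_threshold

tm = build_fibre_tm(FibreSpec())
sched = single_spot_schedule()
print("calibrating (243 measurements, 162 inverse rows) ...")
inv = run_calibration(tm, sched)["inverse"]

for label, wd, refocus in [("working distance 0", 0.0, False),
                           ("1 mm, uncorrected", 1000.0, False),
                           ("1 mm, refocused", 1000.0, True)]:
    curve = resolution_study(tm, inv, wd, refocus)
    print(f"{label}: contrast {np.round(curve.contrast, 2)} at bar widths "
          f"{[float(w) for w in curve.bar_widths]} µm")
    try:
        r, u = resolution_at_threshold(curve)
        print(f"  -> MTF-0.3 resolution {r:.1f} ± {u:.1f} µm")
    except ValueError:
        print("  -> resolution beyond the measured bar range")
print("-> defocus at 1 mm destroys the bars; back-propagating the "
      "recovered quantitative phase restores near-contact resolution.")
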