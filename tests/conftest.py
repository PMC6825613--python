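"""Shared fixtures: synthetic fibres, calibrated rigs, field generators."""

import numpy as np
import pytest
import scipy.sparse as sp

from fibrepol.fibre import FibreSpec, build_fibre_tm
from fibrepol.calibration import run_calibration
from fibrepol.pipeline import single_spot_schedule
from fibrepol.transmission import TransmissionMatrix, values_to_field
from fibrepol.polarimetry import equivalence_class, _circ_dist


@pytest.fixture(scope="session")
def fibre_tm():
    """Default desk-scale fibre (576 cores, paper pitch/NA), seed 0."""
    return build_fibre_tm(FibreSpec())


@pytest.fixture(scope="session")
def small_tm():
    """Tiny fibre for fast acquisition tests."""
    return build_fibre_tm(FibreSpec(n_cores_across=10, seed=1))


@pytest.fixture(scope="session")
def identity_tm(fibre_tm):
    """Identity transmission matrix on the desk-scale facet grid."""
    n2 = fibre_tm.matrix.shape[0]
    tm = TransmissionMatrix(sp.identity(n2, format="csr", dtype=complex),
                            fibre_tm.row_coords, fibre_tm.col_coords,
                            "forward", meta=fibre_tm.meta)
    tm.grid_shape = fibre_tm.grid_shape
    tm.pixel_pitch = fibre_tm.pixel_pitch
    tm.wavelength_nm = fibre_tm.wavelength_nm
    return tm


@pytest.fixture(scope="session")
def desk_rig(fibre_tm):
    """Desk-scale fibre calibrated with the single-spot 9x9/9 µm schedule.

    This is the expensive shared fixture: 243 measurements, 162 inverse rows.
    """
    schedule = single_spot_schedule()
    result = run_calibration(fibre_tm, schedule)
    return {"tm": fibre_tm, "inverse": result["inverse"],
            "schedule": schedule, "counts": result["counts"],
            "residuals": result["residuals"]}


def fibre_speckle_field(tm, seed):
    """Proximal-type field: fibre modes with random complex amplitudes."""
    r = np.random.default_rng(seed)
    n = tm.grid_shape[0]
    n_cores = len(tm.core_positions)
    a = r.normal(size=2 * n_cores) + 1j * r.normal(size=2 * n_cores)
    vals = np.zeros(2 * n * n, complex)
    for pol in range(2):
        vals[pol::2] = tm.mode_matrix @ a[pol::2]
    return values_to_field(vals, tm.row_coords, tm.grid_shape,
                           tm.pixel_pitch, tm.wavelength_nm)


def support_field(tm, schedule, seed):
    """Distal field spanned by spot profiles at the resolvable positions."""
    from fibrepol.fields import OpticalField
    r = np.random.default_rng(seed)
    n = tm.grid_shape[0]
    dp = schedule.distal_positions()
    ax = (np.arange(n) - (n - 1) / 2) * tm.pixel_pitch
    xx, yy = np.meshgrid(ax, ax)
    coef = r.normal(size=(len(dp), 2)) + 1j * r.normal(size=(len(dp), 2))
    scal = np.zeros((2, n, n), complex)
    for (p, c) in zip(dp, coef):
        prof = schedule.spot_profile(xx - p[0], yy - p[1])
        scal[0] += c[0] * prof
        scal[1] += c[1] * prof
    return OpticalField(scal, tm.pixel_pitch, tm.wavelength_nm)


def class_aware_errors(p_est, p_true):
    """Per-parameter circular-aware deviations, minimised over the
    degeneracy class of the estimate."""
    best, bd = np.inf, None
    for m in equivalence_class(p_est):
        d = np.array([
            _circ_dist(m.theta_phi, p_true.theta_phi, np.pi),
            _circ_dist(m.phi, p_true.phi, 2 * np.pi),
            _circ_dist(m.delta, p_true.delta, 2 * np.pi),
            abs(m.D - p_true.D),
            _circ_dist(m.theta_D, p_true.theta_D, np.pi)])
        if d.sum() < best:
            best, bd = d.sum(), d
    return bd


def correlation(a, b):
    a = np.asarray(a).reshape(-1)
    b = np.asarray(b).reshape(-1)
    return float(np.abs(np.vdot(a, b))
                 / (np.linalg.norm(a) * np.linalg.norm(b)))
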