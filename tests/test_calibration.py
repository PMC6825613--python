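"""Sparse row recovery and the parallelised calibration bookkeeping."""

import numpy as np
import pytest
import scipy.sparse as sp

from fibrepol.sparse import bpdn, InfeasibleError
from fibrepol.fibre import FibreSpec, build_fibre_tm
from fibrepol.calibration import (CalibrationSchedule, SolverConfig,
                                  make_spot_array, split_spots,
                                  run_calibration, assemble_inverse_tm)
from fibrepol.pipeline import single_spot_schedule


def random_sparse_problem(rng, m=40, n=64, k=3):
    A = (rng.normal(size=(m, n)) + 1j * rng.normal(size=(m, n))) / np.sqrt(2 * m)
    idx = rng.choice(n, k, replace=False)
    x0 = np.zeros(n, complex)
    x0[idx] = rng.normal(size=k) + 1j * rng.normal(size=k)
    return A, x0, idx


class TestBpdn:
    def test_matches_least_squares_on_true_support(self):
        # noiseless sparse rows: solution equals LS restricted to the support
        rng = np.random.default_rng(0)
        for _ in range(10):
            A, x0, idx = random_sparse_problem(rng)
            b = A @ x0
            res = bpdn(A, b, delta=1e-8 * np.linalg.norm(b))
            oracle = np.zeros_like(x0)
            sol, *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
            oracle[idx] = sol
            assert np.abs(res.x - oracle).max() < 1e-6
            assert set(np.flatnonzero(np.abs(res.x) > 1e-8)) == set(idx)

    def test_residual_bound_always_met(self):
        rng = np.random.default_rng(1)
        for delta_frac in (0.3, 0.1, 0.02):
            A, x0, _ = random_sparse_problem(rng)
            b = A @ x0 + 0.01 * (rng.normal(size=40) + 1j * rng.normal(size=40))
            delta = delta_frac * np.linalg.norm(b)
            res = bpdn(A, b, delta)
            assert res.residual <= delta * (1 + 1e-6)

    def test_infeasible_bound_reports_achievable(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 3)) + 0j
        b = rng.normal(size=10) + 0j
        with pytest.raises(InfeasibleError) as exc:
            bpdn(A, b, delta=1e-12)
        assert exc.value.achievable > 0

    def test_loose_bound_returns_zero(self):
        A = np.eye(4) + 0j
        b = 0.1 * np.ones(4) + 0j
        res = bpdn(A, b, delta=1.0)
        assert np.abs(res.x).max() == 0


class TestScheduleBookkeeping:
    def test_default_schedule_counts(self):
        s = CalibrationSchedule()
        assert s.n_spots == 12
        assert s.n_raw_inputs == 81 * 3 == 243
        assert s.n_characterisation == 12 * 243 == 2916
        assert len(s.distal_positions()) == 12 * 81 == 972

    def test_parallelisation_identity(self):
        for kw in ({}, dict(n_spots_x=1, n_spots_y=1),
                   dict(grid_size=(5, 5))):
            s = CalibrationSchedule(**kw)
            assert s.n_characterisation == s.n_spots * s.n_raw_inputs

    def test_enumerate_inputs_distinct(self):
        s = CalibrationSchedule()
        inputs = list(s.enumerate_inputs())
        assert len(inputs) == 243
        assert len(set(inputs)) == 243


class TestSpotArray:
    GRID = dict(grid_shape=(129, 129), pixel_pitch=2.25, wavelength_nm=852.0)

    def test_twelve_spots_at_nominal_spacing(self):
        s = CalibrationSchedule()
        f = make_spot_array(s, t_index=40, state_index=0, **self.GRID)
        intens = np.abs(f.data[0]) ** 2
        from scipy.ndimage import maximum_filter
        local_max = (intens == maximum_filter(intens, size=9)) \
            & (intens > 0.2 * intens.max())
        ys, xs = np.nonzero(local_max)
        assert len(xs) == 12
        coords = np.column_stack([f.x_coords[xs], f.y_coords[ys]])
        # nearest-neighbour distances along grid axes equal the spot spacing
        x_centres = np.unique(np.round(coords[:, 0], 1))
        y_centres = np.unique(np.round(coords[:, 1], 1))
        np.testing.assert_allclose(np.diff(x_centres), 68.2, atol=2.25)
        np.testing.assert_allclose(np.diff(y_centres), 68.2, atol=2.25)

    def test_single_spot_peaks_at_prescribed_coordinate(self):
        s = single_spot_schedule()
        t = 13
        f = make_spot_array(s, t, 0, grid_shape=(49, 49), pixel_pitch=2.25,
                            wavelength_nm=852.0)
        intens = np.abs(f.data[0]) ** 2
        iy, ix = np.unravel_index(np.argmax(intens), intens.shape)
        pos = s.spot_positions(t)[0]
        assert abs(f.x_coords[ix] - pos[0]) <= 2.25 / 2 + 1e-9
        assert abs(f.y_coords[iy] - pos[1]) <= 2.25 / 2 + 1e-9

    def test_spot_outside_grid_rejected(self):
        s = CalibrationSchedule()
        with pytest.raises(ValueError, match="outside"):
            make_spot_array(s, 0, 0, grid_shape=(25, 25), pixel_pitch=2.25,
                            wavelength_nm=852.0)


class TestSplitSpots:
    def test_partition_preserves_field_in_window_union(self):
        s = CalibrationSchedule()
        f = make_spot_array(s, 0, 0, **TestSpotArray.GRID)
        parts, flags = split_spots(f, s, 0)
        assert len(parts) == 12
        total = sum(p.data for p in parts)
        # inside the union of windows the split parts reproduce the field
        union = np.abs(total) > 0
        np.testing.assert_allclose(total[union], f.data[union], atol=1e-12)

    def test_full_schedule_yields_2916_characterisation_fields(self):
        s = CalibrationSchedule()
        count = 0
        for t, st in s.enumerate_inputs():
            count += s.n_spots   # one split field per spot per measurement
        assert count == 2916

    def test_straddling_spot_flagged(self):
        s = single_spot_schedule()
        # spot deliberately displaced onto the window border
        f = make_spot_array(s, 0, 0, grid_shape=(49, 49), pixel_pitch=2.25,
                            wavelength_nm=852.0)
        shift = int(round(s.spot_spacing / 2 / 2.25))
        g = f.copy()
        g.data = np.roll(g.data, shift, axis=2)
        with pytest.warns(UserWarning, match="window border"):
            _, flags = split_spots(g, s, 0)
        assert any(flags)


class TestRowRecovery:
    def test_identity_fibre_rows_are_unit_vectors(self, identity_tm):
        sched = single_spot_schedule(grid_size=(3, 3))
        out = run_calibration(identity_tm, sched)
        inv = out["inverse"]
        for i, pos in enumerate(sched.distal_positions()):
            j = int(np.argmin(np.abs(inv.col_coords - pos).sum(axis=1)))
            for pol in (0, 1):
                row = inv.matrix.getrow(2 * i + pol).toarray().ravel()
                expect = np.zeros_like(row)
                expect[2 * j + pol] = 1.0
                assert np.abs(row - expect).max() < 1e-6

    def test_rows_confined_to_locality_window(self, desk_rig):
        inv = desk_rig["inverse"]
        half = inv.locality_window / 2
        csr = inv.matrix
        for r in range(csr.shape[0]):
            cols = csr.indices[csr.indptr[r]:csr.indptr[r + 1]]
            d = np.abs(inv.col_coords[cols // 2] - inv.row_coords[r // 2])
            assert (d <= half + 1e-9).all()

    def test_residuals_below_tolerance(self, desk_rig):
        # the BPDN bound (5% of ||x_r||) is honoured by every row
        for res in desk_rig["residuals"].values():
            assert res <= 0.05 * 1.0 * (1 + 1e-6) + 1e-9

    def test_small_tolerance_residuals_achievable_noiseless(self):
        # underdetermined noiseless rows admit near-exact sparse fits
        tm = build_fibre_tm(FibreSpec(seed=2))
        sched = single_spot_schedule(grid_size=(3, 3))
        out = run_calibration(tm, sched, SolverConfig(bpdn_tolerance=1e-3))
        res = np.array(list(out["residuals"].values()))
        assert np.median(res) < 1e-3

    def test_missing_rows_reported(self):
        pos = np.zeros((2, 2))
        prox = np.zeros((4, 2))
        rows = {(0, 0): sp.csr_matrix((1, 8)), (0, 1): sp.csr_matrix((1, 8))}
        with pytest.raises(ValueError, match="missing"):
            assemble_inverse_tm(rows, pos, prox)


class TestEndToEndRecovery:
    def test_forward_then_inverse_recovers_support_fields(self, desk_rig):
        from conftest import support_field, correlation
        from fibrepol.transmission import sample_field_at, values_to_field
        tm, inv = desk_rig["tm"], desk_rig["inverse"]
        sched = desk_rig["schedule"]
        for seed in range(3):
            fld = support_field(tm, sched, seed)
            x = sample_field_at(fld, tm.distal_coords)
            y = tm.apply(x)
            yf = values_to_field(y, tm.proximal_coords, tm.grid_shape,
                                 tm.pixel_pitch, tm.wavelength_nm)
            y_s = sample_field_at(yf, inv.col_coords)
            xhat = inv.matrix @ y_s
            x_true = sample_field_at(fld, inv.row_coords)
            assert correlation(xhat, x_true) > 0.99
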