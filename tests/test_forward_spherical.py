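"""Forward-model tests: geometry sampling, EEG series, MEG radial field."""

import numpy as np
import pytest

from ramus import (
    DipoleSource,
    HeadModel,
    SensorArray,
    SourceSpace,
    build_source_space,
    combine_emeg,
    eeg_leadfield,
    meg_radial_leadfield,
    simulate_data,
)
from ramus.errors import DegenerateDataError, GeometryError, ParameterError
from ramus.forward_spherical import MM


def surface_potential_closed_form(q, r0_m, re_m, R_m, sigma):
    """Independent oracle: dipole potential on a homogeneous conducting
    sphere, from the classical closed-form summation of the series."""
    d = re_m - r0_m
    dn = np.linalg.norm(d)
    g = R_m - (re_m @ r0_m) / R_m + dn
    return (1.0 / (4 * np.pi * sigma)) * (
        2 * (q @ d) / dn**3 + (1.0 / (R_m * g)) * (q @ (re_m / R_m + d / dn))
    )


class TestSourceSpace:
    def test_shell_bounds_and_determinism(self):
        sp1 = build_source_space(5000, 0.0, 85.0, seed=11)
        sp2 = build_source_space(5000, 0.0, 85.0, seed=11)
        r = sp1.radii()
        assert r.max() <= 85.0 and sp1.n_positions == 5000
        np.testing.assert_array_equal(sp1.positions, sp2.positions)

    def test_single_position(self):
        sp = build_source_space(1, 10.0, 20.0, seed=0)
        assert sp.positions.shape == (1, 3)
        assert 10.0 <= sp.radii()[0] <= 20.0

    def test_mean_radius_uniform_ball(self):
        # uniform in a ball of radius R: E[r] = 3R/4, Var[r] = 3R^2/80
        R = 85.0
        sp = build_source_space(50000, 0.0, R, seed=5)
        se = np.sqrt(3.0 / 80.0) * R / np.sqrt(50000)
        assert abs(sp.radii().mean() - 0.75 * R) < 3 * se

    def test_invalid_shell(self):
        with pytest.raises(ParameterError):
            build_source_space(10, 50.0, 40.0, seed=0)
        with pytest.raises(ParameterError):
            build_source_space(10, 0.0, 90.0, seed=0, head=HeadModel())


class TestEEGLeadfield:
    def test_central_dipole_cosine_pattern(self, electrodes, head):
        sp = SourceSpace(positions=[[0.0, 0.0, 0.0]])
        L = eeg_leadfield(sp, electrodes, head)
        pattern = electrodes.positions[:, 2] / 100.0
        pattern = pattern - pattern.mean()
        corr = np.corrcoef(L.matrix[:, 2], pattern)[0, 1]
        assert corr > 1 - 1e-12

    def test_average_reference(self, eeg_small):
        sums = np.abs(eeg_small.matrix.sum(axis=0))
        norms = np.linalg.norm(eeg_small.matrix, axis=0)
        assert np.all(sums < 1e-10 * norms)

    def test_homogeneous_sphere_closed_form(self, electrodes, head_homogeneous):
        positions = np.array(
            [[30.0, -20.0, 40.0], [0.0, 0.0, 60.0], [-45.0, 7.0, 50.0], [5.0, 3.0, 1.0]]
        )
        sp = SourceSpace(positions=positions)
        L = eeg_leadfield(sp, electrodes, head_homogeneous)
        R_m, sigma = 0.1, 0.33
        for i, p in enumerate(positions):
            for c in range(3):
                q = np.zeros(3)
                q[c] = 1.0
                ref = np.array(
                    [
                        surface_potential_closed_form(q, p * MM, re * MM, R_m, sigma)
                        for re in electrodes.positions
                    ]
                )
                ref -= ref.mean()
                err = np.linalg.norm(L.matrix[:, 3 * i + c] - ref) / np.linalg.norm(ref)
                assert err < 1e-6

    def test_series_truncation_converged(self, electrodes):
        # raising the cut-off leaves every tested column unchanged within tol
        sp = SourceSpace(positions=[[20.0, 10.0, 50.0]])
        lo = eeg_leadfield(sp, electrodes, HeadModel(series_truncation=80))
        hi = eeg_leadfield(sp, electrodes, HeadModel(series_truncation=200))
        diff = np.abs(lo.matrix - hi.matrix).max() / np.abs(hi.matrix).max()
        assert diff < 1e-7

    def test_linearity_of_superposition(self, eeg_small, space_small):
        x = np.zeros(space_small.n_components)
        x[4] = 2.5
        np.testing.assert_allclose(
            eeg_small.matrix @ x, 2.5 * eeg_small.matrix[:, 4], rtol=1e-12
        )

    def test_source_outside_raises(self, electrodes, head):
        sp = SourceSpace(positions=[[0.0, 0.0, 88.0]])
        with pytest.raises(GeometryError):
            eeg_leadfield(sp, electrodes, head)

    def test_electrode_off_surface_raises(self, head, space_small):
        bad = SensorArray(kind="electrode", positions=[[0.0, 0.0, 90.0]])
        with pytest.raises(GeometryError):
            eeg_leadfield(space_small, bad, head)


class TestMEGLeadfield:
    def test_radial_dipole_silent(self, meg_small, space_small):
        # a dipole parallel to its position vector produces no radial field
        scale = np.abs(meg_small.matrix).max()
        for i in range(0, space_small.n_positions, 7):
            p = space_small.positions[i]
            r = np.linalg.norm(p)
            if r < 1.0:
                continue
            col = meg_small.matrix[:, 3 * i : 3 * i + 3] @ (p / r)
            assert np.abs(col).max() < 1e-12 * scale

    def test_free_space_radial_field(self, magnetometers, head):
        # independent oracle: full free-space dipole field with mu0/4pi,
        # projected radially, then the constant divided back out
        sp = SourceSpace(positions=[[30.0, -20.0, 40.0]])
        L = meg_radial_leadfield(sp, magnetometers, head)
        mu0_4pi = 1e-7
        for c in range(3):
            q = np.zeros(3)
            q[c] = 1.0
            ref = []
            for rs in magnetometers.positions:
                d = (rs - sp.positions[0]) * MM
                B = mu0_4pi * np.cross(q, d) / np.linalg.norm(d) ** 3
                ref.append((rs / np.linalg.norm(rs)) @ B / mu0_4pi)
            ref = np.array(ref)
            assert np.abs(L.matrix[:, c] - ref).max() < 1e-12 * np.abs(ref).max()

    def test_moment_scaling(self, meg_small):
        # doubling the moment doubles the signal (linearity in x)
        x = np.zeros(meg_small.matrix.shape[1])
        x[5] = 1.0
        np.testing.assert_allclose(
            meg_small.matrix @ (2 * x), 2 * (meg_small.matrix @ x), rtol=1e-13
        )

    def test_sensor_inside_conductor_raises(self, space_small, head):
        inside = SensorArray(kind="radial_magnetometer", positions=[[0.0, 0.0, 95.0]])
        with pytest.raises(GeometryError):
            meg_radial_leadfield(space_small, inside, head)


class TestSimulateData:
    def _dipoles(self, space):
        i = 5
        return [
            DipoleSource(
                position=space.positions[i], moment_direction=[0, 0, 1], amplitude=10.0
            )
        ]

    def test_noiseless_equals_normalized_superposition(self, eeg_small, space_small):
        dips = self._dipoles(space_small)
        ms = simulate_data(eeg_small, dips, 0.0, seed=0)
        clean = 10.0 * eeg_small.matrix[:, 3 * 5 + 2]
        np.testing.assert_allclose(ms.y, clean / np.abs(clean).max(), rtol=1e-12)
        assert ms.sigma == 0.0

    def test_noise_std_three_percent(self, eeg_small, space_small):
        dips = self._dipoles(space_small)
        clean_max = np.abs(10.0 * eeg_small.matrix[:, 3 * 5 + 2]).max()
        m = eeg_small.matrix.shape[0]
        devs = []
        for rep in range(300):
            ms = simulate_data(eeg_small, dips, 3.0, seed=rep)
            devs.append((ms.y - ms.clean_y) * ms.normalization_factor)
        devs = np.concatenate(devs)
        se = 0.03 * clean_max / np.sqrt(2 * devs.size)
        assert abs(devs.std() - 0.03 * clean_max) < 3 * se

    def test_normalized_to_one(self, eeg_small, space_small):
        ms = simulate_data(eeg_small, self._dipoles(space_small), 3.0, seed=1)
        assert np.abs(ms.y).max() == pytest.approx(1.0, abs=1e-14)

    def test_reproducible(self, eeg_small, space_small):
        a = simulate_data(eeg_small, self._dipoles(space_small), 3.0, seed=42)
        b = simulate_data(eeg_small, self._dipoles(space_small), 3.0, seed=42)
        np.testing.assert_array_equal(a.y, b.y)

    def test_degenerate(self, eeg_small):
        with pytest.raises(DegenerateDataError):
            simulate_data(eeg_small, [], 0.0, seed=0)

    def test_far_dipole_warns(self, eeg_small):
        far = [DipoleSource(position=[1.0, 2.0, 3.0], moment_direction=[1, 0, 0],
                            amplitude=1.0)]
        with pytest.warns(UserWarning, match="mm from the nearest"):
            simulate_data(eeg_small, far, 0.0, seed=0)


class TestCombineEMEG:
    def test_identical_matrices_stack_plainly(self, eeg_small):
        fused = combine_emeg(eeg_small, eeg_small)
        np.testing.assert_array_equal(fused.matrix[: eeg_small.n_sensors], eeg_small.matrix)
        np.testing.assert_array_equal(fused.matrix[eeg_small.n_sensors :], eeg_small.matrix)

    def test_frobenius_matching(self, eeg_small, meg_small):
        fused = combine_emeg(eeg_small, meg_small)
        m = eeg_small.n_sensors
        top, bottom = fused.matrix[:m], fused.matrix[m:]
        assert np.linalg.norm(top) == pytest.approx(np.linalg.norm(bottom), rel=1e-12)
        # explicit factor-of-two check: ||L_eeg|| = 2 ||L_meg|| gives c = 2
        half = _scaled(eeg_small, 0.5)
        fused2 = combine_emeg(eeg_small, half)
        np.testing.assert_allclose(fused2.matrix[m:], 2.0 * half.matrix, rtol=1e-12)

    def test_data_scaled_with_matrix(self, eeg_small, meg_small, space_small):
        dips = [
            DipoleSource(position=space_small.positions[3],
                         moment_direction=[0, 1, 0], amplitude=5.0)
        ]
        y_e = simulate_data(eeg_small, dips, 3.0, seed=7)
        y_m = simulate_data(meg_small, dips, 3.0, seed=8)
        fused, data = combine_emeg(eeg_small, meg_small, y_e, y_m)
        c = np.linalg.norm(eeg_small.matrix) / np.linalg.norm(meg_small.matrix)
        m = eeg_small.n_sensors
        np.testing.assert_allclose(data.y[m:], c * y_m.y, rtol=1e-12)
        np.testing.assert_array_equal(data.y[:m], y_e.y)


def _scaled(lead, factor):
    from ramus import LeadField

    return LeadField(
        matrix=factor * lead.matrix,
        modality=lead.modality,
        units=lead.units,
        space=lead.space,
        sensors=lead.sensors,
    )
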