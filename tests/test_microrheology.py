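"""MSD computation and the two rheology branches."""

import numpy as np
import pandas as pd
import pytest

from mucochip import microrheology as mr
from mucochip import synthetic_data as synth
from mucochip.constants import BOLTZMANN_J_K, CP_PER_PA_S
from mucochip.containers import TrajectorySet

RADIUS_M = 100e-9
TEMP_K = 298.15


def _traj_from_xy(xy_by_particle, fps=20.0):
    rows = []
    for pid, xy in enumerate(xy_by_particle):
        for frame, (x, y) in enumerate(xy):
            rows.append((pid, frame, x, y))
    return TrajectorySet(
        pd.DataFrame(rows, columns=["particle", "frame", "x_um", "y_um"]),
        frame_rate_hz=fps,
    )


def brute_force_msd(xy_by_particle, max_lag, dt):
    """Independent oracle: explicit double loop over all ordered frame pairs."""
    curves = []
    for xy in xy_by_particle:
        n = len(xy)
        per_lag = []
        for lag in range(1, max_lag + 1):
            acc = []
            for t in range(n - lag):
                dx = xy[t + lag][0] - xy[t][0]
                dy = xy[t + lag][1] - xy[t][1]
                acc.append(dx * dx + dy * dy)
            per_lag.append(sum(acc) / len(acc))
        curves.append(per_lag)
    mean = [sum(c[k] for c in curves) / len(curves) for k in range(max_lag)]
    return np.array([(k + 1) * dt for k in range(max_lag)]), np.array(mean)


class TestComputeMSD:
    def test_matches_brute_force_oracle(self, rng):
        """compute_msd equals the all-pairs double loop on 3 x 20 frames."""
        xy = [rng.normal(size=(20, 2)).cumsum(axis=0) for _ in range(3)]
        traj = _traj_from_xy(xy)
        curve = mr.compute_msd(traj, max_lag_fraction=1.0, min_track_length=10)
        lags, msd = brute_force_msd([a.tolist() for a in xy], 19, 0.05)
        np.testing.assert_allclose(curve.lags_s, lags, rtol=1e-12)
        np.testing.assert_allclose(curve.msd_um2, msd, rtol=1e-12)

    def test_first_lag_is_frame_interval(self, rng):
        traj = _traj_from_xy([rng.normal(size=(30, 2))], fps=50.0)
        curve = mr.compute_msd(traj)
        assert curve.lags_s[0] == pytest.approx(1.0 / 50.0)

    def test_stationary_particle_zero(self):
        traj = _traj_from_xy([[(3.0, 4.0)] * 20])
        curve = mr.compute_msd(traj)
        np.testing.assert_array_equal(curve.msd_um2, 0.0)

    def test_additivity_under_duplication(self, rng):
        """Concatenating identical particle sets leaves the ensemble MSD unchanged."""
        xy = [rng.normal(size=(40, 2)).cumsum(axis=0) for _ in range(4)]
        single = mr.compute_msd(_traj_from_xy(xy))
        doubled = mr.compute_msd(_traj_from_xy(xy + xy))
        np.testing.assert_allclose(single.msd_um2, doubled.msd_um2, rtol=1e-12)

    def test_no_qualifying_tracks(self):
        traj = _traj_from_xy([[(0.0, 0.0)] * 5])
        with pytest.raises(mr.EmptyMSDError):
            mr.compute_msd(traj, min_track_length=10)


class TestPowerLaw:
    def test_ballistic_alpha_two(self):
        xy = [[(0.05 * t * 2.0, 0.0) for t in range(40)]]  # x = v t
        curve = mr.compute_msd(_traj_from_xy(xy))
        alpha, _ = mr.fit_power_law(curve)
        assert alpha == pytest.approx(2.0, abs=1e-9)

    def test_brownian_alpha_near_one(self, brownian_1cp_trajectories):
        _, traj = brownian_1cp_trajectories
        curve = mr.compute_msd(traj)
        alpha, _ = mr.fit_power_law(curve)
        assert alpha == pytest.approx(1.0, abs=0.05)

    def test_zero_msd_rejected(self):
        curve = mr.MSDCurve(np.array([0.05, 0.10, 0.15]), np.array([0.0, 1.0, 2.0]),
                            np.array([5, 5, 5]))
        with pytest.raises(ValueError, match="log"):
            mr.fit_power_law(curve)

    def test_needs_three_lags(self):
        curve = mr.MSDCurve(np.array([0.05, 0.10]), np.array([1.0, 2.0]),
                            np.array([5, 5]))
        with pytest.raises(ValueError):
            mr.fit_power_law(curve)


@pytest.mark.parametrize(
    "alpha,expected",
    [(1.0, "viscous"), (0.5, "viscoelastic"), (0.95, "viscoelastic"),
     (0.951, "viscous")],
)
def test_classify_regime_boundary(alpha, expected):
    assert mr.classify_regime(alpha) == expected


def test_classify_rejects_nan():
    with pytest.raises(ValueError):
        mr.classify_regime(float("nan"))


class TestViscousBranch:
    def test_recovers_water_viscosity(self, brownian_1cp_trajectories):
        truth, traj = brownian_1cp_trajectories
        curve = mr.compute_msd(traj)
        res = mr.viscosity_viscous(curve, RADIUS_M, TEMP_K)
        assert res.viscosity_cp == pytest.approx(1.0, rel=0.10)
        assert res.regime == "viscous"

    def test_viscosity_scales_with_temperature(self):
        """eta ~ T/D: same MSD read at higher T gives proportionally more eta."""
        curve = mr.MSDCurve(
            np.arange(1, 11) * 0.05, np.arange(1, 11) * 0.05 * 8.7,
            np.full(10, 100),
        )
        r1 = mr.viscosity_viscous(curve, RADIUS_M, 298.15)
        r2 = mr.viscosity_viscous(curve, RADIUS_M, 2 * 298.15)
        assert r2.viscosity_cp == pytest.approx(2 * r1.viscosity_cp, rel=1e-12)

    def test_units_roundtrip(self):
        """Reported cP equals the Pa*s Stokes-Einstein value x 1000."""
        d_um2_s = 2.0
        curve = mr.MSDCurve(
            np.arange(1, 11) * 0.05, 4 * d_um2_s * np.arange(1, 11) * 0.05,
            np.full(10, 100),
        )
        res = mr.viscosity_viscous(curve, RADIUS_M, TEMP_K)
        eta_pa_s = BOLTZMANN_J_K * TEMP_K / (6 * np.pi * d_um2_s * 1e-12 * RADIUS_M)
        assert res.viscosity_cp == pytest.approx(eta_pa_s * CP_PER_PA_S, rel=1e-9)
        assert res.diffusion_coefficient_um2_s == pytest.approx(d_um2_s, rel=1e-9)


class TestViscoelasticBranch:
    def test_recovers_maxwell_parameters(self, maxwell_trajectories):
        truth, traj = maxwell_trajectories
        curve = mr.compute_msd(traj)
        res = mr.analyze_msd(curve, RADIUS_M, TEMP_K)
        assert res.regime == "viscoelastic"
        assert res.viscosity_cp == pytest.approx(20.0, rel=0.15)
        assert res.elastic_modulus_pa == pytest.approx(1.0, rel=0.15)

    def test_compliance_intercept_is_inverse_modulus(self):
        lags = np.arange(1, 11) * 0.05
        msd_m2 = synth.maxwell_msd_m2(lags, 0.02, 1.0, RADIUS_M, TEMP_K)
        curve = mr.MSDCurve(lags, msd_m2 * 1e12, np.full(10, 100))
        j = mr.creep_compliance(curve, RADIUS_M, TEMP_K)
        slope, intercept = np.polyfit(lags, j, 1)
        assert 1.0 / intercept == pytest.approx(1.0, rel=1e-9)   # G = 1 Pa
        assert 1.0 / slope == pytest.approx(0.02, rel=1e-9)      # eta = 20 cP

    def test_cross_branch_consistency(self, brownian_1cp_trajectories):
        """Viscous data pushed through the Maxwell branch: huge G, same eta."""
        truth, traj = brownian_1cp_trajectories
        curve = mr.compute_msd(traj)
        viscous = mr.viscosity_viscous(curve, RADIUS_M, TEMP_K)
        maxwell = mr.viscosity_viscoelastic(curve, RADIUS_M, TEMP_K)
        assert maxwell.viscosity_cp == pytest.approx(viscous.viscosity_cp, rel=0.10)
        # the fitted elastic term 1/G is a near-zero intercept: it must be
        # negligible against the viscous compliance at the longest lag
        j_max = mr.creep_compliance(curve, RADIUS_M, TEMP_K)[-1]
        assert 1.0 / maxwell.elastic_modulus_pa < 0.05 * j_max

    def test_decreasing_msd_rejected(self):
        curve = mr.MSDCurve(np.arange(1, 6) * 0.05, np.linspace(2.0, 1.0, 5),
                            np.full(5, 10))
        with pytest.raises(ValueError, match="slope"):
            mr.viscosity_viscoelastic(curve, RADIUS_M, TEMP_K)
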