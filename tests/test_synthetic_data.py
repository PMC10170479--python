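"""Generators: target laws, limits, determinism."""

import numpy as np
import pytest

from mucochip import synthetic_data as synth
from mucochip.constants import BOLTZMANN_J_K
from mucochip.impedance_fit import CircuitParams, circuit_impedance


# k_B T / (6 pi eta a) at eta = 1 cP, a = 100 nm, T = 298.15 K,
# frozen from an independent closed-form evaluation
D_WATER_100NM_M2_S = 2.1838e-12


def test_stokes_einstein_closed_form():
    d = synth.stokes_einstein_diffusivity(1e-3, 100e-9, 298.15)
    assert d == pytest.approx(D_WATER_100NM_M2_S, rel=1e-4)
    with pytest.raises(ValueError):
        synth.stokes_einstein_diffusivity(-1e-3, 100e-9, 298.15)


def test_ground_truth_validation():
    with pytest.raises(ValueError):
        synth.RheoGroundTruth(viscosity_pa_s=0.0)
    with pytest.raises(ValueError):
        synth.RheoGroundTruth(viscosity_pa_s=1e-3, elastic_modulus_pa=-1.0)
    with pytest.raises(ValueError):
        synth.RheoGroundTruth(viscosity_pa_s=1e-3, n_frames=1)


def test_brownian_msd_matches_4dt():
    """Empirical ensemble MSD tracks 4 D tau within 5% at short lags."""
    truth = synth.RheoGroundTruth(
        viscosity_pa_s=1e-3, n_particles=500, n_frames=100,
        localization_noise_sd_m=0.0, seed=3,
    )
    traj = synth.simulate_brownian_trajectories(truth)
    d_um2 = truth.diffusion_coefficient_m2_s() * 1e12
    # time averaging leaves few independent pairs at long lags, so the
    # tight per-lag check stops at 1/8 of the track length
    for lag in (1, 5, truth.n_frames // 8):
        tau = lag * truth.dt_s
        disp = []
        for pid, grp in traj.table.groupby("particle"):
            xy = grp[["x_um", "y_um"]].to_numpy()
            d = xy[lag:] - xy[:-lag]
            disp.append(np.mean(np.sum(d * d, axis=1)))
        assert np.mean(disp) == pytest.approx(4.0 * d_um2 * tau, rel=0.05)


def test_huge_viscosity_freezes_particles():
    truth = synth.RheoGroundTruth(
        viscosity_pa_s=1e6, n_particles=5, n_frames=20,
        localization_noise_sd_m=0.0, seed=0,
    )
    traj = synth.simulate_brownian_trajectories(truth)
    for pid in range(5):
        xy = traj.positions(pid)
        assert np.max(np.abs(xy - xy[0])) < 1e-3  # um


@pytest.mark.parametrize("generator", ["brownian", "viscoelastic"])
def test_trajectory_seed_determinism(generator):
    kwargs = dict(viscosity_pa_s=5e-3, n_particles=10, n_frames=30, seed=7)
    if generator == "viscoelastic":
        kwargs["elastic_modulus_pa"] = 2.0
    make = (synth.simulate_brownian_trajectories if generator == "brownian"
            else synth.simulate_viscoelastic_trajectories)
    a = make(synth.RheoGroundTruth(**kwargs))
    b = make(synth.RheoGroundTruth(**kwargs))
    assert a.table.equals(b.table)


def test_viscoelastic_msd_matches_maxwell_target(maxwell_trajectories):
    """Ensemble MSD within 5% of the analytic Maxwell curve at lags <= 1 s."""
    truth, traj = maxwell_trajectories
    lags = np.arange(1, 21) * truth.dt_s  # up to 1 s
    target = synth.maxwell_msd_m2(
        lags, truth.viscosity_pa_s, truth.elastic_modulus_pa,
        truth.particle_radius_m, truth.temperature_k,
    ) * 1e12
    for k, tau in enumerate(lags):
        lag = k + 1
        disp = []
        for pid, grp in traj.table.groupby("particle"):
            xy = grp[["x_um", "y_um"]].to_numpy()
            d = xy[lag:] - xy[:-lag]
            disp.append(np.mean(np.sum(d * d, axis=1)))
        assert np.mean(disp) == pytest.approx(target[k], rel=0.05)


def test_viscoelastic_stiff_limit_reduces_to_brownian():
    """G -> large: the Maxwell MSD collapses onto the pure-viscous 4 D t."""
    truth = synth.RheoGroundTruth(
        viscosity_pa_s=1e-3, elastic_modulus_pa=1e6,
        n_particles=300, n_frames=60, localization_noise_sd_m=0.0, seed=4,
    )
    traj = synth.simulate_viscoelastic_trajectories(truth)
    d_um2 = synth.stokes_einstein_diffusivity(1e-3, 100e-9, 298.15) * 1e12
    lag = 5
    disp = []
    for pid, grp in traj.table.groupby("particle"):
        xy = grp[["x_um", "y_um"]].to_numpy()
        d = xy[lag:] - xy[:-lag]
        disp.append(np.mean(np.sum(d * d, axis=1)))
    assert np.mean(disp) == pytest.approx(4.0 * d_um2 * lag * truth.dt_s, rel=0.05)


def test_maxwell_plateau_intercept():
    """MSD(0) = 2 k_B T / (3 pi a G)."""
    expected = 2.0 * BOLTZMANN_J_K * 298.15 / (3.0 * np.pi * 100e-9 * 1.0)
    assert synth.maxwell_msd_m2(0.0, 0.02, 1.0, 100e-9, 298.15) == pytest.approx(expected)


def test_wrong_branch_raises():
    visc = synth.RheoGroundTruth(viscosity_pa_s=1e-3)
    ve = synth.RheoGroundTruth(viscosity_pa_s=1e-3, elastic_modulus_pa=1.0)
    with pytest.raises(ValueError):
        synth.simulate_viscoelastic_trajectories(visc)
    with pytest.raises(ValueError):
        synth.simulate_brownian_trajectories(ve)


class TestRenderSpotVideo:
    def test_stationary_particle_argmax(self):
        import pandas as pd
        from mucochip.containers import TrajectorySet
        table = pd.DataFrame(
            {"particle": [0] * 5, "frame": range(5),
             "x_um": [20.0] * 5, "y_um": [31.0] * 5}
        )
        traj = TrajectorySet(table, frame_rate_hz=20.0)
        video, sidecar = synth.render_spot_video(
            traj, image_shape=(64, 64), pixel_size_um=1.0, snr=None)
        for t in range(5):
            y, x = np.unravel_index(np.argmax(video.frames[t]), (64, 64))
            assert (x, y) == (20, 31)
        assert sidecar["x_px"].iloc[0] == 20.0

    def test_out_of_frame_lists_frames(self):
        import pandas as pd
        from mucochip.containers import TrajectorySet
        table = pd.DataFrame(
            {"particle": [0, 0], "frame": [0, 1], "x_um": [5.0, 99.0],
             "y_um": [5.0, 5.0]}
        )
        traj = TrajectorySet(table, frame_rate_hz=20.0)
        with pytest.raises(ValueError, match=r"frames \[1\]"):
            synth.render_spot_video(traj, image_shape=(32, 32), pixel_size_um=1.0)

    def test_empty_set_gives_pure_noise(self):
        import pandas as pd
        from mucochip.containers import TrajectorySet
        empty = TrajectorySet(
            pd.DataFrame(columns=["particle", "frame", "x_um", "y_um"]),
            frame_rate_hz=20.0,
        )
        video, sidecar = synth.render_spot_video(
            empty, image_shape=(16, 16), n_frames=3, snr=10.0, seed=0)
        assert video.frames.shape == (3, 16, 16)
        assert len(sidecar) == 0
        with pytest.raises(ValueError):
            synth.render_spot_video(empty, image_shape=(16, 16))


class TestImpedanceGenerator:
    PARAMS = CircuitParams(100.0, 1000.0, 100e-9, 1e-6)

    def test_noiseless_identity(self):
        spec = synth.simulate_impedance_spectrum(self.PARAMS)
        np.testing.assert_allclose(
            spec.z_ohm, circuit_impedance(self.PARAMS, spec.freq_hz))

    def test_default_grid(self):
        freqs = synth.default_impedance_frequencies()
        assert len(freqs) == 50
        assert freqs[0] == pytest.approx(1e5)
        assert freqs[-1] == pytest.approx(0.1)
        ratios = freqs[:-1] / freqs[1:]
        np.testing.assert_allclose(ratios, ratios[0])  # logarithmic step

    def test_shorted_epithelium_ignores_membrane(self):
        """r_teer ~ 0 shorts the parallel RC: |Z| independent of c_mem."""
        a = synth.simulate_impedance_spectrum(
            CircuitParams(100.0, 1e-9, 100e-9, 1e-6))
        b = synth.simulate_impedance_spectrum(
            CircuitParams(100.0, 1e-9, 100e-5, 1e-6))
        np.testing.assert_allclose(a.modulus, b.modulus, rtol=1e-9)

    def test_noise_determinism(self):
        a = synth.simulate_impedance_spectrum(self.PARAMS, noise_fraction=0.02, seed=5)
        b = synth.simulate_impedance_spectrum(self.PARAMS, noise_fraction=0.02, seed=5)
        np.testing.assert_array_equal(a.z_ohm, b.z_ohm)


class TestCiliaTrace:
    def test_peak_count_matches_frequency(self):
        from scipy.signal import find_peaks
        trace = synth.simulate_cilia_trace(8.0, 100.0, 2.0)
        peaks, _ = find_peaks(trace)
        assert len(peaks) == 16  # 8 Hz x 2 s

    def test_zero_cbf_constant(self):
        trace = synth.simulate_cilia_trace(0.0, 100.0, 1.0)
        assert np.ptp(trace) == 0.0

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synth.simulate_cilia_trace(60.0, 100.0, 1.0)

    def test_seed_determinism(self):
        a = synth.simulate_cilia_trace(8.0, noise_sd=0.2, seed=9)
        b = synth.simulate_cilia_trace(8.0, noise_sd=0.2, seed=9)
        np.testing.assert_array_equal(a, b)


class TestTwoLayerZStack:
    def test_layer_placement(self):
        stack, truth = synth.simulate_two_layer_zstack(30.0, 1.0, seed=0)
        z = stack.z_um
        blue = stack.channel("blue").max(axis=(1, 2))
        red = stack.channel("red").max(axis=(1, 2))
        assert z[np.nonzero(blue)[0][-1]] == truth["cell_layer_top_um"]
        assert z[np.nonzero(red)[0][0]] == truth["bead_layer_lo_um"]
        assert truth["bead_layer_lo_um"] - truth["cell_layer_top_um"] == 30.0

    def test_gap_rounding_warns_and_records(self):
        with pytest.warns(UserWarning, match="rounded"):
            _, truth = synth.simulate_two_layer_zstack(30.4, 1.0, seed=0)
        assert truth["gap_rounded_um"] == 30.0

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_two_layer_zstack(-1.0, 1.0)

    def test_seed_determinism(self):
        a, _ = synth.simulate_two_layer_zstack(10.0, 1.0, noise_sd=5.0, seed=2)
        b, _ = synth.simulate_two_layer_zstack(10.0, 1.0, noise_sd=5.0, seed=2)
        np.testing.assert_array_equal(a.planes, b.planes)
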