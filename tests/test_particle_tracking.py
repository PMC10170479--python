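"""Detection and proximity-principle linking."""

import numpy as np
import pandas as pd
import pytest

from mucochip import particle_tracking as pt
from mucochip import synthetic_data as synth
from mucochip.containers import TrajectorySet


def _stationary_traj(x_um, y_um, n_frames=1, fps=20.0):
    table = pd.DataFrame(
        {"particle": [0] * n_frames, "frame": range(n_frames),
         "x_um": [x_um] * n_frames, "y_um": [y_um] * n_frames}
    )
    return TrajectorySet(table, frame_rate_hz=fps)


class TestDetectSpots:
    def test_subpixel_centroid_accuracy(self):
        """A noiseless Gaussian spot at (10.3, 20.7) px localizes to < 0.1 px."""
        traj = _stationary_traj(10.3, 20.7)
        video, _ = synth.render_spot_video(
            traj, image_shape=(48, 48), pixel_size_um=1.0, snr=None)
        det = pt.detect_spots(video.frames[0], intensity_threshold=120.0)
        assert len(det) == 1
        assert det["x_um"].iloc[0] == pytest.approx(10.3, abs=0.1)
        assert det["y_um"].iloc[0] == pytest.approx(20.7, abs=0.1)

    def test_all_zero_frame(self):
        assert len(pt.detect_spots(np.zeros((32, 32)))) == 0

    def test_saturated_frame_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            pt.detect_spots(np.full((16, 16), 500.0), intensity_threshold=100.0)

    def test_negative_image_rejected(self):
        with pytest.raises(ValueError):
            pt.detect_spots(np.full((8, 8), -1.0))

    def test_two_separated_spots(self):
        table = pd.DataFrame(
            {"particle": [0, 1], "frame": [0, 0],
             "x_um": [10.0, 30.0], "y_um": [10.0, 30.0]}
        )
        traj = TrajectorySet(table, frame_rate_hz=20.0)
        video, _ = synth.render_spot_video(
            traj, image_shape=(48, 48), pixel_size_um=1.0, snr=None, n_frames=1)
        det = pt.detect_spots(video.frames[0], intensity_threshold=120.0)
        assert len(det) == 2

    def test_size_filter(self):
        img = np.zeros((32, 32))
        img[5, 5] = 500.0          # single-pixel speck, below min_size
        img[15:19, 15:19] = 500.0  # 16-px blob
        det = pt.detect_spots(img, intensity_threshold=100.0, min_size_px=4)
        assert len(det) == 1
        assert det["spot_area_px"].iloc[0] == 16


class TestLinking:
    def test_single_chain(self):
        det = pd.DataFrame(
            {"frame": range(10), "x_um": np.linspace(0, 1, 10),
             "y_um": np.zeros(10)}
        )
        traj = pt.link_trajectories(det, 1.0, frame_rate_hz=20.0)
        assert traj.n_particles == 1
        assert len(traj.table) == 10

    def test_negative_gate_rejected(self):
        with pytest.raises(ValueError):
            pt.link_trajectories(pd.DataFrame(columns=["frame", "x_um", "y_um"]),
                                 -1.0, 20.0)

    def test_gap_terminates_track(self):
        det = pd.DataFrame(
            {"frame": [0, 1, 3, 4], "x_um": [0.0] * 4, "y_um": [0.0] * 4}
        )
        traj = pt.link_trajectories(det, 1.0, frame_rate_hz=20.0)
        assert traj.n_particles == 2  # the missed frame 2 splits the track

    def test_tie_break_by_index(self):
        """Equidistant candidates resolve to the lower (frame, index) pair."""
        det = pd.DataFrame(
            {"frame": [0, 0, 1], "x_um": [0.0, 2.0, 1.0], "y_um": [0.0, 0.0, 0.0]}
        )
        traj = pt.link_trajectories(det, 5.0, frame_rate_hz=20.0)
        # detection (1.0, 0) continues particle 0 (first of the tied pair)
        p0 = traj.table[traj.table["particle"] == 0]
        assert list(p0["x_um"]) == [0.0, 1.0]

    def test_translation_invariance(self, rng):
        det = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(5), 4),
                "x_um": rng.uniform(0, 50, 20),
                "y_um": rng.uniform(0, 50, 20),
            }
        )
        shifted = det.assign(x_um=det["x_um"] + 123.0, y_um=det["y_um"] - 55.0)
        a = pt.link_trajectories(det, 30.0, 20.0)
        b = pt.link_trajectories(shifted, 30.0, 20.0)
        pd.testing.assert_frame_equal(
            a.table[["particle", "frame"]], b.table[["particle", "frame"]]
        )

    def test_track_count_bounded_by_detections(self, rng):
        det = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(6), 5),
                "x_um": rng.uniform(0, 20, 30),
                "y_um": rng.uniform(0, 20, 30),
            }
        )
        traj = pt.link_trajectories(det, 2.0, 20.0)
        assert traj.n_particles <= len(det)
        # within a frame, no two particles share a detection
        per_frame = traj.table.groupby("frame")["particle"].nunique()
        counts = det.groupby("frame").size()
        assert (per_frame <= counts.reindex(per_frame.index)).all()


class TestEndToEndTracking:
    def test_ground_truth_recovery(self):
        """Sparse Brownian beads: >= 95% of links match the generator."""
        truth = synth.RheoGroundTruth(
            viscosity_pa_s=0.05, n_particles=10, n_frames=40,
            localization_noise_sd_m=0.0, field_of_view_um=100.0, seed=21,
        )
        traj_true = synth.simulate_brownian_trajectories(truth)
        video, sidecar = synth.render_spot_video(
            traj_true, image_shape=(128, 128), pixel_size_um=1.0,
            snr=30.0, seed=22,
        )
        recovered = pt.track_video(video, max_displacement_um=2.0,
                                   intensity_threshold=130.0)
        recovered = pt.filter_min_length(recovered, 30)
        assert recovered.n_particles >= 9  # >= 9/10 beads tracked end to end

        # every recovered link must connect detections of one true particle
        good = bad = 0
        for pid, grp in recovered.table.groupby("particle"):
            xy = grp[["x_um", "y_um"]].to_numpy()
            frames = grp["frame"].to_numpy()
            for k in range(len(grp) - 1):
                def nearest_true(frame, x, y):
                    sub = sidecar[sidecar["frame"] == frame]
                    d = np.hypot(sub["x_um"] - x, sub["y_um"] - y)
                    return sub["particle"].iloc[int(np.argmin(d.to_numpy()))]
                a = nearest_true(frames[k], *xy[k])
                b = nearest_true(frames[k + 1], *xy[k + 1])
                good += a == b
                bad += a != b
        assert good / (good + bad) >= 0.95

    def test_detection_rate_on_rendered_fixture(self):
        truth = synth.RheoGroundTruth(
            viscosity_pa_s=0.05, n_particles=10, n_frames=10,
            localization_noise_sd_m=0.0, field_of_view_um=100.0, seed=5,
        )
        traj = synth.simulate_brownian_trajectories(truth)
        video, _ = synth.render_spot_video(
            traj, image_shape=(128, 128), pixel_size_um=1.0, snr=10.0, seed=6)
        det = pt.detect_video(video, intensity_threshold=130.0)
        per_frame = det.groupby("frame").size()
        assert (per_frame >= 9).all()
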