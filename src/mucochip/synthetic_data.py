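"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding
analysis assumes, so that parameter recovery can be verified without
wet-lab data:

* tracer-bead motion in mucus — Brownian (purely viscous medium) or a
  Gaussian process whose mean squared displacement follows the Maxwell
  creep law (viscoelastic medium);
* fluorescence videos of the beads (Gaussian spots + shot noise) for the
  tracking stage;
* equivalent-circuit impedance spectra with multiplicative complex noise;
* periodic cilia intensity traces;
* two-channel confocal z-stacks with a nuclear slab and a bead layer
  separated by a known mucus gap.

Default acquisition settings mirror the on-chip protocols: 200 nm beads
(radius 100 nm) recorded for 5 s at 20 frames/s in 8 regions at room
temperature; impedance from 100 kHz to 0.1 Hz in 50 logarithmic steps;
cilia videos at 100 frames/s. All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BOLTZMANN_J_K, ROOM_TEMPERATURE_K, UM_PER_M
from .containers import TrajectorySet, VideoStack, ZStack
from .impedance_fit import CircuitParams, ImpedanceSpectrum, circuit_impedance

DEFAULT_FRAME_RATE_HZ = 20.0      # MPT acquisition
DEFAULT_N_FRAMES = 100            # 5 s at 20 frames/s
DEFAULT_N_REGIONS = 8
DEFAULT_PARTICLE_RADIUS_M = 100e-9   # 200 nm diameter tracer beads
DEFAULT_LOCALIZATION_NOISE_M = 20e-9  # tracking error on positions

CILIA_FRAME_RATE_HZ = 100.0

IMPEDANCE_N_POINTS = 50
IMPEDANCE_F_MAX_HZ = 1e5
IMPEDANCE_F_MIN_HZ = 0.1


@dataclass
class RheoGroundTruth:
    """Ground-truth medium and acquisition parameters for bead motion.

    ``elastic_modulus_pa is None`` selects a purely viscous medium
    (Brownian motion); a positive value selects the Maxwell viscoelastic
    medium with creep compliance J(t) = 1/G + t/eta.
    """

    viscosity_pa_s: float
    elastic_modulus_pa: float | None = None
    particle_radius_m: float = DEFAULT_PARTICLE_RADIUS_M
    temperature_k: float = ROOM_TEMPERATURE_K
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    n_particles: int = 50
    n_frames: int = DEFAULT_N_FRAMES
    localization_noise_sd_m: float = DEFAULT_LOCALIZATION_NOISE_M
    field_of_view_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.viscosity_pa_s <= 0:
            raise ValueError("viscosity must be strictly positive")
        if self.elastic_modulus_pa is not None and self.elastic_modulus_pa <= 0:
            raise ValueError("elastic modulus must be strictly positive when present")
        if self.particle_radius_m <= 0:
            raise ValueError("particle radius must be strictly positive")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be strictly positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be strictly positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.localization_noise_sd_m < 0:
            raise ValueError("localization noise must be non-negative")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def diffusion_coefficient_m2_s(self) -> float:
        return stokes_einstein_diffusivity(
            self.viscosity_pa_s, self.particle_radius_m, self.temperature_k
        )


def stokes_einstein_diffusivity(viscosity_pa_s: float, radius_m: float,
                                temperature_k: float) -> float:
    """D = k_B T / (6 pi eta a), in m^2/s."""
    if min(viscosity_pa_s, radius_m, temperature_k) <= 0:
        raise ValueError("viscosity, radius and temperature must be positive")
    return BOLTZMANN_J_K * temperature_k / (6.0 * np.pi * viscosity_pa_s * radius_m)


def maxwell_msd_m2(t_s, viscosity_pa_s: float, elastic_modulus_pa: float,
                   radius_m: float, temperature_k: float) -> np.ndarray:
    """Two-dimensional Maxwell-medium MSD target (m^2).

    MSD(t) = (2 k_B T / (3 pi a)) * (1/G + t/eta), the generalized
    Stokes-Einstein image of the Maxwell creep compliance in 2D.
    """
    amp = 2.0 * BOLTZMANN_J_K * temperature_k / (3.0 * np.pi * radius_m)
    return amp * (1.0 / elastic_modulus_pa + np.asarray(t_s, dtype=float) / viscosity_pa_s)


def _start_positions(rng: np.random.Generator, n: int, fov_um: float) -> np.ndarray:
    return rng.uniform(0.1 * fov_um, 0.9 * fov_um, size=(n, 2))


def _to_trajectory_set(xy_um: np.ndarray, truth: RheoGroundTruth,
                       region_id) -> TrajectorySet:
    """xy_um: (n_particles, n_frames, 2) -> long table in um."""
    n_p, n_f, _ = xy_um.shape
    table = pd.DataFrame(
        {
            "particle": np.repeat(np.arange(n_p), n_f),
            "frame": np.tile(np.arange(n_f), n_p),
            "x_um": xy_um[:, :, 0].ravel(),
            "y_um": xy_um[:, :, 1].ravel(),
        }
    )
    return TrajectorySet(table, truth.frame_rate_hz, region_id=region_id)


def simulate_brownian_trajectories(truth: RheoGroundTruth,
                                   region_id: str | int = 0) -> TrajectorySet:
    """Free diffusion in a purely viscous medium.

    Per-axis displacement increments are i.i.d. Gaussian with variance
    2 D dt, D = k_B T / (6 pi eta a). Optional localization noise is
    added independently to every recorded position.
    """
    if truth.elastic_modulus_pa is not None:
        raise ValueError("ground truth has an elastic modulus; "
                         "use simulate_viscoelastic_trajectories")
    rng = np.random.default_rng(truth.seed)
    d_um2_s = truth.diffusion_coefficient_m2_s() * UM_PER_M**2
    step_sd = np.sqrt(2.0 * d_um2_s * truth.dt_s)
    starts = _start_positions(rng, truth.n_particles, truth.field_of_view_um)
    steps = rng.normal(0.0, step_sd,
                       size=(truth.n_particles, truth.n_frames - 1, 2))
    xy = np.concatenate(
        [starts[:, None, :], starts[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )
    if truth.localization_noise_sd_m > 0:
        xy = xy + rng.normal(0.0, truth.localization_noise_sd_m * UM_PER_M,
                             size=xy.shape)
    return _to_trajectory_set(xy, truth, region_id)


def simulate_viscoelastic_trajectories(truth: RheoGroundTruth,
                                       region_id: str | int = 0) -> TrajectorySet:
    """Gaussian-process bead motion with the Maxwell MSD as exact target.

    Positions are sampled from a zero-mean Gaussian process with
    covariance C(t, s) = [M(t) + M(s) - M(|t - s|)] / 2 per axis, where
    M is the per-axis target MSD and M(0) := 0 on the diagonal of the
    displacement law. With this construction E[(x(t) - x(s))^2] equals
    the target at every discrete lag, including the elastic plateau
    2 k_B T / (3 pi a G) as t -> 0, so the empirical ensemble MSD
    converges to the analytic Maxwell curve as n_particles grows.
    """
    if truth.elastic_modulus_pa is None:
        raise ValueError("ground truth lacks an elastic modulus; "
                         "use simulate_brownian_trajectories")
    rng = np.random.default_rng(truth.seed)
    t = np.arange(truth.n_frames) * truth.dt_s

    def m_axis(tau):  # per-axis MSD in um^2 (half of the 2D MSD)
        return 0.5 * maxwell_msd_m2(
            tau, truth.viscosity_pa_s, truth.elastic_modulus_pa,
            truth.particle_radius_m, truth.temperature_k,
        ) * UM_PER_M**2

    g = m_axis(t)                        # includes the plateau, also at t=0
    lag = np.abs(t[:, None] - t[None, :])
    m_pair = m_axis(lag)
    np.fill_diagonal(m_pair, 0.0)        # M(0) := 0 for the displacement law
    cov = 0.5 * (g[:, None] + g[None, :] - m_pair)

    jitter = 0.0
    for attempt in range(4):
        try:
            chol = np.linalg.cholesky(
                cov + jitter * np.eye(truth.n_frames) if jitter else cov)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 100.0, 1e-12 * np.trace(cov) / truth.n_frames)
    else:
        raise np.linalg.LinAlgError(
            "target-MSD covariance is not positive definite and could not "
            "be regularized")
    if jitter:
        warnings.warn(f"covariance regularized with jitter {jitter:.3e} um^2")

    starts = _start_positions(rng, truth.n_particles, truth.field_of_view_um)
    z = rng.standard_normal((truth.n_frames, truth.n_particles, 2))
    wander = np.einsum("ij,jpk->ipk", chol, z)       # (n_frames, n_p, 2)
    xy = starts[:, None, :] + np.transpose(wander, (1, 0, 2))
    if truth.localization_noise_sd_m > 0:
        xy = xy + rng.normal(0.0, truth.localization_noise_sd_m * UM_PER_M,
                             size=xy.shape)
    return _to_trajectory_set(xy, truth, region_id)


def render_spot_video(
    traj: TrajectorySet,
    image_shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.5,
    psf_sigma_px: float = 1.3,
    snr: float | None = 10.0,
    background: float = 100.0,
    n_frames: int | None = None,
    seed: int = 0,
) -> tuple[VideoStack, pd.DataFrame]:
    """Render trajectories as Gaussian spots with optional shot noise.

    ``snr=None`` disables noise entirely (ideal detector); otherwise the
    spot amplitude is ``snr * sqrt(background)`` and Poisson shot noise is
    applied to background + signal. Returns the video and a ground-truth
    sidecar table with the exact pixel positions.
    """
    h, w = image_shape
    if n_frames is None:
        n_frames = (int(traj.table["frame"].max()) + 1
                    if len(traj.table) else 0)
        if n_frames == 0:
            raise ValueError("empty trajectory set: pass n_frames explicitly "
                             "to render a pure-noise video")
    table = traj.table.copy()
    table["x_px"] = table["x_um"] / pixel_size_um
    table["y_px"] = table["y_um"] / pixel_size_um
    out = (
        (table["x_px"] < 0) | (table["x_px"] > w - 1)
        | (table["y_px"] < 0) | (table["y_px"] > h - 1)
    )
    if out.any():
        bad = sorted(table.loc[out, "frame"].unique().tolist())
        raise ValueError(f"positions outside the field of view in frames {bad}")

    amplitude = 1000.0 if snr is None else float(snr) * np.sqrt(background)
    frames = np.full((n_frames, h, w), background, dtype=float)
    half = int(np.ceil(4 * psf_sigma_px))
    for row in table.itertuples():
        fr = int(row.frame)
        cx, cy = row.x_px, row.y_px
        x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 2, w)
        y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 2, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        frames[fr, y0:y1, x0:x1] += amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * psf_sigma_px**2)
        )
    if snr is not None:
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(float)
    video = VideoStack(frames, traj.frame_rate_hz, pixel_size_um,
                       metadata={"snr": snr, "psf_sigma_px": psf_sigma_px})
    sidecar = table[["particle", "frame", "x_um", "y_um", "x_px", "y_px"]].copy()
    return video, sidecar


def default_impedance_frequencies() -> np.ndarray:
    """50 log-spaced points from 100 kHz down to 0.1 Hz (descending)."""
    return np.logspace(np.log10(IMPEDANCE_F_MAX_HZ), np.log10(IMPEDANCE_F_MIN_HZ),
                       IMPEDANCE_N_POINTS)


def simulate_impedance_spectrum(
    params: CircuitParams,
    freqs_hz: np.ndarray | None = None,
    noise_fraction: float = 0.0,
    seed: int = 0,
    **metadata,
) -> ImpedanceSpectrum:
    """Evaluate the equivalent circuit on a frequency grid, with optional
    multiplicative complex Gaussian noise of the given relative magnitude."""
    freqs = default_impedance_frequencies() if freqs_hz is None else np.asarray(freqs_hz, float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    z = circuit_impedance(params, freqs)
    if noise_fraction:
        rng = np.random.default_rng(seed)
        g = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
        z = z * (1.0 + noise_fraction * g / np.sqrt(2.0))
    return ImpedanceSpectrum(freqs, z, metadata)


def simulate_cilia_trace(
    cbf_hz: float,
    frame_rate_hz: float = CILIA_FRAME_RATE_HZ,
    duration_s: float = 2.0,
    noise_sd: float = 0.0,
    amplitude: float = 1.0,
    baseline: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Periodic ROI-intensity trace with ``cbf_hz`` cycles per second.

    Requires frame_rate > 2 * cbf (Nyquist); cbf = 0 yields a constant
    trace (plus noise if requested).
    """
    if cbf_hz < 0 or frame_rate_hz <= 0 or duration_s <= 0:
        raise ValueError("cbf, frame rate and duration must be non-negative/positive")
    if cbf_hz > 0 and frame_rate_hz <= 2.0 * cbf_hz:
        raise ValueError(
            f"undersampled: frame rate {frame_rate_hz} Hz must exceed the "
            f"Nyquist rate 2 x {cbf_hz} Hz for a {cbf_hz} Hz beat"
        )
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    trace = baseline + amplitude * np.sin(2.0 * np.pi * cbf_hz * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    return trace


def render_trace_video(
    trace: np.ndarray,
    image_shape: tuple[int, int] = (32, 32),
    frame_rate_hz: float = CILIA_FRAME_RATE_HZ,
    pixel_size_um: float = 0.3,
) -> VideoStack:
    """Spread an intensity trace uniformly over a small field of view,
    emulating a flickering ciliated patch for the ROI-trace stage."""
    trace = np.asarray(trace, dtype=float)
    frames = np.broadcast_to(
        trace[:, None, None], (trace.size, *image_shape)
    ).copy()
    return VideoStack(frames, frame_rate_hz, pixel_size_um)


def simulate_two_layer_zstack(
    gap_um: float,
    z_spacing_um: float = 1.0,
    xy_shape: tuple[int, int] = (64, 64),
    cell_layer_top_um: float = 20.0,
    bead_layer_um: float = 4.0,
    n_nuclei: int = 15,
    n_beads: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ZStack, dict]:
    """Two fluorescent layers separated by a known mucus gap.

    The blue channel is bright in a bottom slab (Hoechst-stained nuclei,
    z in [0, cell_layer_top]); the red channel shows aerosolized beads in
    a slab starting ``gap_um`` above the top of the blue slab. Gaps that
    do not fall on the z grid are rounded (with a warning) and the
    rounded value is recorded in the returned ground truth.
    """
    if gap_um < 0:
        raise ValueError("gap must be non-negative")
    if z_spacing_um <= 0:
        raise ValueError("z spacing must be strictly positive")
    gap_rounded = round(gap_um / z_spacing_um) * z_spacing_um
    if abs(gap_rounded - gap_um) > 1e-9:
        warnings.warn(
            f"gap {gap_um} um is not representable on a {z_spacing_um} um "
            f"z grid; rounded to {gap_rounded} um"
        )
    cell_top = round(cell_layer_top_um / z_spacing_um) * z_spacing_um
    bead_lo = cell_top + gap_rounded
    bead_hi = bead_lo + bead_layer_um
    n_z = int(np.ceil(bead_hi / z_spacing_um)) + 3
    z = np.arange(n_z) * z_spacing_um
    h, w = xy_shape

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    blue_mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        blue_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 4.0**2
    red_mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_beads):
        cy, cx = rng.uniform(2, h - 2), rng.uniform(2, w - 2)
        red_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 1.5**2

    planes = np.zeros((n_z, 2, h, w), dtype=float)
    in_blue = z <= cell_top + 1e-9
    in_red = (z >= bead_lo - 1e-9) & (z <= bead_hi + 1e-9)
    planes[in_blue, 0] = 1000.0 * blue_mask
    planes[in_red, 1] = 1000.0 * red_mask
    if noise_sd > 0:
        planes = planes + rng.normal(0.0, noise_sd, size=planes.shape)

    truth = {
        "gap_requested_um": float(gap_um),
        "gap_rounded_um": float(gap_rounded),
        "cell_layer_top_um": float(cell_top),
        "bead_layer_lo_um": float(bead_lo),
        "bead_layer_hi_um": float(bead_hi),
    }
    stack = ZStack(planes, z_spacing_um, channel_names=("blue", "red"),
                   metadata={"ground_truth": truth})
    return stack, truth
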