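"""Mean squared displacements and mucus rheology from bead trajectories.

For each particle the time-averaged MSD over all ordered frame pairs is
computed per lag, then averaged without weights across the particles of a
region. The ensemble curve is classified by the power-law exponent alpha
of MSD ~ tau^alpha:

* alpha > 0.95 — purely viscous medium. MSD = 2 n D tau with n = 2
  dimensions; D from a through-origin linear fit, and the viscosity from
  the Stokes-Einstein relation eta = k_B T / (6 pi D a), reported in cP.
* alpha <= 0.95 — viscoelastic medium. The MSD is converted to the creep
  compliance J(t) = (3 pi a / (2 k_B T)) MSD(t) (generalized
  Stokes-Einstein, 2D) and fitted with the Maxwell law
  J(t) = 1/G + t/eta, giving the elastic modulus from the intercept and
  the viscosity from the inverse slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BOLTZMANN_J_K, CP_PER_PA_S, M_PER_UM
from .containers import TrajectorySet

#: Exponent threshold separating viscous from viscoelastic behavior.
ALPHA_VISCOUS_THRESHOLD = 0.95

#: Fraction of the trajectory length up to which lags are trusted; longer
#: lags average too few displacement pairs and are noise-dominated.
DEFAULT_MAX_LAG_FRACTION = 0.25

N_DIMENSIONS = 2


class EmptyMSDError(ValueError):
    """No trajectory satisfied the minimum-length rule."""


@dataclass
class MSDCurve:
    """Ensemble MSD: lag times (s), MSD (um^2) and per-lag particle counts."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_contributing: np.ndarray
    region_id: str | int = 0

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags_s, "msd_um2": self.msd_um2,
             "n": self.n_contributing}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RheologyResult:
    """Outcome of one region's rheology analysis."""

    alpha: float
    regime: str
    viscosity_cp: float
    diffusion_coefficient_um2_s: float | None = None
    elastic_modulus_pa: float | None = None
    fit_range: tuple = (0, None)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "regime": self.regime,
            "viscosity_cp": self.viscosity_cp,
            "diffusion_coefficient_um2_s": self.diffusion_coefficient_um2_s,
            "elastic_modulus_pa": self.elastic_modulus_pa,
            "fit_range": list(self.fit_range[:1]) + [self.fit_range[1]],
            **self.extras,
        }


def _single_track_msd(xy: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD of one track for lags 1..max_lag (um^2)."""
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        d = xy[k:] - xy[:-k]
        out[k - 1] = np.mean(np.sum(d * d, axis=1))
    return out


def compute_msd(
    traj: TrajectorySet,
    max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION,
    min_track_length: int = 10,
) -> MSDCurve:
    """Ensemble MSD of a region.

    Each qualifying particle contributes its time-averaged MSD over all
    ordered frame pairs at each lag, up to ``max_lag_fraction`` of its own
    track length; the ensemble curve is the unweighted mean over the
    particles available at each lag.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    per_particle: list[np.ndarray] = []
    for pid, grp in traj.table.groupby("particle"):
        xy = grp.sort_values("frame")[["x_um", "y_um"]].to_numpy(dtype=float)
        n = len(xy)
        if n < min_track_length:
            continue
        max_lag = max(int(np.floor(max_lag_fraction * (n - 1))), 1)
        per_particle.append(_single_track_msd(xy, max_lag))
    if not per_particle:
        raise EmptyMSDError(
            f"no trajectory of >= {min_track_length} frames to average"
        )
    k_max = max(len(m) for m in per_particle)
    msd = np.zeros(k_max)
    count = np.zeros(k_max, dtype=int)
    for m in per_particle:
        msd[: len(m)] += m
        count[: len(m)] += 1
    msd /= count
    lags = np.arange(1, k_max + 1) * traj.dt_s
    return MSDCurve(lags, msd, count, traj.region_id)


def _resolve_range(curve: MSDCurve, fit_range) -> slice:
    if fit_range is None:
        return slice(0, len(curve.lags_s))
    return slice(fit_range[0], fit_range[1])


def fit_power_law(curve: MSDCurve, fit_range: tuple | None = None
                  ) -> tuple[float, float]:
    """Least-squares line in log(tau)-log(MSD); returns (alpha, prefactor).

    The prefactor is the MSD extrapolated to tau = 1 s.
    """
    sel = _resolve_range(curve, fit_range)
    tau = curve.lags_s[sel]
    msd = curve.msd_um2[sel]
    if len(tau) < 3:
        raise ValueError("need at least 3 lags in the fit range")
    if np.any(msd <= 0):
        raise ValueError("zero MSD values in the fit range: log-log fit undefined")
    alpha, log_pref = np.polyfit(np.log(tau), np.log(msd), 1)
    return float(alpha), float(np.exp(log_pref))


def classify_regime(alpha: float) -> str:
    """'viscous' iff alpha > 0.95 (strict), else 'viscoelastic'."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    return "viscous" if alpha > ALPHA_VISCOUS_THRESHOLD else "viscoelastic"


def viscosity_viscous(
    curve: MSDCurve,
    particle_radius_m: float,
    temperature_k: float,
    fit_range: tuple | None = None,
) -> RheologyResult:
    """Viscous-branch viscosity from MSD = 4 D tau (through-origin fit)."""
    sel = _resolve_range(curve, fit_range)
    tau = curve.lags_s[sel]
    msd_m2 = curve.msd_um2[sel] * M_PER_UM**2
    d_m2_s = float(np.sum(tau * msd_m2) / (2 * N_DIMENSIONS * np.sum(tau * tau)))
    if d_m2_s <= 0:
        raise ValueError("fitted diffusion coefficient is non-positive")
    eta_pa_s = BOLTZMANN_J_K * temperature_k / (
        6.0 * np.pi * d_m2_s * particle_radius_m
    )
    alpha, _ = fit_power_law(curve, fit_range)
    return RheologyResult(
        alpha=alpha,
        regime="viscous",
        viscosity_cp=eta_pa_s * CP_PER_PA_S,
        diffusion_coefficient_um2_s=d_m2_s / M_PER_UM**2,
        fit_range=(sel.start, sel.stop),
    )


def creep_compliance(curve: MSDCurve, particle_radius_m: float,
                     temperature_k: float) -> np.ndarray:
    """J(t) = (3 pi a / (2 k_B T)) MSD(t), in 1/Pa."""
    msd_m2 = curve.msd_um2 * M_PER_UM**2
    return 3.0 * np.pi * particle_radius_m * msd_m2 / (
        2.0 * BOLTZMANN_J_K * temperature_k
    )


def viscosity_viscoelastic(
    curve: MSDCurve,
    particle_radius_m: float,
    temperature_k: float,
    fit_range: tuple | None = None,
) -> RheologyResult:
    """Maxwell-branch analysis: J(t) = 1/G + t/eta by ordinary least squares."""
    sel = _resolve_range(curve, fit_range)
    tau = curve.lags_s[sel]
    j = creep_compliance(curve, particle_radius_m, temperature_k)[sel]
    if len(tau) < 2:
        raise ValueError("need at least 2 lags for the Maxwell fit")
    slope, intercept = np.polyfit(tau, j, 1)
    if slope <= 0:
        raise ValueError(
            f"Maxwell fit slope {slope:.3e} 1/(Pa*s) is non-positive; "
            "the MSD does not grow with lag over the fit range"
        )
    if intercept <= 0:
        raise ValueError(
            f"Maxwell fit intercept {intercept:.3e} 1/Pa is non-positive; "
            "no elastic plateau is resolvable (the medium may be purely "
            "viscous: use the viscous branch)"
        )
    alpha, _ = fit_power_law(curve, fit_range)
    return RheologyResult(
        alpha=alpha,
        regime="viscoelastic",
        viscosity_cp=(1.0 / slope) * CP_PER_PA_S,
        elastic_modulus_pa=float(1.0 / intercept),
        fit_range=(sel.start, sel.stop),
    )


def analyze_msd(
    curve: MSDCurve,
    particle_radius_m: float,
    temperature_k: float,
    fit_range: tuple | None = None,
) -> RheologyResult:
    """Classify the regime from alpha and dispatch to the right branch."""
    alpha, _ = fit_power_law(curve, fit_range)
    if classify_regime(alpha) == "viscous":
        return viscosity_viscous(curve, particle_radius_m, temperature_k, fit_range)
    return viscosity_viscoelastic(curve, particle_radius_m, temperature_k, fit_range)
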