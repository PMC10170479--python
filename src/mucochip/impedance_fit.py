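"""Equivalent-circuit analysis of epithelial impedance spectra.

The epithelium on its porous support is modeled as an ohmic tight-junction
resistance R_teer in parallel with the plasma-membrane capacitance C_mem,
in series with the solution resistance R_sol and the electrode capacitance
C_e::

    Z(w) = R_sol + 1/(j*w*C_e) + R_teer / (1 + j*w*R_teer*C_mem)

Spectra are acquired from 100 kHz down to 0.1 Hz (50 points, logarithmic
step). Fitting is complex nonlinear least squares on stacked (Re, Im)
residuals weighted by 1/|Z| so every decade contributes; positivity is
enforced by optimizing the log-parameters. The Bode modulus at 12 Hz is
the scalar used to monitor epithelium growth between full fits, and the
fitted R_teer (in Ohm) and C_mem (in nF) form the barrier time course,
which typically peaks around day 3 of culture as tight junctions mature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DEFAULT_BODE_FREQUENCY_HZ = 12.0


class CircuitFitError(RuntimeError):
    """Raised when the circuit fit does not converge or is degenerate."""

    def __init__(self, message: str, best_params=None, residual=None):
        super().__init__(message)
        self.best_params = best_params
        self.residual = residual


@dataclass
class CircuitParams:
    """Elements of the epithelial equivalent circuit (SI units)."""

    r_sol: float
    r_teer: float
    c_membrane: float
    c_electrode: float

    def __post_init__(self) -> None:
        for name in ("r_sol", "r_teer", "c_membrane", "c_electrode"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def c_membrane_nf(self) -> float:
        return self.c_membrane * 1e9

    def as_array(self) -> np.ndarray:
        return np.array([self.r_sol, self.r_teer, self.c_membrane, self.c_electrode])


@dataclass
class ImpedanceSpectrum:
    """Frequencies (Hz) and complex impedance (Ohm); descending grids allowed."""

    freq_hz: np.ndarray
    z_ohm: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.z_ohm = np.asarray(self.z_ohm, dtype=complex)
        if self.freq_hz.shape != self.z_ohm.shape:
            raise ValueError("freq and z arrays must have the same shape")
        if np.any(self.freq_hz <= 0):
            raise ValueError("frequencies must be strictly positive")
        if not (np.all(np.isfinite(self.z_ohm.real)) and np.all(np.isfinite(self.z_ohm.imag))):
            raise ValueError("impedance values must be finite")

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.z_ohm)

    def sorted_ascending(self) -> "ImpedanceSpectrum":
        order = np.argsort(self.freq_hz)
        return ImpedanceSpectrum(self.freq_hz[order], self.z_ohm[order], dict(self.metadata))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "freq_hz": self.freq_hz,
                "z_real_ohm": self.z_ohm.real,
                "z_imag_ohm": self.z_ohm.imag,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **metadata) -> "ImpedanceSpectrum":
        df = pd.read_csv(path)
        return cls(
            df["freq_hz"].to_numpy(),
            df["z_real_ohm"].to_numpy() + 1j * df["z_imag_ohm"].to_numpy(),
            metadata,
        )


@dataclass
class CircuitFit:
    """Fitted circuit parameters with fit diagnostics.

    ``residual`` is the relative RMS of the weighted complex residuals;
    ``covariance`` is the Gauss-Newton estimate for the linear parameters
    (ordered r_sol, r_teer, c_membrane, c_electrode).
    """

    r_sol: float
    r_teer: float
    c_membrane: float
    c_electrode: float
    residual: float
    covariance: np.ndarray | None = None

    @property
    def params(self) -> CircuitParams:
        return CircuitParams(self.r_sol, self.r_teer, self.c_membrane, self.c_electrode)

    @property
    def c_membrane_nf(self) -> float:
        return self.c_membrane * 1e9


def circuit_impedance(params: CircuitParams, freq_hz) -> np.ndarray | complex:
    """Evaluate the equivalent-circuit impedance at the given frequencies."""
    freq = np.asarray(freq_hz, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequency must be strictly positive")
    omega = 2.0 * np.pi * freq
    z = (
        params.r_sol
        + 1.0 / (1j * omega * params.c_electrode)
        + params.r_teer / (1.0 + 1j * omega * params.r_teer * params.c_membrane)
    )
    if np.isscalar(freq_hz):
        return complex(z)
    return z


def _auto_init(spec: ImpedanceSpectrum) -> CircuitParams:
    """Initial guess from the spectrum's asymptotes.

    * r_sol: |Z| at the highest frequency (both capacitors short).
    * c_electrode: from Im(Z) at the lowest frequency, where the series
      capacitor dominates, Im(Z) ~ -1/(w*C_e).
    * r_teer: Re(Z) - r_sol read at the frequency of minimal |Im(Z)|,
      the plateau between the two corners where neither capacitor
      dominates and relative noise is smallest.
    * c_membrane: from the corner frequency where Re(Z) - r_sol crosses
      half of r_teer.
    """
    s = spec.sorted_ascending()
    f, z = s.freq_hz, s.z_ohm
    r_sol = max(abs(z[-1]), 1e-6)

    k_plateau = int(np.argmin(np.abs(z.imag)))
    r_teer = max(z[k_plateau].real - r_sol, 0.1 * r_sol)

    im_low = z[0].imag
    if im_low < 0:
        c_e = 1.0 / (2.0 * np.pi * f[0] * (-im_low))
    else:  # no capacitive tail visible; fall back to a mid-range guess
        c_e = 1.0 / (2.0 * np.pi * f[0] * r_sol)

    # corner of the parallel RC: highest frequency where Re(Z) - r_sol
    # still exceeds half of r_teer
    above = np.nonzero(z.real - r_sol >= 0.5 * r_teer)[0]
    f_corner = f[above[-1]] if above.size else np.sqrt(f[0] * f[-1])
    c_m = 1.0 / (2.0 * np.pi * f_corner * r_teer)
    return CircuitParams(r_sol, r_teer, c_m, c_e)


def fit_circuit(
    spec: ImpedanceSpectrum,
    init: CircuitParams | None = None,
    max_nfev: int = 2000,
) -> CircuitFit:
    """Fit the equivalent circuit to a spectrum by weighted complex NLLS.

    Requires at least 8 frequency points spanning at least 3 decades.
    Raises :class:`CircuitFitError` on non-convergence (carrying the best
    iterate) or when the epithelial branch is unidentifiable (e.g. the
    spectrum of a bare resistor, where r_teer collapses).
    """
    s = spec.sorted_ascending()
    if s.freq_hz.size < 8:
        raise ValueError("need at least 8 frequency points")
    if np.log10(s.freq_hz[-1] / s.freq_hz[0]) < 3.0:
        raise ValueError("spectrum must span at least 3 frequency decades")

    p0 = init if init is not None else _auto_init(s)
    weight = 1.0 / np.abs(s.z_ohm)
    omega = 2.0 * np.pi * s.freq_hz

    def residuals(log_p: np.ndarray) -> np.ndarray:
        # evaluate the raw circuit expression: clipping keeps trial steps
        # of the optimizer finite without the dataclass validation
        r_sol, r_teer, c_m, c_e = np.exp(np.clip(log_p, -200.0, 200.0))
        z = (r_sol + 1.0 / (1j * omega * c_e)
             + r_teer / (1.0 + 1j * omega * r_teer * c_m))
        dz = (z - s.z_ohm) * weight
        return np.concatenate([dz.real, dz.imag])

    result = least_squares(
        residuals,
        np.log(p0.as_array()),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=max_nfev,
    )
    fitted = np.exp(result.x)
    rel_rms = float(np.sqrt(np.mean(result.fun**2)))
    if not result.success and rel_rms > 1e-6:
        raise CircuitFitError(
            f"circuit fit did not converge (status {result.status})",
            best_params=tuple(fitted),
            residual=rel_rms,
        )
    r_sol, r_teer, c_m, c_e = fitted
    if r_teer < 1e-6 * r_sol:
        raise CircuitFitError(
            "epithelial branch unidentifiable: fitted r_teer collapsed "
            "(spectrum indistinguishable from a bare resistor)",
            best_params=tuple(fitted),
            residual=rel_rms,
        )

    # Gauss-Newton covariance on linear parameters via the chain rule
    # d r / d p = (d r / d log p) / p.
    cov = None
    jac = np.asarray(result.jac)
    try:
        jtj = jac.T @ jac
        dof = max(result.fun.size - 4, 1)
        cov_log = np.linalg.inv(jtj) * np.sum(result.fun**2) / dof
        cov = cov_log * np.outer(fitted, fitted)
    except np.linalg.LinAlgError:
        pass
    return CircuitFit(r_sol, r_teer, c_m, c_e, rel_rms, cov)


def bode_modulus_at(spec: ImpedanceSpectrum, f0_hz: float = DEFAULT_BODE_FREQUENCY_HZ) -> float:
    """|Z| at f0 by log-log interpolation (exact on grid points)."""
    s = spec.sorted_ascending()
    if not (s.freq_hz[0] <= f0_hz <= s.freq_hz[-1]):
        raise ValueError(
            f"f0={f0_hz} Hz outside the spectrum range "
            f"[{s.freq_hz[0]}, {s.freq_hz[-1]}] Hz"
        )
    return float(
        np.exp(np.interp(np.log(f0_hz), np.log(s.freq_hz), np.log(s.modulus)))
    )


def teer_timecourse(fits_by_day: dict) -> pd.DataFrame:
    """Order per-day circuit fits and flag the R_teer peak.

    Parameters
    ----------
    fits_by_day:
        Mapping day -> :class:`CircuitFit`. At least 2 time points are
        required for peak detection; a single day yields a table with no
        peak flagged.

    Returns
    -------
    DataFrame with columns ``day, r_teer_ohm, c_membrane_nf, is_peak,
    peak_at_boundary``.
    """
    if not fits_by_day:
        raise ValueError("no fits provided")
    days = sorted(fits_by_day)
    table = pd.DataFrame(
        {
            "day": days,
            "r_teer_ohm": [fits_by_day[d].r_teer for d in days],
            "c_membrane_nf": [fits_by_day[d].c_membrane_nf for d in days],
        }
    )
    table["is_peak"] = False
    table["peak_at_boundary"] = False
    if len(days) >= 2:
        k = int(table["r_teer_ohm"].idxmax())
        table.loc[k, "is_peak"] = True
        table.loc[k, "peak_at_boundary"] = k in (0, len(days) - 1)
    return table
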