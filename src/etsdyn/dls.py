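"""Dynamic light scattering: hydrodynamic sizing and log-normal summaries.

Translational diffusion coefficients are converted to hydrodynamic
diameters with the Stokes-Einstein relation

    D_H = k_B T / (3 pi eta D_t)

and intensity-weighted size distributions are summarised by fitting a
log-normal: a Gaussian in ln(D_H) with a free amplitude, parameterised
by the geometric mean mu_g (the distribution median, nm) and the
dimensionless geometric standard deviation sigma_g >= 1.  A conventional
size range is quoted as mu_g divided and multiplied by sigma_g.

The raw autocorrelation inversion performed by instrument firmware is
out of scope; this module starts from intensity-vs-size distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import FittingError, ValidationError

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DLSConfig",
    "SizeDistribution",
    "LogNormalSizeModel",
    "LogNormalFitResults",
    "DistributionShift",
    "stokes_einstein_dh",
    "dh_to_diffusion",
    "fit_lognormal",
    "compare_distributions",
]

BOLTZMANN_J_PER_K = 1.380649e-23  # exact (SI definition)


@dataclass(frozen=True)
class DLSConfig:
    """Solvent conditions for Stokes-Einstein conversion.

    Defaults: 25 degC and the viscosity of water at 25 degC
    (0.8872 mPa s), a standard stand-in for dilute PBS.
    """

    temperature_K: float = 298.15
    viscosity_Pa_s: float = 0.8872e-3

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValidationError("temperature must be positive (kelvin)")
        if self.viscosity_Pa_s <= 0:
            raise ValidationError("viscosity must be positive (Pa s)")


def stokes_einstein_dh(dt_m2_per_s: float, cfg: DLSConfig = DLSConfig()) -> float:
    """Hydrodynamic diameter (nm) of a sphere with diffusion coefficient dt."""
    dt = np.asarray(dt_m2_per_s, dtype=float)
    if np.any(dt <= 0):
        raise ValidationError("diffusion coefficient must be positive")
    d_m = BOLTZMANN_J_PER_K * cfg.temperature_K / (3.0 * np.pi * cfg.viscosity_Pa_s * dt)
    out = d_m * 1e9
    return out if out.ndim else float(out)


def dh_to_diffusion(dh_nm: float, cfg: DLSConfig = DLSConfig()) -> float:
    """Inverse of :func:`stokes_einstein_dh` (nm -> m^2/s)."""
    dh = np.asarray(dh_nm, dtype=float)
    if np.any(dh <= 0):
        raise ValidationError("hydrodynamic diameter must be positive")
    out = BOLTZMANN_J_PER_K * cfg.temperature_K / (3.0 * np.pi * cfg.viscosity_Pa_s * dh * 1e-9)
    return out if out.ndim else float(out)


@dataclass
class SizeDistribution:
    """Intensity-weighted hydrodynamic-diameter distribution."""

    dh_nm: np.ndarray
    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.dh_nm = np.asarray(self.dh_nm, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.dh_nm) != len(self.weights):
            raise ValidationError("dh grid and weights must have equal length")
        if np.any(self.dh_nm <= 0):
            raise ValidationError("diameters must be positive")
        if np.any(np.diff(self.dh_nm) <= 0):
            raise ValidationError("diameter grid must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be non-negative")
        if self.weights.sum() <= 0:
            raise ValidationError("weights must have positive total")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"dh_nm": self.dh_nm, "intensity": self.weights}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "SizeDistribution":
        df = pd.read_csv(path)
        missing = {"dh_nm", "intensity"} - set(df.columns)
        if missing:
            raise ValidationError(f"distribution CSV missing columns: {sorted(missing)}")
        return cls(
            dh_nm=df["dh_nm"].to_numpy(),
            weights=df["intensity"].to_numpy(),
            label=label if label is not None else str(Path(path).stem),
        )


def _lognormal_shape(dh_nm, mu_g: float, sigma_g: float):
    """Unit-amplitude Gaussian in ln(D_H) centred at ln(mu_g)."""
    s = math.log(sigma_g)
    z = (np.log(dh_nm) - math.log(mu_g)) / s
    return np.exp(-0.5 * z * z)


class LogNormalSizeModel:
    """Least-squares log-normal summary of a size distribution.

    Fits ``A * exp(-(ln d - ln mu_g)^2 / (2 ln^2 sigma_g))`` to the
    intensity weights; the amplitude A is a nuisance parameter, so the
    fit is invariant to uniform rescaling of the weights.
    """

    param_names = ("mu_g", "sigma_g", "amplitude")

    def __init__(self, dist: SizeDistribution):
        if int(np.sum(dist.weights > 0)) < 5:
            raise ValidationError(
                "log-normal fit needs at least 5 grid points with positive weight"
            )
        self.dist = dist

    def _start_params(self) -> np.ndarray:
        d, w = self.dist.dh_nm, self.dist.weights
        ln_d = np.log(d)
        mu = float(np.sum(w * ln_d) / w.sum())
        var = float(np.sum(w * (ln_d - mu) ** 2) / w.sum())
        s0 = max(math.sqrt(var), 1e-4)
        return np.array([mu, s0, float(w.max())])

    def fit(self) -> "LogNormalFitResults":
        d, w = self.dist.dh_nm, self.dist.weights

        def resid(p):
            ln_mu, s, amp = p
            z = (np.log(d) - ln_mu) / s
            return amp * np.exp(-0.5 * z * z) - w

        def jac(p):
            ln_mu, s, amp = p
            z = (np.log(d) - ln_mu) / s
            e = np.exp(-0.5 * z * z)
            return np.column_stack([amp * e * z / s, amp * e * z * z / s, e])

        sol = optimize.least_squares(
            resid, self._start_params(), jac=jac,
            bounds=([-np.inf, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if not sol.success:
            raise FittingError(f"log-normal fit failed for {self.dist.label!r}")
        ln_mu, s, amp = sol.x
        if s < 1e-7:
            raise FittingError(
                f"degenerate distribution {self.dist.label!r}: fitted spread "
                "collapses to a single grid point (sigma_g -> 1)"
            )
        rss = float(2.0 * sol.cost)
        df = len(d) - 3
        J = jac(sol.x)
        s2 = rss / df if df > 0 else np.nan
        cov = s2 * np.linalg.pinv(J.T @ J)
        return LogNormalFitResults(
            model=self, mu_g=float(math.exp(ln_mu)), sigma_g=float(math.exp(s)),
            amplitude=float(amp), cov_internal=cov, rss=rss, df_resid=df,
        )


@dataclass
class LogNormalFitResults:
    """Fitted log-normal size summary.

    ``mu_g`` is the geometric mean (= distribution median, nm) and
    ``sigma_g`` the dimensionless geometric SD.  Standard errors come
    from the linearized covariance of the internal (ln mu_g, ln sigma_g)
    parameters via the delta method.
    """

    model: LogNormalSizeModel
    mu_g: float
    sigma_g: float
    amplitude: float
    cov_internal: np.ndarray  # covariance of (ln mu_g, s = ln sigma_g, amplitude)
    rss: float
    df_resid: int

    @property
    def label(self) -> str:
        return self.model.dist.label

    @property
    def se_mu(self) -> float:
        return self.mu_g * float(np.sqrt(max(self.cov_internal[0, 0], 0.0)))

    @property
    def se_sigma(self) -> float:
        return self.sigma_g * float(np.sqrt(max(self.cov_internal[1, 1], 0.0)))

    # log-normal law statistics ----------------------------------------
    @property
    def median(self) -> float:
        return self.mu_g

    @property
    def mode(self) -> float:
        return self.mu_g * math.exp(-math.log(self.sigma_g) ** 2)

    @property
    def mean(self) -> float:
        return self.mu_g * math.exp(0.5 * math.log(self.sigma_g) ** 2)

    @property
    def range_low(self) -> float:
        """Lower end of the conventional size range, mu_g / sigma_g."""
        return self.mu_g / self.sigma_g

    @property
    def range_high(self) -> float:
        """Upper end of the conventional size range, mu_g * sigma_g."""
        return self.mu_g * self.sigma_g

    def predict(self, dh_nm) -> np.ndarray:
        return self.amplitude * _lognormal_shape(
            np.asarray(dh_nm, dtype=float), self.mu_g, self.sigma_g
        )

    def summary(self) -> str:
        return "\n".join([
            "Log-normal hydrodynamic size summary",
            "=" * 44,
            f"distribution: {self.label}",
            f"mu_g (median D_H): {self.mu_g:.3f} nm  (se {self.se_mu:.3f})",
            f"sigma_g:           {self.sigma_g:.3f}     (se {self.se_sigma:.3f})",
            f"range (mu_g -/x sigma_g): {self.range_low:.3f} - {self.range_high:.3f} nm",
            f"mode {self.mode:.3f} nm   mean {self.mean:.3f} nm",
            f"rss {self.rss:.4g}   df {self.df_resid}",
        ])

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mu_g_nm": self.mu_g,
            "sigma_g": self.sigma_g,
            "se_mu_nm": self.se_mu,
            "se_sigma": self.se_sigma,
            "range_low_nm": self.range_low,
            "range_high_nm": self.range_high,
            "mode_nm": self.mode,
            "mean_nm": self.mean,
            "rss": self.rss,
            "df": self.df_resid,
        }


def fit_lognormal(dist: SizeDistribution) -> LogNormalFitResults:
    """Convenience wrapper: ``LogNormalSizeModel(dist).fit()``."""
    return LogNormalSizeModel(dist).fit()


@dataclass
class DistributionShift:
    """Comparison of two log-normal size summaries (b relative to a).

    ``delta_median`` < 0 is a downward size shift; ``sigma_ratio`` < 1
    is a tightening, > 1 a broadening of the distribution.  z-scores use
    SEs propagated from both fits (the sigma comparison is done on the
    log scale, where the ratio is a difference).
    """

    label_a: str
    label_b: str
    delta_median_nm: float
    sigma_ratio: float
    z_median: float
    z_sigma: float

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "delta_median_nm": self.delta_median_nm,
            "sigma_ratio": self.sigma_ratio,
            "z_median": self.z_median,
            "z_sigma": self.z_sigma,
        }


def compare_distributions(a: LogNormalFitResults, b: LogNormalFitResults) -> DistributionShift:
    """Shift report: change in median D_H and spread from fit a to fit b."""
    delta = b.mu_g - a.mu_g
    ratio = b.sigma_g / a.sigma_g
    se_delta = math.hypot(a.se_mu, b.se_mu)
    z_med = delta / se_delta if se_delta > 0 else (0.0 if delta == 0 else math.inf)
    se_log = math.hypot(a.se_sigma / a.sigma_g, b.se_sigma / b.sigma_g)
    log_ratio = math.log(ratio)
    z_sig = log_ratio / se_log if se_log > 0 else (0.0 if log_ratio == 0 else math.inf)
    return DistributionShift(
        label_a=a.label, label_b=b.label,
        delta_median_nm=float(delta), sigma_ratio=float(ratio),
        z_median=float(z_med), z_sigma=float(z_sig),
    )
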