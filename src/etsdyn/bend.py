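"""Point-kink reptation model of protein-bent DNA electrophoretic mobility.

Within reptation theory, the mobility of a duplex migrating through a
gel scales with the square of its normalized end-to-end distance.  For a
fragment of unit contour length carrying a rigid point kink of angle
``theta`` (deflection from linearity) at fractional position ``x``, the
squared end-to-end distance is ``1 - 2 x (1 - x) (1 - cos theta)``, so
the relative mobility of the protein-bound fragment is modelled as

    Rf(x) = K * [1 - 2 x (1 - x) (1 - cos theta)]

where ``K`` collects every non-bend contribution (effective charge and
frictional coupling of the complex with the gel matrix).  The model is
quadratic in ``x``, minimised at the fragment midpoint ``x = 0.5`` with
value ``K (1 + cos theta) / 2``, and equals ``K`` at both ends
independently of the bend angle — so the fitted intercepts at
``x in {0, 1}`` read out non-bend effects directly, while the curvature
reads out bending.

The main entry points are :class:`BendMobilityModel` (fit one mobility
profile) and :func:`compare_profiles` (nested-model F test asking
whether two profiles share a single ``(K, theta)``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import FittingError, ValidationError

__all__ = [
    "THETA_CONVENTION",
    "MobilityProfile",
    "BendMobilityModel",
    "BendFitResults",
    "ModelComparison",
    "predict_rf",
    "kink_curvature_factor",
    "fit_profile",
    "confidence_band",
    "compare_profiles",
    "k_from_ends",
]

#: Angle convention embedded in every report: theta is the deflection from
#: linearity (180 degrees minus the included angle of the kink).  The scale
#: of theta depends on this convention; K and the fitted curve do not.
THETA_CONVENTION = (
    "theta = deflection from linearity in degrees "
    "(180 - included angle); curvature term uses cos(theta)"
)

_THETA_MAX = 180.0 - 1e-9


def kink_curvature_factor(theta_deg):
    """Curvature term ``1 - cos(theta)`` of the point-kink model.

    The single place where the angle-to-curvature mapping is defined;
    every model evaluation goes through it.
    """
    return 1.0 - np.cos(np.deg2rad(theta_deg))


def predict_rf(x, K: float, theta_deg: float):
    """Relative mobility of a point-kinked fragment.

    Parameters
    ----------
    x : float or array
        Flexure displacement(s) in [0, 1].
    K : float
        Non-bend mobility factor (> 0); the value of Rf at x = 0 and 1.
    theta_deg : float
        Bend angle in degrees, in [0, 180).

    Returns
    -------
    float or ndarray
        ``K * [1 - 2 x (1 - x) (1 - cos theta)]``.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("flexure displacement x must lie in [0, 1]")
    if not K > 0:
        raise ValidationError(f"K must be positive, got {K}")
    if not (0.0 <= theta_deg < 180.0):
        raise ValidationError(f"theta must lie in [0, 180) degrees, got {theta_deg}")
    out = K * (1.0 - 2.0 * x * (1.0 - x) * kink_curvature_factor(theta_deg))
    return out if out.ndim else float(out)


@dataclass
class MobilityProfile:
    """Relative mobilities of one protein/DNA complex across a permutation panel.

    Each point is the mean of replicate relative-mobility measurements
    (bound-band migration divided by unbound-band migration) at one
    flexure displacement, with its standard error.
    """

    x: np.ndarray
    rf_mean: np.ndarray
    rf_se: np.ndarray
    n_rep: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rf_mean = np.asarray(self.rf_mean, dtype=float)
        self.rf_se = np.asarray(self.rf_se, dtype=float)
        self.n_rep = np.asarray(self.n_rep, dtype=int)
        n = len(self.x)
        if not (len(self.rf_mean) == len(self.rf_se) == len(self.n_rep) == n):
            raise ValidationError("profile arrays must have equal length")
        if n == 0:
            raise ValidationError("profile must contain at least one point")
        if np.any((self.x < 0) | (self.x > 1)):
            raise ValidationError("x must lie in [0, 1]")
        if np.any((self.rf_mean <= 0) | (self.rf_mean > 1.5)):
            raise ValidationError("rf_mean must lie in (0, 1.5]")
        if np.any(self.rf_se < 0):
            raise ValidationError("rf_se must be non-negative")
        if np.any(self.n_rep < 1):
            raise ValidationError("n_rep must be >= 1")
        order = np.argsort(self.x)
        self.x = self.x[order]
        self.rf_mean = self.rf_mean[order]
        self.rf_se = self.rf_se[order]
        self.n_rep = self.n_rep[order]

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "x": self.x,
                "rf_mean": self.rf_mean,
                "rf_se": self.rf_se,
                "n_rep": self.n_rep,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str | None = None) -> "MobilityProfile":
        required = {"x", "rf_mean", "rf_se", "n_rep"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"mobility table missing columns: {sorted(missing)}")
        if label is None:
            label = str(df["label"].iloc[0]) if "label" in df.columns else ""
        return cls(
            x=df["x"].to_numpy(),
            rf_mean=df["rf_mean"].to_numpy(),
            rf_se=df["rf_se"].to_numpy(),
            n_rep=df["n_rep"].to_numpy(),
            label=label,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, label: str | None = None) -> "MobilityProfile":
        return cls.from_frame(pd.read_csv(path, sep="\t"), label=label)


def _check_identifiability(profile: MobilityProfile) -> None:
    near = np.abs(profile.x - 0.5) < 0.15
    far = np.abs(profile.x - 0.5) > 0.3
    if len(profile) < 4 or not (near.any() and far.any()):
        warnings.warn(
            f"profile {profile.label!r} may not identify (K, theta): need >= 4 "
            "points including both near-centre (|x-0.5| < 0.15) and "
            "near-terminal (|x-0.5| > 0.3) placements; fitting anyway",
            stacklevel=3,
        )


def _start_params(profile: MobilityProfile) -> np.ndarray:
    """Deterministic initialization.

    K0 = mean rf of the two most terminal placements (where Rf ~ K);
    theta0 from inverting the midpoint value K(1+cos theta)/2 at the
    x closest to 0.5, clamped into [0, 179] degrees.
    """
    ext = np.argsort(-np.abs(profile.x - 0.5))[:2]
    K0 = float(np.mean(profile.rf_mean[ext]))
    K0 = max(K0, 1e-6)
    i_mid = int(np.argmin(np.abs(profile.x - 0.5)))
    c = 2.0 * profile.rf_mean[i_mid] / K0 - 1.0
    theta0 = math.degrees(math.acos(min(1.0, max(-1.0, c))))
    return np.array([K0, min(179.0, max(0.0, theta0))])


class BendMobilityModel:
    """Weighted nonlinear least squares for the point-kink mobility model.

    Parameters
    ----------
    profile : MobilityProfile
        Mean relative mobilities with standard errors.  Points are
        weighted by 1/se^2; if any standard error is zero the fit falls
        back to unweighted least squares.

    Examples
    --------
    >>> x = np.linspace(0.05, 0.95, 11)
    >>> prof = MobilityProfile(x, predict_rf(x, 0.95, 50.0),
    ...                        np.zeros_like(x), np.ones_like(x), "demo")
    >>> res = BendMobilityModel(prof).fit()
    >>> round(res.K, 6), round(res.theta_deg, 4)
    (0.95, 50.0)
    """

    param_names = ("K", "theta_deg")

    def __init__(self, profile: MobilityProfile):
        self.profile = profile
        self.weighted = bool(np.all(profile.rf_se > 0))
        self._sigma = profile.rf_se if self.weighted else np.ones_like(profile.rf_se)
        _check_identifiability(profile)

    # weighted residuals and their jacobian ------------------------------
    def _resid(self, params: np.ndarray) -> np.ndarray:
        K, theta = params
        model = K * (1.0 - 2.0 * self.profile.x * (1.0 - self.profile.x)
                     * kink_curvature_factor(theta))
        return (self.profile.rf_mean - model) / self._sigma

    def _jac(self, params: np.ndarray) -> np.ndarray:
        K, theta = params
        g = 2.0 * self.profile.x * (1.0 - self.profile.x)
        # residual = (y - model)/sigma, so each column is -d(model)/d(param)/sigma
        dK = -(1.0 - g * kink_curvature_factor(theta)) / self._sigma
        dtheta = (K * g * np.sin(np.deg2rad(theta)) * np.pi / 180.0) / self._sigma
        return np.column_stack([dK, dtheta])

    def rss(self, params) -> float:
        """Weighted residual sum of squares at arbitrary parameters."""
        return float(np.sum(self._resid(np.asarray(params, float)) ** 2))

    def fit(
        self,
        start_params: np.ndarray | None = None,
        random_restarts: int = 0,
        seed: int | None = None,
    ) -> "BendFitResults":
        """Fit (K, theta) by damped least squares.

        The default is fully deterministic: a single trust-region
        descent from the closed-form initialization.  ``random_restarts``
        adds seeded extra starts and keeps the best optimum.
        """
        if len(self.profile) < 3:
            raise FittingError("need at least 3 points to fit 2 parameters")
        starts = [np.asarray(start_params, float) if start_params is not None
                  else _start_params(self.profile)]
        if random_restarts:
            rng = np.random.default_rng(seed)
            for _ in range(random_restarts):
                starts.append(np.array([
                    starts[0][0] * rng.lognormal(0.0, 0.2),
                    rng.uniform(0.0, 179.0),
                ]))
        best = None
        for p0 in starts:
            sol = optimize.least_squares(
                self._resid, p0, jac=self._jac,
                bounds=([1e-12, 0.0], [np.inf, _THETA_MAX]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FittingError(
                f"bend-model fit failed for profile {self.profile.label!r}: "
                "no least-squares start converged"
            )
        return BendFitResults(self, best.x, float(2.0 * best.cost))


@dataclass
class BendFitResults:
    """Fitted point-kink model: estimates, covariance and diagnostics.

    ``rss`` is the (weighted) residual sum of squares; ``df_resid`` is
    ``n_points - 2``.  The covariance is the linearized (Gauss-Newton)
    estimate ``s^2 (J'J)^-1`` with ``s^2 = rss / df_resid``.
    """

    model: BendMobilityModel
    params: np.ndarray
    rss: float

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        J = self.model._jac(self.params)
        JTJ = J.T @ J
        s2 = self.rss / self.df_resid if self.df_resid > 0 else np.nan
        # pinv tolerates the theta-gradient collapse at the theta = 0 boundary
        self.cov_params = s2 * np.linalg.pinv(JTJ)
        self._singular = np.linalg.matrix_rank(JTJ) < 2

    # -- accessors -------------------------------------------------------
    @property
    def K(self) -> float:
        return float(self.params[0])

    @property
    def theta_deg(self) -> float:
        return float(self.params[1])

    @property
    def nobs(self) -> int:
        return len(self.model.profile)

    @property
    def df_resid(self) -> int:
        return self.nobs - 2

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    @property
    def ci95(self) -> np.ndarray:
        return self.conf_int()

    def predict(self, x) -> np.ndarray:
        return predict_rf(x, self.K, self.theta_deg)

    def k_from_ends(self) -> float:
        """Rf at x = 0 (equal to x = 1): the direct non-bend readout.

        Algebraically identical to the fitted K; exposed because the
        terminal placements assess non-bend effects independently of the
        bend angle.
        """
        return float(self.predict(0.0))

    # -- inference -------------------------------------------------------
    def conf_int(self, alpha: float = 0.05, method: str = "delta") -> np.ndarray:
        """Per-parameter confidence limits.

        ``method="delta"`` uses the linearized covariance with a
        t(df_resid) critical value; ``method="profile"`` profiles the
        weighted RSS in each parameter (the F-based joint-support
        construction) and is preferred near the theta = 0 boundary.
        """
        if method == "delta":
            tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
            half = tcrit * self.bse
            return np.column_stack([self.params - half, self.params + half])
        if method == "profile":
            return np.array([
                self._profile_ci(i, alpha) for i in range(2)
            ])
        raise ValidationError(f"unknown conf_int method {method!r}")

    def _profile_ci(self, index: int, alpha: float) -> tuple[float, float]:
        fcrit = stats.f.ppf(1.0 - alpha, 1, self.df_resid)
        target = self.rss * (1.0 + fcrit / self.df_resid)
        lo_bound, hi_bound = (1e-12, np.inf) if index == 0 else (0.0, _THETA_MAX)

        def prss(value: float) -> float:
            other = 1 - index

            def f(v: float) -> float:
                p = np.empty(2)
                p[index] = value
                p[other] = v
                return self.model.rss(p)

            res = optimize.minimize_scalar(
                f,
                bounds=(1e-12, 10.0) if other == 0 else (0.0, _THETA_MAX),
                method="bounded",
            )
            return res.fun

        def brk(a: float, b: float) -> float:
            return optimize.brentq(lambda v: prss(v) - target, a, b, xtol=1e-10)

        est = self.params[index]
        span = max(10.0 * self.bse[index], 1e-3 * max(abs(est), 1.0), 1e-6)
        # walk outward until the profile RSS crosses the F threshold
        lo, hi = est, est
        for _ in range(60):
            lo = max(lo_bound, lo - span)
            if prss(lo) > target or lo == lo_bound:
                break
        for _ in range(60):
            hi = min(hi_bound if np.isfinite(hi_bound) else hi + span, hi + span)
            if prss(hi) > target or hi == hi_bound:
                break
        lower = brk(lo, est) if prss(lo) > target else lo
        upper = brk(est, hi) if np.isfinite(hi) and prss(hi) > target else hi
        return (lower, upper)

    def conf_band(self, x_grid, alpha: float = 0.05) -> pd.DataFrame:
        """Pointwise delta-method confidence band around the fitted curve.

        Band half-width at x is ``t(1-alpha/2, df) * sqrt(g' C g)`` with
        ``g`` the parameter gradient of the prediction.  At the fragment
        ends the theta-gradient vanishes, so the band width there is set
        purely by var(K).
        """
        if self._singular or not np.all(np.isfinite(self.cov_params)):
            raise FittingError("confidence band unavailable: singular covariance")
        x = np.asarray(x_grid, dtype=float)
        g = 2.0 * x * (1.0 - x)
        curv = kink_curvature_factor(self.theta_deg)
        grad = np.column_stack([
            1.0 - g * curv,
            -self.K * g * np.sin(np.deg2rad(self.theta_deg)) * np.pi / 180.0,
        ])
        var = np.einsum("ij,jk,ik->i", grad, self.cov_params, grad)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        half = tcrit * np.sqrt(np.clip(var, 0.0, None))
        fit = self.predict(x)
        return pd.DataFrame(
            {"x": x, "rf_fit": fit, "lower": fit - half, "upper": fit + half}
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Point-kink bend mobility model",
            "=" * 46,
            f"profile:   {self.model.profile.label}",
            f"nobs: {self.nobs}   df_resid: {self.df_resid}   "
            f"weighted: {self.model.weighted}",
            f"rss (weighted): {self.rss:.6g}",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'se':>10}{'95% CI':>22}",
        ]
        for name, est, se, (lo, hi) in zip(self.param_names, self.params, self.bse, ci):
            lines.append(f"{name:<10}{est:>12.4f}{se:>10.4f}"
                         f"{f'[{lo:.4f}, {hi:.4f}]':>22}")
        lines.append("-" * 46)
        lines.append(THETA_CONVENTION)
        return "\n".join(lines)

    param_names = BendMobilityModel.param_names

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "label": self.model.profile.label,
            "K": self.K,
            "theta_deg": self.theta_deg,
            "se_K": float(self.bse[0]),
            "se_theta_deg": float(self.bse[1]),
            "ci95_K": [float(ci[0, 0]), float(ci[0, 1])],
            "ci95_theta_deg": [float(ci[1, 0]), float(ci[1, 1])],
            "rss": self.rss,
            "df": self.df_resid,
            "nobs": self.nobs,
            "weighted": self.model.weighted,
            "theta_convention": THETA_CONVENTION,
        }


def fit_profile(profile: MobilityProfile, **fit_kwargs) -> BendFitResults:
    """Convenience wrapper: ``BendMobilityModel(profile).fit(...)``."""
    return BendMobilityModel(profile).fit(**fit_kwargs)


def confidence_band(fit: BendFitResults, x_grid, alpha: float = 0.05) -> pd.DataFrame:
    """Delta-method 95% band for a fitted profile (see ``conf_band``)."""
    return fit.conf_band(x_grid, alpha=alpha)


def k_from_ends(fit: BendFitResults) -> float:
    """Non-bend factor read from the fitted curve at x = 0 / x = 1."""
    return fit.k_from_ends()


@dataclass
class ModelComparison:
    """Nested-model F test: one shared (K, theta) versus two separate pairs.

    The global model (2 parameters, both profiles) is nested in the
    separate model (4 parameters), so under the null that both profiles
    share one ``(K, theta)`` the statistic

        F = [(RSS_global - RSS_separate) / 2] / [RSS_separate / df_sep]

    follows F(2, df_sep) with ``df_sep = n_a + n_b - 4``.
    """

    label_a: str
    label_b: str
    rss_global: float
    rss_separate: float
    df_global: int
    df_separate: int
    f_stat: float
    p_value: float
    alpha: float
    fit_a: BendFitResults
    fit_b: BendFitResults
    params_global: np.ndarray

    @property
    def verdict(self) -> str:
        return "distinguishable" if self.p_value < self.alpha else "indistinguishable"

    def format_p(self, floor: float = 1e-5) -> str:
        """Report style: p below the floor prints as an inequality."""
        return f"<{floor:g}" if self.p_value < floor else f"{self.p_value:.5g}"

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "rss_global": self.rss_global,
            "rss_separate": self.rss_separate,
            "df_global": self.df_global,
            "df_separate": self.df_separate,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "p_printed": self.format_p(),
            "alpha": self.alpha,
            "verdict": self.verdict,
            "K_global": float(self.params_global[0]),
            "theta_deg_global": float(self.params_global[1]),
        }


def _fit_joint(a: MobilityProfile, b: MobilityProfile,
               p0: np.ndarray) -> tuple[np.ndarray, float]:
    ma, mb = BendMobilityModel(a), BendMobilityModel(b)

    def resid(p):
        return np.concatenate([ma._resid(p), mb._resid(p)])

    def jac(p):
        return np.vstack([ma._jac(p), mb._jac(p)])

    sol = optimize.least_squares(
        resid, p0, jac=jac, bounds=([1e-12, 0.0], [np.inf, _THETA_MAX]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FittingError("joint (global) bend-model fit failed to converge")
    return sol.x, float(2.0 * sol.cost)


def compare_profiles(
    a: MobilityProfile, b: MobilityProfile, alpha: float = 0.05
) -> ModelComparison:
    """Can one (K, theta) pair explain both mobility profiles?

    Fits each profile separately and the pooled data globally with
    shared parameters, then performs the F test on residual sums of
    squares.  Profiles need not share an x grid.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both profiles must be non-empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_a = fit_profile(a)
        fit_b = fit_profile(b)
        p0 = 0.5 * (fit_a.params + fit_b.params)
        params_g, rss_g = _fit_joint(a, b, p0)
    rss_sep = fit_a.rss + fit_b.rss
    # guard tiny negative differences from numerical round-off
    rss_g = max(rss_g, rss_sep)
    df_sep = len(a) + len(b) - 4
    df_g = len(a) + len(b) - 2
    if df_sep <= 0:
        raise ValidationError("too few points for the nested-model F test")
    f_stat = ((rss_g - rss_sep) / 2.0) / (rss_sep / df_sep)
    p_value = float(stats.f.sf(f_stat, 2, df_sep))
    return ModelComparison(
        label_a=a.label, label_b=b.label,
        rss_global=rss_g, rss_separate=rss_sep,
        df_global=df_g, df_separate=df_sep,
        f_stat=float(f_stat), p_value=p_value, alpha=alpha,
        fit_a=fit_a, fit_b=fit_b, params_global=params_g,
    )
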