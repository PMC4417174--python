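"""Lane-trace quantitation and replicate statistics for permutation gels.

Densitometry traces of native-gel lanes are reduced to band centroids,
bound/unbound migration ratios (relative mobility, Rf) and, across a
panel of flexure displacements, per-position Welch t tests comparing
high- and low-affinity complexes with Benjamini-Hochberg control of the
false discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DetectionError, ValidationError

__all__ = [
    "LaneTrace",
    "Band",
    "RelativeMobility",
    "locate_bands",
    "relative_mobility",
    "welch_t",
    "adjust_fdr",
    "position_tests",
]


@dataclass
class LaneTrace:
    """One lane's intensity trace along the migration axis.

    ``positions`` is the migration coordinate (arbitrary units, strictly
    increasing, larger = migrated further); ``intensities`` the signal.
    """

    positions: np.ndarray
    intensities: np.ndarray
    label: str = ""
    role: str = ""  # "bound" / "unbound" / free text

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != len(self.intensities):
            raise ValidationError("positions and intensities must have equal length")
        if len(self.positions) < 3:
            raise ValidationError("trace needs at least 3 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")


@dataclass(frozen=True)
class Band:
    """A detected band: intensity-weighted centroid and integrated area."""

    center: float
    area: float
    start_index: int
    stop_index: int


def locate_bands(trace: LaneTrace, threshold_mads: float = 3.0) -> list[Band]:
    """Detect bands as above-noise regions and return their centroids.

    The noise floor is ``median + threshold_mads * MAD`` of the whole
    trace.  Contiguous above-floor regions are split at interior local
    minima, and each sub-region contributes one band whose centre is the
    intensity-weighted centroid of the baseline-subtracted signal.
    """
    y = trace.intensities
    baseline = float(np.median(y))
    mad = float(np.median(np.abs(y - baseline)))
    floor = baseline + threshold_mads * mad
    above = y > floor
    if not above.any() or mad == 0 and np.ptp(y) == 0:
        raise DetectionError(
            f"lane {trace.label!r}: no band above the noise floor "
            f"(median {baseline:.3g} + {threshold_mads} x MAD {mad:.3g})"
        )
    bands: list[Band] = []
    # contiguous runs of above-floor samples
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(np.flatnonzero(above & ~np.roll(above, 1)))
    if above[0]:
        starts = [0] + [s for s in starts if s != 0]
    stops = list(np.flatnonzero(above & ~np.roll(above, -1)))
    if above[-1] and (not stops or stops[-1] != len(y) - 1):
        stops.append(len(y) - 1)
    for s, e in zip(starts, stops):
        # split multi-peak regions at interior local minima
        seg = y[s : e + 1]
        minima = signal.argrelextrema(seg, np.less)[0] if len(seg) > 2 else np.array([])
        cuts = [s] + [s + int(m) for m in minima] + [e + 1]
        for a, b in zip(cuts, cuts[1:]):
            if b - a < 1:
                continue
            w = np.clip(y[a:b] - baseline, 0.0, None)
            tot = float(w.sum())
            if tot <= 0:
                continue
            center = float(np.sum(trace.positions[a:b] * w) / tot)
            area = float(np.trapezoid(w, trace.positions[a:b])) if b - a > 1 else tot
            bands.append(Band(center=center, area=area, start_index=a, stop_index=b - 1))
    if not bands:
        raise DetectionError(f"lane {trace.label!r}: no band above the noise floor")
    return bands


def _primary_band(trace: LaneTrace, threshold_mads: float) -> Band:
    bands = locate_bands(trace, threshold_mads=threshold_mads)
    return max(bands, key=lambda b: b.area)


@dataclass
class RelativeMobility:
    """Replicate relative mobilities (bound / unbound migration) at one x."""

    values: np.ndarray
    x: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if np.any(self.values <= 0):
            raise ValidationError("relative mobility must be positive")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def se(self) -> float:
        if self.n < 2:
            return 0.0
        return float(np.std(self.values, ddof=1) / np.sqrt(self.n))


def relative_mobility(
    bound: LaneTrace, unbound: LaneTrace, threshold_mads: float = 3.0
) -> float:
    """Rf of one replicate: primary-band migration ratio bound/unbound.

    The primary band is the largest-area band in each lane.  Migration
    is measured from the start of the trace (the well), so Rf is
    invariant both to uniform intensity rescaling of either lane and to
    a common shift of the migration axis.
    """
    b = _primary_band(bound, threshold_mads)
    u = _primary_band(unbound, threshold_mads)
    migration_b = b.center - bound.positions[0]
    migration_u = u.center - unbound.positions[0]
    if migration_u <= 0:
        raise ValidationError("unbound band migrated a non-positive distance")
    return migration_b / migration_u


def welch_t(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test from summary statistics.

    Parameters are group means, standard errors *of the mean* and
    replicate counts.  Returns ``(t, df, p)`` with the
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("welch_t needs n >= 2 in each group")
    if se1 < 0 or se2 < 0:
        raise ValidationError("standard errors must be non-negative")
    pooled = se1**2 + se2**2
    if pooled == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        warnings.warn(
            "zero standard errors with unequal means: p reported as 0",
            stacklevel=2,
        )
        return float(np.inf) * np.sign(mean1 - mean2), float(n1 + n2 - 2), 0.0
    t = (mean1 - mean2) / np.sqrt(pooled)
    df = pooled**2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(1.0, p)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def position_tests(
    high: dict[float, RelativeMobility] | list[RelativeMobility],
    low: dict[float, RelativeMobility] | list[RelativeMobility],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position high-vs-low Welch tests with FDR adjustment.

    ``high`` and ``low`` map flexure displacement to replicate
    mobilities (lists are keyed by their ``.x`` attribute).  Returns one
    row per x with means, the Welch statistic, raw and BH-adjusted
    p-values, and a significance flag at adjusted p < ``alpha``.
    """
    def as_map(side, name):
        if isinstance(side, dict):
            return dict(side)
        m = {}
        for rm in side:
            if rm.x is None:
                raise ValidationError(f"{name}: RelativeMobility entries need .x set")
            m[rm.x] = rm
        return m

    hi, lo = as_map(high, "high"), as_map(low, "low")
    missing = sorted(set(hi) ^ set(lo))
    if missing:
        raise ValidationError(
            f"high/low x grids do not match; unmatched x values: {missing}"
        )
    xs = sorted(hi)
    rows = []
    for x in xs:
        h, l = hi[x], lo[x]
        t, df, p = welch_t(h.mean, h.se, h.n, l.mean, l.se, l.n)
        rows.append((x, h.mean, h.se, l.mean, l.se, t, df, p))
    df_out = pd.DataFrame(
        rows,
        columns=["x", "mean_high", "se_high", "mean_low", "se_low",
                 "t_stat", "df", "p_raw"],
    )
    df_out["p_adjusted"] = adjust_fdr(df_out["p_raw"].to_numpy())
    df_out["significant"] = df_out["p_adjusted"] < alpha
    return df_out
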