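"""Quantitation of DMS / DNase I footprints from capillary electropherograms.

A footprinting run yields a fluorescence trace whose peaks correspond to
cleavage at individual bases.  Analysis proceeds by (1) integrating the
baseline-subtracted signal over per-base windows supplied by an index
map, (2) normalising every peak area to a control peak outside the
binding interface (cancelling recovery differences between samples),
(3) summarising protection of the core consensus guanines in the bound
versus unbound sample, and (4) flagging any other base whose normalised
area changes by more than a threshold (default 20%).  DNase I traces are
additionally screened for the hypersensitivity that is diagnostic of a
site-specific ETS/DNA complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "Electropherogram",
    "PeakTable",
    "ProtectionReport",
    "subtract_baseline",
    "integrate_peaks",
    "normalize_to_control",
    "protection",
    "flag_changes",
    "hypersensitivity_check",
    "read_index_map",
    "write_index_map",
]


@dataclass
class Electropherogram:
    """One capillary trace: scan coordinate vs fluorescence signal."""

    scan: np.ndarray
    signal: np.ndarray
    channel: str = ""
    sample: str = "unbound"  # "unbound" or "bound:<protein>"

    def __post_init__(self) -> None:
        self.scan = np.asarray(self.scan, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.scan) != len(self.signal):
            raise ValidationError("scan and signal must have equal length")
        if np.any(np.diff(self.scan) <= 0):
            raise ValidationError("scan coordinate must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"scan": self.scan, "signal": self.signal}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, channel: str = "", sample: str = "unbound"):
        df = pd.read_csv(path)
        missing = {"scan", "signal"} - set(df.columns)
        if missing:
            raise ValidationError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(df["scan"].to_numpy(), df["signal"].to_numpy(), channel, sample)


def subtract_baseline(trace: Electropherogram, window: int = 101) -> Electropherogram:
    """Rolling-minimum baseline removal (slow capillary drift), clipped at 0."""
    if window < 1:
        raise ValidationError("baseline window must be >= 1")
    s = pd.Series(trace.signal)
    base = s.rolling(window, center=True, min_periods=1).min().to_numpy()
    return Electropherogram(
        scan=trace.scan,
        signal=np.clip(trace.signal - base, 0.0, None),
        channel=trace.channel,
        sample=trace.sample,
    )


def read_index_map(path: str | Path) -> pd.DataFrame:
    """Index-map TSV: base_index, window_start, window_end, is_control."""
    df = pd.read_csv(path, sep="\t")
    missing = {"base_index", "window_start", "window_end", "is_control"} - set(df.columns)
    if missing:
        raise ValidationError(f"index map missing columns: {sorted(missing)}")
    return df


def write_index_map(index_map: pd.DataFrame, path: str | Path) -> None:
    index_map.to_csv(path, sep="\t", index=False)


@dataclass
class PeakTable:
    """Per-base integrated (and optionally control-normalised) peak areas."""

    table: pd.DataFrame  # columns: base_index, area, [normalized_area]
    control_index: int | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        if "base_index" not in self.table.columns or "area" not in self.table.columns:
            raise ValidationError("peak table needs base_index and area columns")
        if self.table["base_index"].duplicated().any():
            raise ValidationError("duplicate base indices in peak table")
        if (self.table["area"] < 0).any():
            raise ValidationError("peak areas must be non-negative")

    @property
    def normalized(self) -> bool:
        return "normalized_area" in self.table.columns

    def area(self, base_index: int) -> float:
        sel = self.table.loc[self.table["base_index"] == base_index, "area"]
        if sel.empty:
            raise ValidationError(f"base {base_index} not in peak table")
        return float(sel.iloc[0])

    def normalized_area(self, base_index: int) -> float:
        if not self.normalized:
            raise ValidationError("peak table has not been normalised")
        sel = self.table.loc[self.table["base_index"] == base_index, "normalized_area"]
        if sel.empty:
            raise ValidationError(f"base {base_index} not in peak table")
        return float(sel.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def integrate_peaks(trace: Electropherogram, index_map: pd.DataFrame,
                    baseline_window: int | None = None) -> PeakTable:
    """Trapezoidal peak integration over per-base windows.

    ``index_map`` rows assign each base a closed scan window
    ``[window_start, window_end]``; window interiors must not overlap
    (adjacent windows may share a boundary scan, which preserves
    additivity of trapezoidal areas).  If
    ``baseline_window`` is given, rolling-minimum baseline subtraction
    is applied first.
    """
    required = {"base_index", "window_start", "window_end"}
    if missing := required - set(index_map.columns):
        raise ValidationError(f"index map missing columns: {sorted(missing)}")
    im = index_map.sort_values("window_start").reset_index(drop=True)
    if (im["window_end"] <= im["window_start"]).any():
        raise ValidationError("each window must satisfy window_end > window_start")
    overlaps = im["window_start"].iloc[1:].to_numpy() < im["window_end"].iloc[:-1].to_numpy()
    if overlaps.any():
        bad = im["base_index"].iloc[1:][overlaps].tolist()
        raise ValidationError(f"overlapping windows at base indices {bad}")
    if im["window_start"].min() < trace.scan[0] or im["window_end"].max() > trace.scan[-1]:
        raise ValidationError("index-map windows extend outside the trace")
    if baseline_window is not None:
        trace = subtract_baseline(trace, baseline_window)
    areas = []
    for row in im.itertuples():
        mask = (trace.scan >= row.window_start) & (trace.scan <= row.window_end)
        n_in = int(mask.sum())
        area = float(np.trapezoid(trace.signal[mask], trace.scan[mask])) if n_in > 1 else 0.0
        areas.append((int(row.base_index), area))
    out = pd.DataFrame(areas, columns=["base_index", "area"]).sort_values(
        "base_index").reset_index(drop=True)
    control = None
    if "is_control" in im.columns:
        ctrl_rows = im.loc[im["is_control"].astype(bool), "base_index"]
        if len(ctrl_rows) > 1:
            raise ValidationError("index map marks more than one control peak")
        if len(ctrl_rows) == 1:
            control = int(ctrl_rows.iloc[0])
    return PeakTable(table=out, control_index=control, sample=trace.sample)


def normalize_to_control(table: PeakTable, control_index: int | None = None) -> PeakTable:
    """Divide every area by the control-peak area (control maps to 1)."""
    ctrl = control_index if control_index is not None else table.control_index
    if ctrl is None:
        raise ValidationError("no control peak specified")
    ctrl_area = table.area(ctrl)
    if ctrl_area <= 0:
        raise ValidationError(f"control peak (base {ctrl}) has zero area")
    out = table.table.copy()
    out["normalized_area"] = out["area"] / ctrl_area
    return PeakTable(table=out, control_index=ctrl, sample=table.sample)


@dataclass
class ProtectionReport:
    """Protection of the core consensus guanines in the bound state.

    ``protection_percent`` = 100 * (1 - bound/unbound core signal),
    both control-normalised; negative values indicate hypersensitivity.
    Fractional areas are quoted at the reporting precision (0.1).
    """

    core_indices: tuple[int, ...]
    core_fraction_bound: float
    core_fraction_unbound: float
    protection_percent: float
    delta_flags: list[int]
    precision: float = 0.1

    def _round(self, v: float) -> float:
        return round(v / self.precision) * self.precision

    @property
    def core_fraction_bound_rounded(self) -> float:
        return self._round(self.core_fraction_bound)

    @property
    def core_fraction_unbound_rounded(self) -> float:
        return self._round(self.core_fraction_unbound)

    def to_dict(self) -> dict:
        return {
            "core_indices": list(self.core_indices),
            "core_fraction_bound": self.core_fraction_bound,
            "core_fraction_unbound": self.core_fraction_unbound,
            "core_fraction_bound_rounded": self.core_fraction_bound_rounded,
            "core_fraction_unbound_rounded": self.core_fraction_unbound_rounded,
            "protection_percent": self.protection_percent,
            "delta_flags": self.delta_flags,
            "precision": self.precision,
        }


def protection(bound: PeakTable, unbound: PeakTable,
               core_indices, flag_threshold: float = 0.20) -> ProtectionReport:
    """Core-guanine protection summary with >threshold change flags."""
    if not bound.normalized or not unbound.normalized:
        raise ValidationError("protection requires control-normalised tables")
    core = tuple(int(i) for i in core_indices)
    if not core:
        raise ValidationError("core_indices must be non-empty")
    b_sum = sum(bound.normalized_area(i) for i in core)
    u_sum = sum(unbound.normalized_area(i) for i in core)
    if u_sum <= 0:
        raise ValidationError("unbound core signal is zero; protection undefined")
    pct = 100.0 * (1.0 - b_sum / u_sum)
    flags = flag_changes(bound, unbound, threshold=flag_threshold,
                         exclude=set(core))
    return ProtectionReport(
        core_indices=core,
        core_fraction_bound=b_sum,
        core_fraction_unbound=u_sum,
        protection_percent=round(pct, 1),
        delta_flags=flags,
    )


def flag_changes(bound: PeakTable, unbound: PeakTable,
                 threshold: float = 0.20, exclude: set[int] | None = None) -> list[int]:
    """Bases whose normalised area changes by more than ``threshold``.

    Relative change is |bound - unbound| / unbound (the unbound state is
    the reference condition).  The control peak is always excluded; a
    base with zero unbound but nonzero bound signal is flagged (infinite
    change).
    """
    if not bound.normalized or not unbound.normalized:
        raise ValidationError("flag_changes requires control-normalised tables")
    b_idx = set(bound.table["base_index"])
    u_idx = set(unbound.table["base_index"])
    if b_idx != u_idx:
        raise ValidationError(
            f"bound/unbound tables index different bases: {sorted(b_idx ^ u_idx)}"
        )
    skip = set(exclude or ())
    if bound.control_index is not None:
        skip.add(bound.control_index)
    if unbound.control_index is not None:
        skip.add(unbound.control_index)
    flags = []
    for i in sorted(b_idx):
        if i in skip:
            continue
        u = unbound.normalized_area(i)
        b = bound.normalized_area(i)
        if u == 0:
            if b > 0:
                flags.append(i)
            continue
        if abs(b - u) / u > threshold:
            flags.append(i)
    return flags


def hypersensitivity_check(bound: PeakTable, unbound: PeakTable,
                           window, factor: float = 2.0) -> bool:
    """Site-specific complex verdict from DNase I hypersensitivity.

    True iff any base in ``window`` shows a bound/unbound normalised
    area ratio strictly greater than ``factor``.
    """
    window = [int(i) for i in window]
    if not window:
        raise ValidationError("hypersensitivity window must be non-empty")
    if not bound.normalized or not unbound.normalized:
        raise ValidationError("hypersensitivity_check requires normalised tables")
    for i in window:
        u = unbound.normalized_area(i)
        b = bound.normalized_area(i)
        if u == 0:
            if b > 0:
                return True
            continue
        if b / u > factor:
            return True
    return False
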