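"""Synthetic data generation for every analysis in the package.

Generators emulate the statistical structure of the experimental inputs:
an 11-fragment, 143-bp circular-permutation panel with a 10-bp ETS site;
quadruplicate relative mobilities following the point-kink model with
Gaussian replicate noise (SE 0.005); gel lane traces with Gaussian
bands; log-normal hydrodynamic size distributions with multiplicative
intensity noise; guanine-ladder electropherograms with core-site
protection and a distal control peak; and multinomial motif count
matrices drawn from a stated PWM.

Every generator is a pure function of its scenario parameters and a
seed.  Three built-in scenarios capture the qualitative contrasts of
interest: ``pu1-like`` (high- and low-affinity complexes differ in both
the bend angle and the non-bend factor, with curves crossing near
x = 0.5), ``ets1-minimal-like`` (identical parameters) and
``ets1-autoinhibited-like`` (identical parameters, larger hydrodynamic
size).  The parameter values are chosen for pattern realism, not as
estimates of any measured quantity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bend import MobilityProfile, predict_rf
from .constructs import BindingSite, PermutedSeries, make_series
from .dls import SizeDistribution, _lognormal_shape
from .exceptions import ValidationError
from .footprint import Electropherogram
from .gel import LaneTrace, RelativeMobility
from .motif import BASES, MotifMatrix

__all__ = [
    "ScenarioSpec",
    "builtin_scenario",
    "BUILTIN_SCENARIOS",
    "consensus_pwm",
    "gen_mobility_replicates",
    "gen_mobility_profiles",
    "gen_gel_lanes",
    "gen_dls",
    "gen_electropherogram",
    "find_core_guanines",
    "gen_motif_counts",
]


@dataclass
class ScenarioSpec:
    """Complete parameterisation of one synthetic study scenario.

    ``bend`` maps complex class ("high"/"low") to (K, theta_deg);
    ``dls`` maps species ("unbound"/"high"/"low") to (mu_g nm, sigma_g).
    ``rf_se`` and ``n_rep`` set the replicate noise model: each
    replicate mobility is the model value plus N(0, (rf_se * sqrt(n_rep))^2)
    so that the SE of the replicate mean is rf_se.
    """

    name: str
    bend: dict[str, tuple[float, float]]
    sites: dict[str, str]
    dls: dict[str, tuple[float, float]]
    binding: dict[str, tuple[float, float]]  # protein -> (kd_sp_M, kd_ns_M)
    seed: int = 0
    rf_se: float = 0.005
    n_rep: int = 4
    fragment_length: int = 143
    site_length: int = 10
    n_fragments: int = 11
    dls_noise_cv: float = 0.05
    core_suppression: float = 0.1
    dnase_enhancement: float = 3.0
    footprint_noise_sd: float = 0.5
    motif_strength: float = 0.85
    motif_strength_b: float = 0.72

    def __post_init__(self) -> None:
        for cls, (K, theta) in self.bend.items():
            if not K > 0 or not (0.0 <= theta < 180.0):
                raise ValidationError(f"bend[{cls!r}]: invalid (K, theta) = {(K, theta)}")
        for sp, (mu, sig) in self.dls.items():
            if not mu > 0 or not sig >= 1.0:
                raise ValidationError(f"dls[{sp!r}]: need mu_g > 0 and sigma_g >= 1")
        if self.rf_se < 0 or self.n_rep < 1:
            raise ValidationError("rf_se must be >= 0 and n_rep >= 1")
        if self.core_suppression < 0:
            raise ValidationError("core_suppression must be >= 0")
        if self.seed is None:
            raise ValidationError("scenario seed is mandatory")

    def series(self) -> PermutedSeries:
        site_seq = self.sites.get("high")
        site = (BindingSite("high", site_seq, "high") if site_seq else None)
        return make_series(self.fragment_length, self.site_length,
                           self.n_fragments, site=site)

    def replace(self, **changes) -> "ScenarioSpec":
        return dataclasses.replace(self, **changes)

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bend"] = {k: list(v) for k, v in self.bend.items()}
        d["dls"] = {k: list(v) for k, v in self.dls.items()}
        d["binding"] = {k: list(v) for k, v in self.binding.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        for key in ("bend", "dls", "binding"):
            d[key] = {k: tuple(v) for k, v in d.get(key, {}).items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _builtin_defs() -> dict[str, dict]:
    # High/low bend parameters for pu1-like solve
    # K_h (1 + cos th_h) ~= K_l (1 + cos th_l) so the curves nearly
    # coincide at x = 0.5 and diverge toward the fragment ends.
    return {
        "pu1-like": dict(
            bend={"high": (0.95, 60.0), "low": (0.88, 52.0)},
            sites={"high": "AGCGGAAGTG", "low": "AAAGGAATGG"},
            dls={"unbound": (4.0, 1.40), "high": (3.8, 1.25), "low": (4.5, 1.55)},
            binding={"a": (1e-10, 1e-5), "b": (1e-10, 1e-7)},
        ),
        "ets1-minimal-like": dict(
            bend={"high": (0.90, 50.0), "low": (0.90, 50.0)},
            sites={"high": "GCCGGAAGTG", "low": "TCCGGAAACC"},
            dls={"unbound": (4.0, 1.20), "high": (3.9, 1.18), "low": (4.2, 1.22)},
            binding={"a": (1e-10, 1e-5), "b": (1e-10, 1e-7)},
        ),
        "ets1-autoinhibited-like": dict(
            bend={"high": (0.93, 45.0), "low": (0.93, 45.0)},
            sites={"high": "GCCGGAAGTG", "low": "TCCGGAAACC"},
            dls={"unbound": (4.6, 1.20), "high": (4.9, 1.30), "low": (5.0, 1.30)},
            binding={"a": (1e-10, 1e-5), "b": (1e-10, 1e-7)},
        ),
    }


BUILTIN_SCENARIOS = tuple(_builtin_defs())


def builtin_scenario(name: str, seed: int = 0) -> ScenarioSpec:
    """One of the shipped scenarios: pu1-like, ets1-minimal-like,
    ets1-autoinhibited-like."""
    defs = _builtin_defs()
    if name not in defs:
        raise ValidationError(
            f"unknown scenario {name!r}; choose from {sorted(defs)}"
        )
    return ScenarioSpec(name=name, seed=seed, **defs[name])


def _rng(spec: ScenarioSpec, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(spec.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# mobility profiles


def gen_mobility_replicates(
    spec: ScenarioSpec,
    series: PermutedSeries | None = None,
    seed: int | None = None,
) -> dict[str, dict[float, RelativeMobility]]:
    """Replicate relative mobilities for the high and low complexes.

    Each replicate is ``predict_rf(x, K, theta) + N(0, rf_se * sqrt(n_rep))``
    so the SE of the replicate mean equals ``rf_se``.
    """
    series = series if series is not None else spec.series()
    rng = _rng(spec, seed)
    sd = spec.rf_se * np.sqrt(spec.n_rep)
    out: dict[str, dict[float, RelativeMobility]] = {}
    for cls in ("high", "low"):
        K, theta = spec.bend[cls]
        reps: dict[float, RelativeMobility] = {}
        for x in series.x:
            mu = predict_rf(x, K, theta)
            vals = mu + (rng.normal(0.0, sd, size=spec.n_rep) if sd > 0
                         else np.zeros(spec.n_rep))
            reps[x] = RelativeMobility(values=vals, x=x, label=f"{spec.name}:{cls}")
        out[cls] = reps
    return out


def _profile_from_replicates(
    reps: dict[float, RelativeMobility], label: str, pool_se: bool = True
) -> MobilityProfile:
    """Summarise replicates into a mean/SE profile.

    With ``pool_se`` (default) the replicate variance is pooled across
    positions before forming the SE: the replicate noise is
    homoscedastic by construction (one gel batch), and per-position SEs
    from a handful of replicates carry so few degrees of freedom that
    weighting by them miscalibrates the downstream F test.
    """
    xs = sorted(reps)
    se = np.array([reps[x].se for x in xs])
    if pool_se and len(xs) > 1:
        se = np.full(len(xs), float(np.sqrt(np.mean(se**2))))
    return MobilityProfile(
        x=np.array(xs),
        rf_mean=np.array([reps[x].mean for x in xs]),
        rf_se=se,
        n_rep=np.array([reps[x].n for x in xs]),
        label=label,
    )


def gen_mobility_profiles(
    spec: ScenarioSpec,
    series: PermutedSeries | None = None,
    seed: int | None = None,
) -> tuple[MobilityProfile, MobilityProfile]:
    """(high, low) mean/SE mobility profiles from seeded replicates."""
    reps = gen_mobility_replicates(spec, series=series, seed=seed)
    return (
        _profile_from_replicates(reps["high"], f"{spec.name}:high"),
        _profile_from_replicates(reps["low"], f"{spec.name}:low"),
    )


# ---------------------------------------------------------------------------
# gel lanes


def gen_gel_lanes(
    profile: MobilityProfile,
    seed: int | None = 0,
    unbound_position: float = 100.0,
    band_sigma: float = 1.5,
    bound_amplitude: float = 80.0,
    unbound_amplitude: float = 100.0,
    noise_sd: float = 0.2,
    n_samples: int = 601,
) -> list[tuple[LaneTrace, LaneTrace]]:
    """One (bound, unbound) lane-trace pair per profile point.

    The unbound band sits at a fixed migration position; the bound band
    at ``rf * unbound_position``.  Bands are Gaussian with additive
    seeded noise.
    """
    rng = np.random.default_rng(seed)
    pos = np.linspace(0.0, 1.2 * unbound_position, n_samples)
    pairs = []
    for x, rf in zip(profile.x, profile.rf_mean):
        b_center = rf * unbound_position
        bound_sig = bound_amplitude * np.exp(-0.5 * ((pos - b_center) / band_sigma) ** 2)
        unb_sig = unbound_amplitude * np.exp(
            -0.5 * ((pos - unbound_position) / band_sigma) ** 2)
        if noise_sd > 0:
            bound_sig = np.clip(bound_sig + rng.normal(0, noise_sd, n_samples), 0, None)
            unb_sig = np.clip(unb_sig + rng.normal(0, noise_sd, n_samples), 0, None)
        pairs.append((
            LaneTrace(pos, bound_sig, label=f"{profile.label} x={x:.3f}", role="bound"),
            LaneTrace(pos, unb_sig, label=f"{profile.label} x={x:.3f}", role="unbound"),
        ))
    return pairs


# ---------------------------------------------------------------------------
# DLS


def gen_dls(
    spec: ScenarioSpec,
    species: str = "unbound",
    seed: int | None = None,
    n_grid: int = 64,
    amplitude: float = 100.0,
    noise_cv: float | None = None,
) -> SizeDistribution:
    """Log-normal intensity distribution on a log-spaced diameter grid.

    Multiplicative noise: each weight is scaled by ``exp(cv * z)`` with
    standard-normal z, giving a coefficient of variation ~ cv.
    """
    if species not in spec.dls:
        raise ValidationError(f"scenario has no DLS species {species!r}")
    mu_g, sigma_g = spec.dls[species]
    cv = spec.dls_noise_cv if noise_cv is None else noise_cv
    rng = _rng(spec, seed)
    half_decades = 4.0 * max(np.log10(sigma_g), 0.02)
    grid = np.logspace(np.log10(mu_g) - half_decades, np.log10(mu_g) + half_decades,
                       n_grid)
    w = amplitude * _lognormal_shape(grid, mu_g, max(sigma_g, 1.0 + 1e-9))
    if cv > 0:
        w = w * np.exp(cv * rng.standard_normal(n_grid))
    return SizeDistribution(dh_nm=grid, weights=w,
                            label=f"{spec.name}:{species}")


# ---------------------------------------------------------------------------
# electropherograms


def find_core_guanines(sequence_window: str) -> list[int]:
    """0-based indices of the two core guanines of the first GGAA/GGAT."""
    seq = sequence_window.upper()
    for core in ("GGAA", "GGAT"):
        k = seq.find(core)
        if k >= 0:
            return [k, k + 1]
    raise ValidationError("sequence window contains no GGAA/GGAT core")


def gen_electropherogram(
    spec: ScenarioSpec,
    sequence_window: str,
    bound: bool,
    mode: str = "dms",
    seed: int | None = None,
    scan_per_base: float = 10.0,
    scan_offset: float = 20.0,
    peak_sigma: float = 2.0,
    base_amplitude: float = 100.0,
) -> tuple[Electropherogram, pd.DataFrame]:
    """Synthetic capillary trace plus its per-base index map.

    DMS mode places one Gaussian peak per guanine of the sense
    (5'-GGAA-3') strand; when ``bound``, the two core-consensus guanine
    amplitudes are multiplied by ``spec.core_suppression``.  DNase mode
    places a peak at every base and, when ``bound``, multiplies the
    amplitudes within the 4-base core window by
    ``spec.dnase_enhancement`` (minor-groove widening hypersensitivity).
    The control peak is the guanine (DMS) or base (DNase) farthest from
    the site, marked ``is_control`` in the index map.
    """
    seq = sequence_window.upper()
    if mode not in ("dms", "dnase"):
        raise ValidationError(f"mode must be 'dms' or 'dnase', got {mode!r}")
    core = find_core_guanines(seq)
    core_window = list(range(core[0], core[0] + 4))
    if mode == "dms":
        peak_bases = [i for i, b in enumerate(seq) if b == "G"]
    else:
        peak_bases = list(range(len(seq)))
    if not peak_bases:
        raise ValidationError("no peak-generating bases in window")
    # control: peak base farthest from the core, at least 5 bases away
    distal = [i for i in peak_bases
              if min(abs(i - c) for c in core_window) >= 5]
    if not distal:
        raise ValidationError("no candidate control peak >= 5 bases from the site")
    control = max(distal, key=lambda i: min(abs(i - c) for c in core_window))
    rng = _rng(spec, seed)
    n_scan = int(scan_offset * 2 + scan_per_base * len(seq))
    scan = np.arange(float(n_scan))
    signal = np.zeros(n_scan)
    rows = []
    for i in peak_bases:
        center = scan_offset + scan_per_base * i
        # deterministic per-base amplitude variation (sequence context)
        amp = base_amplitude * (0.85 + 0.3 * ((i * 37) % 11) / 10.0)
        if i == control:
            amp = base_amplitude * 1.2
        if bound and mode == "dms" and i in core:
            amp *= spec.core_suppression
        if bound and mode == "dnase" and i in core_window:
            amp *= spec.dnase_enhancement
        signal += amp * np.exp(-0.5 * ((scan - center) / peak_sigma) ** 2)
        # windows may share a boundary with an adjacent peak but not overlap
        half = min(3.0 * peak_sigma, scan_per_base / 2.0)
        rows.append((i, center - half, center + half, i == control))
    if spec.footprint_noise_sd > 0:
        signal = np.clip(signal + rng.normal(0, spec.footprint_noise_sd, n_scan),
                         0.0, None)
    index_map = pd.DataFrame(
        rows, columns=["base_index", "window_start", "window_end", "is_control"]
    )
    sample = "bound" if bound else "unbound"
    return (
        Electropherogram(scan=scan, signal=signal, channel=mode, sample=sample),
        index_map,
    )


# ---------------------------------------------------------------------------
# motif counts


def consensus_pwm(sequence: str, strength: float = 0.85,
                  name: str = "") -> MotifMatrix:
    """PWM preferring ``sequence`` with probability ``strength`` per position."""
    seq = sequence.upper()
    if not (0.25 <= strength <= 1.0):
        raise ValidationError("strength must lie in [0.25, 1]")
    probs = np.full((4, len(seq)), (1.0 - strength) / 3.0)
    for j, b in enumerate(seq):
        if b not in BASES:
            raise ValidationError(f"non-ACGT base {b!r} in consensus")
        probs[BASES.index(b), j] = strength
    return MotifMatrix(probs=probs, name=name or f"consensus:{seq}")


def gen_motif_counts(pwm: MotifMatrix, n_sites: int,
                     seed: int | None = 0) -> MotifMatrix:
    """Multinomial site tallies drawn column-wise from a PWM."""
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.column_stack([
        rng.multinomial(n_sites, pwm.probs[:, j]) for j in range(pwm.length)
    ])
    return MotifMatrix.from_counts(counts, source="synthetic",
                                   name=f"{pwm.name}:n={n_sites}")
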