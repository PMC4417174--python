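"""Run-level orchestration: scenario generation, analyses and reports.

Each ``run_*`` function loads its inputs from files, executes the
corresponding analysis, and writes machine-readable reports.  Reports
are deterministic: the JSON payload is a pure function of the inputs
and seed (no timestamps), with provenance (input SHA-256 hashes, seed,
package version) kept in a separate ``metadata`` object.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bend import (THETA_CONVENTION, MobilityProfile, compare_profiles,
                   fit_profile)
from .dls import SizeDistribution, compare_distributions, fit_lognormal
from .exceptions import ValidationError
from .footprint import (Electropherogram, hypersensitivity_check,
                        integrate_peaks, normalize_to_control, protection,
                        read_index_map)
from .gel import RelativeMobility, position_tests
from .motif import (DiscriminationInputs, delta_total_ic, ic_difference,
                    read_motif, total_ic, write_motif)
from .simulate import (ScenarioSpec, builtin_scenario, consensus_pwm,
                       find_core_guanines, gen_dls, gen_electropherogram,
                       gen_mobility_replicates, gen_motif_counts,
                       _profile_from_replicates)

logger = logging.getLogger("etsdyn")

__all__ = [
    "RunConfig",
    "generate_inputs",
    "run_bend",
    "run_dls",
    "run_footprint",
    "run_motif",
    "run_all",
]


@dataclass
class RunConfig:
    """Shared run options: output directory, significance level, seed."""

    out_dir: Path
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        self.out_dir.mkdir(parents=True, exist_ok=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_report(path: Path, results: dict, inputs: list[Path],
                 seed: int | None = None) -> None:
    """Deterministic JSON report with provenance metadata."""
    payload = {
        "metadata": {
            "package": "etsdyn",
            "version": __version__,
            "seed": seed,
            "inputs": {str(p): _sha256(p) for p in sorted(map(Path, inputs))},
        },
        "results": results,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    logger.info("wrote %s", path)


# ---------------------------------------------------------------------------
# scenario generation


def generate_inputs(spec: ScenarioSpec, out_dir: Path) -> dict[str, Path]:
    """Write every input file for a scenario into ``out_dir``.

    Emits the permutation-series definition, per-replicate and
    mean/SE mobility tables, DLS distributions per species, DMS and
    DNase electropherograms (bound/unbound) with index maps, motif
    count matrices for both proteins, the binding-constant table and
    the scenario spec itself.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    series = spec.series()
    paths["series"] = out / "series.tsv"
    series.to_tsv(paths["series"])

    reps = gen_mobility_replicates(spec, series=series)
    rep_rows = [
        (cls, x, i + 1, v)
        for cls, m in reps.items()
        for x, rm in sorted(m.items())
        for i, v in enumerate(rm.values)
    ]
    paths["mobility_replicates"] = out / "mobility_replicates.tsv"
    pd.DataFrame(rep_rows, columns=["affinity", "x", "replicate", "rf"]).to_csv(
        paths["mobility_replicates"], sep="\t", index=False)
    for cls in ("high", "low"):
        prof = _profile_from_replicates(reps[cls], f"{spec.name}:{cls}")
        paths[f"mobility_{cls}"] = out / f"mobility_{cls}.tsv"
        prof.to_tsv(paths[f"mobility_{cls}"])

    for i, species in enumerate(spec.dls):
        dist = gen_dls(spec, species=species, seed=spec.seed + 17 + i)
        p = out / f"dls_{species}.csv"
        dist.to_csv(p)
        paths[f"dls_{species}"] = p

    window = "TACGTTGACT" + spec.sites["high"] + "ACTTAGCTGA"
    for mode in ("dms", "dnase"):
        for bound in (False, True):
            trace, index_map = gen_electropherogram(
                spec, window, bound=bound, mode=mode,
                seed=spec.seed + 101 + (1 if bound else 0),
            )
            tag = f"{mode}_{'bound' if bound else 'unbound'}"
            p = out / f"trace_{tag}.csv"
            trace.to_csv(p)
            paths[f"trace_{tag}"] = p
            if not bound:
                pm = out / f"index_map_{mode}.tsv"
                index_map.to_csv(pm, sep="\t", index=False)
                paths[f"index_map_{mode}"] = pm
    core = find_core_guanines(window)
    (out / "footprint_meta.json").write_text(json.dumps(
        {"sequence_window": window, "core_indices": core,
         "dnase_window": list(range(core[0], core[0] + 4))}, indent=2) + "\n")
    paths["footprint_meta"] = out / "footprint_meta.json"

    pwm_a = consensus_pwm(spec.sites["high"], spec.motif_strength, name="protein_a")
    # protein B tolerates more sequence variation (weaker per-position
    # preference), mirroring a less stringent discriminator
    pwm_b = consensus_pwm(spec.sites["high"], spec.motif_strength_b,
                          name="protein_b")
    for tag, pwm in (("a", pwm_a), ("b", pwm_b)):
        counts = gen_motif_counts(pwm, n_sites=1000, seed=spec.seed + 211 + ord(tag))
        p = out / f"motif_{tag}.tsv"
        write_motif(counts, p, format="counts_tsv")
        paths[f"motif_{tag}"] = p

    paths["binding"] = out / "binding.csv"
    pd.DataFrame(
        [(prot, kd_sp, kd_ns) for prot, (kd_sp, kd_ns) in spec.binding.items()],
        columns=["protein", "kd_specific_M", "kd_nonspecific_M"],
    ).to_csv(paths["binding"], index=False)

    paths["scenario"] = out / "scenario.yaml"
    spec.to_yaml(paths["scenario"])
    logger.info("generated scenario %s inputs in %s", spec.name, out)
    return paths


# ---------------------------------------------------------------------------
# analyses


def _replicates_from_tsv(path: Path) -> dict[str, dict[float, RelativeMobility]]:
    df = pd.read_csv(path, sep="\t")
    missing = {"affinity", "x", "rf"} - set(df.columns)
    if missing:
        raise ValidationError(f"replicate table missing columns: {sorted(missing)}")
    out: dict[str, dict[float, RelativeMobility]] = {}
    for (cls, x), grp in df.groupby(["affinity", "x"]):
        out.setdefault(str(cls), {})[float(x)] = RelativeMobility(
            values=grp["rf"].to_numpy(), x=float(x), label=str(cls))
    return out


def run_bend(high_tsv: Path, low_tsv: Path, config: RunConfig,
             replicates_tsv: Path | None = None) -> dict:
    """Fit both profiles, compare them, and (optionally) run the
    per-position replicate t tests."""
    high = MobilityProfile.from_tsv(high_tsv)
    low = MobilityProfile.from_tsv(low_tsv)
    fit_high = fit_profile(high)
    fit_low = fit_profile(low)
    cmp = compare_profiles(high, low, alpha=config.alpha)
    results = {
        "fit_high": fit_high.to_dict(),
        "fit_low": fit_low.to_dict(),
        "comparison": cmp.to_dict(),
        "theta_convention": THETA_CONVENTION,
    }
    inputs = [high_tsv, low_tsv]
    if replicates_tsv is not None:
        reps = _replicates_from_tsv(replicates_tsv)
        table = position_tests(reps["high"], reps["low"], alpha=config.alpha)
        table.to_csv(config.out_dir / "position_tests.tsv", sep="\t", index=False)
        results["position_tests"] = {
            "n_positions": int(len(table)),
            "n_significant": int(table["significant"].sum()),
            "significant_x": [float(v) for v in table.loc[table["significant"], "x"]],
            "alpha": config.alpha,
        }
        inputs.append(replicates_tsv)
    write_report(config.out_dir / "bend_report.json", results, inputs, config.seed)
    return results


def run_dls(dist_csvs: list[Path], config: RunConfig,
            reference: str | None = "unbound") -> dict:
    """Fit a log-normal to every distribution; report shifts vs the reference."""
    fits = {}
    for p in dist_csvs:
        dist = SizeDistribution.from_csv(p)
        fits[dist.label] = fit_lognormal(dist)
    results = {"fits": {k: f.to_dict() for k, f in fits.items()}}
    ref_key = None
    if reference is not None:
        for k in fits:
            if reference in k:
                ref_key = k
                break
    if ref_key is not None:
        shifts = {
            k: compare_distributions(fits[ref_key], f).to_dict()
            for k, f in fits.items() if k != ref_key
        }
        results["shifts_vs_reference"] = shifts
        results["reference"] = ref_key
    write_report(config.out_dir / "dls_report.json", results, list(dist_csvs),
                 config.seed)
    return results


def run_footprint(bound_csv: Path, unbound_csv: Path, index_map_tsv: Path,
                  core_indices: list[int], config: RunConfig,
                  dnase_bound_csv: Path | None = None,
                  dnase_unbound_csv: Path | None = None,
                  dnase_index_map_tsv: Path | None = None,
                  dnase_window: list[int] | None = None) -> dict:
    """Protection quantitation (DMS) plus optional DNase hypersensitivity."""
    index_map = read_index_map(index_map_tsv)
    bound = normalize_to_control(integrate_peaks(
        Electropherogram.from_csv(bound_csv, sample="bound"), index_map))
    unbound = normalize_to_control(integrate_peaks(
        Electropherogram.from_csv(unbound_csv, sample="unbound"), index_map))
    report = protection(bound, unbound, core_indices)
    results: dict = {"protection": report.to_dict()}
    rows = bound.table.merge(unbound.table, on="base_index",
                             suffixes=("_bound", "_unbound"))
    rows.to_csv(config.out_dir / "peak_tables.tsv", sep="\t", index=False)
    inputs = [bound_csv, unbound_csv, index_map_tsv]
    if dnase_bound_csv is not None and dnase_unbound_csv is not None:
        im = read_index_map(dnase_index_map_tsv or index_map_tsv)
        db = normalize_to_control(integrate_peaks(
            Electropherogram.from_csv(dnase_bound_csv, sample="bound"), im))
        du = normalize_to_control(integrate_peaks(
            Electropherogram.from_csv(dnase_unbound_csv, sample="unbound"), im))
        window = dnase_window if dnase_window else core_indices
        specific = hypersensitivity_check(db, du, window)
        results["dnase"] = {
            "window": [int(i) for i in window],
            "site_specific": bool(specific),
        }
        inputs += [dnase_bound_csv, dnase_unbound_csv]
        if dnase_index_map_tsv:
            inputs.append(dnase_index_map_tsv)
    write_report(config.out_dir / "footprint_report.json", results, inputs,
                 config.seed)
    return results


def run_motif(motif_a_path: Path, motif_b_path: Path, binding_csv: Path,
              config: RunConfig, motif_format: str = "counts_tsv") -> dict:
    """Information content of both motifs and the discrimination bound."""
    ma = read_motif(motif_a_path, format=motif_format)
    mb = read_motif(motif_b_path, format=motif_format)
    ica, icb = total_ic(ma), total_ic(mb)
    binding = pd.read_csv(binding_csv)
    required = {"protein", "kd_specific_M", "kd_nonspecific_M"}
    if missing := required - set(binding.columns):
        raise ValidationError(f"binding CSV missing columns: {sorted(missing)}")
    if len(binding) < 2:
        raise ValidationError("binding CSV needs two proteins")
    a, b = binding.iloc[0], binding.iloc[1]
    disc = delta_total_ic(DiscriminationInputs(
        kd_sp_a=float(a.kd_specific_M), kd_ns_a=float(a.kd_nonspecific_M),
        kd_sp_b=float(b.kd_specific_M), kd_ns_b=float(b.kd_nonspecific_M),
    ))
    results = {
        "ic_a": ica.to_dict(),
        "ic_b": icb.to_dict(),
        "delta_ic_motifs_bits": ic_difference(ma, mb),
        "discrimination": disc.to_dict(),
        "proteins": [str(a.protein), str(b.protein)],
    }
    write_report(config.out_dir / "motif_report.json", results,
                 [motif_a_path, motif_b_path, binding_csv], config.seed)
    return results


def run_all(scenario: str | ScenarioSpec, out_dir: Path, seed: int = 0,
            alpha: float = 0.05) -> dict:
    """Generate a scenario's inputs and run every analysis on them."""
    spec = (scenario if isinstance(scenario, ScenarioSpec)
            else builtin_scenario(scenario, seed=seed))
    out = Path(out_dir)
    paths = generate_inputs(spec, out / "inputs")
    config = RunConfig(out_dir=out / "reports", alpha=alpha, seed=spec.seed)
    meta = json.loads(Path(paths["footprint_meta"]).read_text())
    results = {
        "bend": run_bend(paths["mobility_high"], paths["mobility_low"], config,
                         replicates_tsv=paths["mobility_replicates"]),
        "dls": run_dls([paths[k] for k in paths if k.startswith("dls_")], config),
        "footprint": run_footprint(
            paths["trace_dms_bound"], paths["trace_dms_unbound"],
            paths["index_map_dms"], meta["core_indices"], config,
            dnase_bound_csv=paths["trace_dnase_bound"],
            dnase_unbound_csv=paths["trace_dnase_unbound"],
            dnase_index_map_tsv=paths["index_map_dnase"],
            dnase_window=meta["dnase_window"],
        ),
        "motif": run_motif(paths["motif_a"], paths["motif_b"], paths["binding"],
                           config),
    }
    return results
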