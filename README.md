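# etsdyn

Quantitative analyses of **dynamic heterogeneity in DNA site
discrimination by ETS-family transcription factors**. The ETS domains of
PU.1 and Ets-1 are structurally near-identical when bound to
high-affinity DNA, yet they discriminate among binding sites very
differently. This package implements the solution-biophysics toolkit
used to expose that contrast:

- **Circular-permutation bend analysis.** A panel of equal-length DNA
  fragments carries the same 10-bp binding site at varying internal
  positions (flexure displacement *x* ∈ (0, 1)). Within reptation
  theory, the mobility of the protein-bound fragment relative to the
  unbound one follows the point-kink model

  *R*<sub>f</sub>(*x*) = *K* · [1 − 2*x*(1 − *x*)(1 − cos *θ*)],

  where *θ* is the induced bend angle (deflection from linearity) and
  *K* collects non-bend effects (effective charge and frictional
  coupling with the gel matrix); *R*<sub>f</sub>(0) = *R*<sub>f</sub>(1) = *K*
  independently of *θ*, so terminal placements read out non-bend effects
  directly. Weighted nonlinear least squares estimates (*K*, *θ*) with
  delta-method or profile-likelihood 95% limits, and a nested-model
  *F* test on residual sums of squares asks whether two complexes
  (e.g. high- vs low-affinity) share a single (*K*, *θ*).
- **Gel quantitation and replicate statistics:** band centroiding from
  lane traces, quadruplicate relative mobilities, per-position Welch
  *t* tests with Benjamini–Hochberg FDR control.
- **Dynamic light scattering:** Stokes–Einstein conversion
  *D*<sub>H</sub> = *k*<sub>B</sub>*T*/(3πη*D*<sub>t</sub>) and log-normal
  fits of intensity-weighted size distributions, summarised by the
  geometric mean *μ*<sub>g</sub> (median diameter) and dimensionless
  geometric SD *σ*<sub>g</sub>, with size range *μ*<sub>g</sub> ×/÷ *σ*<sub>g</sub>.
- **Footprint quantitation:** per-base peak integration of capillary
  electropherograms, control-peak normalisation, core-guanine protection
  percentages, >20% change flags and DNase I hypersensitivity verdicts.
- **Motif information content:** positional IC = 2 + Σ *p* log₂ *p*
  bits under an equiprobable background, total IC, logo stack heights,
  and the discrimination-energetics bound
  Δ(total IC)<sub>A−B</sub> = ε<sub>r</sub>[log₂(*K*<sub>sp,A</sub>/*K*<sub>ns,A</sub>) −
  log₂(*K*<sub>sp,B</sub>/*K*<sub>ns,B</sub>)] with ε<sub>r</sub> = ln 2 by default.
- **Synthetic data generators** for every input (mobility replicates,
  lane traces, DLS distributions, electropherograms, motif counts), so
  the full pipeline is testable without instrument data.

The package is aimed at nucleic-acids biophysicists running circular
permutation, DLS or footprinting experiments on protein/DNA complexes,
and at anyone wanting a reproducible reference implementation of these
analyses.

## Worked example

Generate the built-in "pu1-like" scenario (high/low-affinity complexes
differ in both *K* and *θ*, curves nearly coinciding at *x* ≈ 0.5) and
run every analysis:

```bash
etsdyn all --scenario pu1-like --seed 7 --out demo
```

Key numbers from `demo/reports/` (seed 7):

- `bend_report.json`: high-affinity fit *K* = 0.951 (95% CI
  0.946–0.957), *θ* = 61.0°; low-affinity *K* = 0.880, *θ* = 52.0°;
  *F* = 189.2, *p* < 1e−05 → **distinguishable**. The generating values
  were (0.95, 60°) and (0.88, 52°). Position tests flag significant
  high/low mobility differences only away from centred sites
  (*x* = 0.03, 0.13, 0.22, 0.87, 0.97) — the signature of complexes
  differing in non-bend interactions, which vanish in sensitivity near
  *x* = 0.5 where bending dominates.
- `dls_report.json`: unbound *μ*<sub>g</sub> = 4.01 nm, *σ*<sub>g</sub> = 1.40
  (range 2.87–5.59 nm); the high-affinity complex is smaller and
  tighter (3.82 nm, 1.25), the low-affinity complex larger and broader
  (4.52 nm, 1.55) — the coupling of size-distribution shape to site
  identity.
- `footprint_report.json`: core-guanine protection 90.0% relative to
  unbound, no >20% flanking changes, DNase hypersensitivity positive
  (site-specific complex confirmed).
- `motif_report.json`: synthetic motif pair 11.48 vs 7.23 bits total IC
  (difference 4.25 bits), against a discrimination-energetics bound of
  4.605 bits from the binding constants (specific *K*<sub>d</sub>
  10⁻¹⁰ M for both proteins; nonspecific 10⁻⁵ vs 10⁻⁷ M).

The same analyses run on your own files via the `bend`, `dls`,
`footprint` and `motif` subcommands (TSV/CSV inputs; see `--help`), or
from Python:

```python
from etsdyn import MobilityProfile, BendMobilityModel, compare_profiles

profile = MobilityProfile.from_tsv("mobility_high.tsv")
results = BendMobilityModel(profile).fit()
print(results.summary())
```

## Layout

- `src/etsdyn/constructs.py` — permuted fragment series, flexure displacement
- `src/etsdyn/bend.py` — point-kink mobility model, fits, F tests
- `src/etsdyn/gel.py` — band quantitation, Welch/BH statistics
- `src/etsdyn/dls.py` — Stokes–Einstein, log-normal size summaries
- `src/etsdyn/footprint.py` — electropherogram peak quantitation
- `src/etsdyn/motif.py` — information content, discrimination energetics
- `src/etsdyn/simulate.py` — scenario specs and data generators
- `src/etsdyn/pipeline.py`, `cli.py` — orchestration and the `etsdyn` CLI
- `docs/methods.md` — models, assumptions, numerical choices
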