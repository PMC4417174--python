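"""Motif information content and binding-discrimination energetics.

Under an equiprobable-base background, the information content of one
motif position with base probabilities p is

    IC = 2 + sum_b p_b log2 p_b      (bits; 0 log 0 := 0)

ranging from 0 bits (uniform column) to 2 bits (a single absolutely
preferred base).  Total IC is the sum over positions; sequence-logo
stack heights are IC times the base probability.

The total-IC difference between two DNA-binding proteins is bounded by
their specific/nonspecific binding free-energy gap: with equilibrium
association constants K_sp and K_ns,

    Delta(total IC)_{A-B} =
        epsilon_r * [log2(K_sp,A / K_ns,A) - log2(K_sp,B / K_ns,B)]

where epsilon_r <= ln 2 ~ 0.7 is the conversion efficiency of binding
free energy into sequence information under isothermal conditions.
Binding constants are accepted as *dissociation* constants (the form
experimental affinities are quoted in, e.g. 1e-10 M) and inverted
internally, so each log-ratio term is log2(Kd_ns / Kd_sp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

__all__ = [
    "BASES",
    "MotifMatrix",
    "ICProfile",
    "DiscriminationInputs",
    "DiscriminationResult",
    "positional_ic",
    "total_ic",
    "ic_difference",
    "delta_total_ic",
    "read_motif",
    "write_motif",
]

BASES = ("A", "C", "G", "T")
_COL_TOL = 1e-9


@dataclass
class MotifMatrix:
    """A 4 x L base-probability matrix (rows A, C, G, T).

    ``counts`` is kept when the matrix came from observed site tallies;
    ``probs`` always holds column-normalised probabilities.
    """

    probs: np.ndarray
    counts: np.ndarray | None = None
    source: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValidationError("probs must be a 4 x L matrix (rows A, C, G, T)")
        if self.probs.shape[1] < 1:
            raise ValidationError("motif must have at least one position")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        colsums = self.probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _COL_TOL):
            bad = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValidationError(
                f"column {bad + 1} sums to {colsums[bad]:.12f}, not 1"
            )
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != self.probs.shape:
                raise ValidationError("counts must match probs shape")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(cls, counts, pseudocount: float = 0.0,
                    source: str = "", name: str = "") -> "MotifMatrix":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValidationError("counts must be a 4 x L matrix")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        work = counts + pseudocount
        colsums = work.sum(axis=0)
        if np.any(colsums <= 0):
            bad = int(np.argmax(colsums <= 0))
            raise ValidationError(f"column {bad + 1} has zero total count")
        return cls(probs=work / colsums, counts=counts, source=source, name=name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(BASES),
                            columns=range(1, self.length + 1))


def positional_ic(column) -> float:
    """Information content (bits) of one motif column.

    ``IC = 2 + sum p log2 p`` with the 0 log 0 = 0 convention, assuming
    an equiprobable background.
    """
    p = np.asarray(column, dtype=float)
    if p.shape != (4,):
        raise ValidationError("column must be a 4-vector (A, C, G, T)")
    if np.any(p < 0):
        raise ValidationError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > _COL_TOL:
        raise ValidationError(f"column sums to {p.sum():.12f}, not 1")
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


@dataclass
class ICProfile:
    """Per-position and total information content of a motif."""

    positional_ic: np.ndarray  # bits per position
    total_ic: float  # bits
    stack_heights: np.ndarray  # 4 x L, bits: IC[i] * p[b, i]
    name: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "positional_ic_bits": [float(v) for v in self.positional_ic],
            "total_ic_bits": float(self.total_ic),
        }


def total_ic(motif: MotifMatrix, small_sample_correction: bool = False) -> ICProfile:
    """Positional ICs, their sum, and logo stack heights for a motif.

    ``small_sample_correction`` subtracts the first-order
    (Miller-Madow) bias term ``3 / (2 n ln 2)`` per column using the
    motif's counts; it is off by default (the bare equiprobable-
    background formula).
    """
    ics = np.array([positional_ic(motif.probs[:, j]) for j in range(motif.length)])
    if small_sample_correction:
        if motif.counts is None:
            raise ValidationError("small-sample correction requires counts")
        n = motif.counts.sum(axis=0).astype(float)
        ics = np.clip(ics - 3.0 / (2.0 * n * math.log(2.0)), 0.0, 2.0)
    stacks = ics[np.newaxis, :] * motif.probs
    return ICProfile(
        positional_ic=ics,
        total_ic=float(ics.sum()),
        stack_heights=stacks,
        name=motif.name,
    )


def ic_difference(motif_a: MotifMatrix, motif_b: MotifMatrix) -> float:
    """Total-IC difference (bits), motif A minus motif B.

    Motifs must share a length; align or trim explicitly beforehand.
    """
    if motif_a.length != motif_b.length:
        raise ValidationError(
            f"motif lengths differ ({motif_a.length} vs {motif_b.length}); "
            "pad or trim explicitly before comparing"
        )
    return total_ic(motif_a).total_ic - total_ic(motif_b).total_ic


@dataclass(frozen=True)
class DiscriminationInputs:
    """Dissociation constants (molar) for two proteins A and B.

    ``epsilon_r`` is the free-energy-to-information conversion
    efficiency, at most ln 2 (~0.7) under isothermal conditions; ln 2 is
    the default.
    """

    kd_sp_a: float
    kd_ns_a: float
    kd_sp_b: float
    kd_ns_b: float
    epsilon_r: float = math.log(2.0)

    def __post_init__(self) -> None:
        for nm in ("kd_sp_a", "kd_ns_a", "kd_sp_b", "kd_ns_b"):
            if not getattr(self, nm) > 0:
                raise ValidationError(f"{nm} must be positive (molar)")
        if not (0.0 < self.epsilon_r <= 1.0):
            raise ValidationError("epsilon_r must lie in (0, 1]")


@dataclass(frozen=True)
class DiscriminationResult:
    """Discrimination-energetics bound on the total-IC difference.

    ``bits_a`` / ``bits_b`` are the per-protein maximum-information
    terms ``epsilon_r * log2(Kd_ns / Kd_sp)``; ``delta_total_ic`` their
    difference (A minus B), antisymmetric under protein swap.
    """

    delta_total_ic: float
    bits_a: float
    bits_b: float
    epsilon_r: float
    note: str = (
        "binding constants interpreted as dissociation constants; "
        "each term is epsilon_r * log2(Kd_ns / Kd_sp)"
    )

    def to_dict(self) -> dict:
        return {
            "delta_total_ic_bits": self.delta_total_ic,
            "bits_a": self.bits_a,
            "bits_b": self.bits_b,
            "epsilon_r": self.epsilon_r,
            "convention": self.note,
        }


def delta_total_ic(inputs: DiscriminationInputs) -> DiscriminationResult:
    """Information gain difference available from site discrimination.

    Each protein's extractable information is
    ``epsilon_r * log2(K_sp / K_ns)`` in association form, i.e.
    ``epsilon_r * log2(Kd_ns / Kd_sp)`` with the dissociation constants
    accepted here.
    """
    bits_a = inputs.epsilon_r * math.log2(inputs.kd_ns_a / inputs.kd_sp_a)
    bits_b = inputs.epsilon_r * math.log2(inputs.kd_ns_b / inputs.kd_sp_b)
    return DiscriminationResult(
        delta_total_ic=bits_a - bits_b,
        bits_a=bits_a,
        bits_b=bits_b,
        epsilon_r=inputs.epsilon_r,
    )


# ---------------------------------------------------------------------------
# motif file I/O


def read_motif(path: str | Path, format: str = "jaspar",
               pseudocount: float = 0.0) -> MotifMatrix:
    """Read a motif matrix from JASPAR, MEME-minimal or counts-TSV text.

    Counts-based formats are normalised to probabilities (optional
    pseudocount, default 0); probability-based MEME matrices are taken
    as-is (after renormalising away printed rounding).
    """
    path = Path(path)
    if format in ("jaspar", "meme_minimal"):
        from Bio import motifs as bio_motifs

        fmt = "jaspar" if format == "jaspar" else "minimal"
        try:
            with open(path) as fh:
                records = bio_motifs.parse(fh, fmt)
                records = list(records)
        except Exception as exc:  # Bio raises bare ValueError/KeyError
            raise ParseError(f"{path}: cannot parse as {format}: {exc}") from exc
        if not records:
            raise ParseError(f"{path}: no motif records found")
        m = records[0]
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        if np.any(counts.sum(axis=0) <= 0):
            raise ParseError(f"{path}: motif column with zero total count")
        if format == "meme_minimal":
            probs = counts / counts.sum(axis=0)
            return MotifMatrix(probs=probs, counts=None, source=format,
                               name=m.name or path.stem)
        return MotifMatrix.from_counts(counts, pseudocount=pseudocount,
                                       source=format, name=m.name or path.stem)
    if format == "counts_tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: cannot read counts TSV: {exc}") from exc
        if list(df.index) != list(BASES):
            raise ParseError(
                f"{path}: counts TSV rows must be A, C, G, T (got {list(df.index)})"
            )
        return MotifMatrix.from_counts(df.to_numpy(dtype=float),
                                       pseudocount=pseudocount,
                                       source=format, name=path.stem)
    raise ValidationError(f"unknown motif format {format!r}")


def write_motif(motif: MotifMatrix, path: str | Path,
                format: str = "counts_tsv") -> None:
    """Write a motif as counts TSV (counts if present, else probabilities)
    or JASPAR-style bracketed counts."""
    path = Path(path)
    mat = motif.counts if motif.counts is not None else motif.probs
    if format == "counts_tsv":
        pd.DataFrame(np.asarray(mat, dtype=float), index=list(BASES),
                     columns=[str(i + 1) for i in range(motif.length)]
                     ).to_csv(path, sep="\t")
        return
    if format == "jaspar":
        with open(path, "w") as fh:
            fh.write(f">{motif.name or 'motif'}\n")
            for b, row in zip(BASES, np.asarray(mat, dtype=float)):
                vals = " ".join(f"{v:.12g}" for v in row)
                fh.write(f"{b} [ {vals} ]\n")
        return
    raise ValidationError(f"unknown motif format {format!r}")
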