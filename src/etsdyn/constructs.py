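"""Circularly permuted DNA fragment series for bend-angle electrophoresis.

A circular permutation panel is a set of equal-length DNA fragments that
carry the same protein binding site at a different internal position in
each fragment.  Protein-induced bending retards fragments with centred
sites the most, so the position dependence of the bound fragment's
mobility reports on the bend geometry.  The key per-fragment coordinate
is the *flexure displacement* ``x``: the fractional position of the site
centre along the fragment, 0 at one end, 0.5 at the centre, 1 at the
other end.

Coordinates are 1-based and fully closed: base pair ``i`` occupies the
continuous interval ``[i - 1, i]``, so its centre sits at ``i - 0.5``.
With this convention a site centred exactly at the fragment midpoint has
``x = 0.5`` regardless of site length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "BindingSite",
    "PermutedFragment",
    "PermutedSeries",
    "flexure_displacement",
    "site_fraction",
    "make_series",
    "CORE_CONSENSUS",
]

#: Core ETS recognition element, 5'-GGA(A/T)-3'.
CORE_CONSENSUS = ("GGAA", "GGAT")


@dataclass(frozen=True)
class BindingSite:
    """A 10-bp ETS binding site (sense strand).

    Parameters
    ----------
    name : str
        Short label, e.g. ``"PU.1-high"``.
    sequence : str
        10-base DNA string; should contain the ETS core consensus
        GGAA or GGAT (a warning, not an error, is raised otherwise so
        that degenerate test sequences remain usable).
    affinity_class : str
        Either ``"high"`` or ``"low"``.
    """

    name: str
    sequence: str
    affinity_class: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != 10:
            raise ValidationError(
                f"binding site {self.name!r}: sequence must be exactly 10 bases, "
                f"got {len(seq)}"
            )
        if set(seq) - set("ACGT"):
            raise ValidationError(
                f"binding site {self.name!r}: non-ACGT characters in {seq!r}"
            )
        if self.affinity_class not in ("high", "low"):
            raise ValidationError(
                f"affinity_class must be 'high' or 'low', got {self.affinity_class!r}"
            )
        if not any(core in seq for core in CORE_CONSENSUS):
            warnings.warn(
                f"binding site {self.name!r} ({seq}) lacks the ETS core consensus "
                "GGAA/GGAT on the sense strand",
                stacklevel=3,
            )


@dataclass(frozen=True)
class PermutedFragment:
    """One fragment of a circular permutation series.

    ``site_start`` is the 1-based coordinate of the first site base.  It
    may be fractional: :func:`make_series` places sites at exactly even
    spacings, which for some geometries requires half-integer starts
    (physical constructs round to the nearest restriction site; only the
    resulting ``x`` values matter downstream).
    """

    fragment_length: int
    site_start: float
    site_length: int
    label: str

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise ValidationError(f"{self.label!r}: fragment_length must be positive")
        if self.site_length < 0:
            raise ValidationError(f"{self.label!r}: site_length must be >= 0")
        if self.site_start < 1 and self.site_length > 0:
            raise ValidationError(
                f"{self.label!r}: site_start must be >= 1, got {self.site_start}"
            )
        if self.site_length > 0 and (
            self.site_start + self.site_length - 1 > self.fragment_length
        ):
            raise ValidationError(
                f"{self.label!r}: site (start {self.site_start}, length "
                f"{self.site_length}) extends past fragment end "
                f"({self.fragment_length} bp)"
            )

    @property
    def x(self) -> float:
        return flexure_displacement(self)


def flexure_displacement(fragment: PermutedFragment) -> float:
    """Fractional position of the site centre along the fragment.

    Returns ``(site_start + (site_length - 1)/2 - 0.5) / fragment_length``
    under the continuous-coordinate convention (bp *i* occupies
    ``[i-1, i]``).  Always in the open interval (0, 1) for a site that
    lies within the fragment.
    """
    if fragment.site_length <= 0:
        raise ValidationError("flexure displacement undefined for an empty site")
    centre = fragment.site_start + (fragment.site_length - 1) / 2.0 - 0.5
    return centre / fragment.fragment_length


def site_fraction(fragment: PermutedFragment) -> float:
    """Percent of the fragment length occupied by the binding site."""
    if fragment.fragment_length == 0:
        raise ValidationError("fragment_length must be nonzero")
    return 100.0 * fragment.site_length / fragment.fragment_length


@dataclass
class PermutedSeries:
    """An ordered circular-permutation panel sharing one binding site."""

    fragments: list[PermutedFragment]
    site: BindingSite | None = None

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValidationError("series must contain at least one fragment")
        lengths = {f.fragment_length for f in self.fragments}
        if len(lengths) != 1:
            raise ValidationError(
                f"all fragments must share fragment_length; got {sorted(lengths)}"
            )
        labels = [f.label for f in self.fragments]
        if len(set(labels)) != len(labels):
            raise ValidationError("fragment labels must be unique")
        xs = self.x
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValidationError(
                "flexure displacements must be strictly increasing along the series"
            )

    @property
    def x(self) -> list[float]:
        """Flexure displacement of every fragment, in series order."""
        return [flexure_displacement(f) for f in self.fragments]

    @property
    def fragment_length(self) -> int:
        return self.fragments[0].fragment_length

    def __len__(self) -> int:
        return len(self.fragments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [f.label for f in self.fragments],
                "fragment_length": [f.fragment_length for f in self.fragments],
                "site_start": [f.site_start for f in self.fragments],
                "site_length": [f.site_length for f in self.fragments],
                "x": self.x,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the series definition (with computed x) as TSV."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, site: BindingSite | None = None) -> "PermutedSeries":
        df = pd.read_csv(path, sep="\t")
        required = {"label", "fragment_length", "site_start", "site_length"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"series TSV missing columns: {sorted(missing)}")
        fragments = [
            PermutedFragment(
                fragment_length=int(r.fragment_length),
                site_start=float(r.site_start),
                site_length=int(r.site_length),
                label=str(r.label),
            )
            for r in df.itertuples()
        ]
        return cls(fragments=fragments, site=site)


def make_series(
    fragment_length: int,
    site_length: int,
    n_fragments: int,
    site: BindingSite | None = None,
) -> PermutedSeries:
    """Build a permutation panel with evenly spaced site placements.

    The site is slid from flush with one fragment end to flush with the
    other in ``n_fragments`` even steps, so the flexure displacements are
    symmetric about 0.5 (exactly: ``x_i + x_{n+1-i} = 1``) and for odd
    ``n_fragments`` one fragment is maximally centred.
    """
    if n_fragments < 2:
        raise ValidationError("n_fragments must be >= 2")
    if site_length <= 0:
        raise ValidationError("site_length must be positive")
    if site_length > fragment_length:
        raise ValidationError(
            f"site ({site_length} bp) cannot exceed fragment ({fragment_length} bp)"
        )
    span = fragment_length - site_length  # available travel in bp
    width = len(str(n_fragments))
    fragments = [
        PermutedFragment(
            fragment_length=fragment_length,
            site_start=1.0 + span * i / (n_fragments - 1),
            site_length=site_length,
            label=f"frag{str(i + 1).zfill(width)}",
        )
        for i in range(n_fragments)
    ]
    return PermutedSeries(fragments=fragments, site=site)
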