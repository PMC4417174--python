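"""Optional plots (requires matplotlib; install the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .bend import BendFitResults, MobilityProfile
from .dls import LogNormalFitResults, SizeDistribution
from .motif import BASES, MotifMatrix, total_ic


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_bend_fit(fit: BendFitResults, ax=None, n_grid: int = 201):
    """Data with SE bars, fitted curve and 95% confidence band."""
    ax = _ax(ax)
    prof = fit.model.profile
    grid = np.linspace(0.0, 1.0, n_grid)
    band = fit.conf_band(grid)
    ax.fill_between(band["x"], band["lower"], band["upper"], alpha=0.25, lw=0)
    ax.plot(band["x"], band["rf_fit"])
    ax.errorbar(prof.x, prof.rf_mean, yerr=prof.rf_se, fmt="o", ms=4, capsize=2)
    ax.set_xlabel("flexure displacement x")
    ax.set_ylabel("relative mobility $R_f$")
    ax.set_title(f"{prof.label}: K={fit.K:.3f}, theta={fit.theta_deg:.1f} deg")
    return ax


def plot_dls_overlay(dist: SizeDistribution, fit: LogNormalFitResults, ax=None):
    """Intensity distribution (symbols) with its log-normal fit (line)."""
    ax = _ax(ax)
    ax.semilogx(dist.dh_nm, dist.weights, "o", ms=4)
    grid = np.logspace(np.log10(dist.dh_nm[0]), np.log10(dist.dh_nm[-1]), 301)
    ax.semilogx(grid, fit.predict(grid))
    ax.axvline(fit.mu_g, ls="--", lw=0.8)
    ax.set_xlabel("hydrodynamic diameter $D_H$ (nm)")
    ax.set_ylabel("relative intensity")
    ax.set_title(f"{fit.label}: $\\mu_g$={fit.mu_g:.2f} nm, "
                 f"$\\sigma_g$={fit.sigma_g:.2f}")
    return ax


def plot_logo(motif: MotifMatrix, ax=None):
    """Information-content sequence logo drawn as stacked letter bars."""
    ax = _ax(ax)
    prof = total_ic(motif)
    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c"}
    for j in range(motif.length):
        bottom = 0.0
        order = np.argsort(motif.probs[:, j])
        for bi in order:
            h = prof.stack_heights[bi, j]
            if h <= 0:
                continue
            ax.bar(j + 1, h, bottom=bottom, color=colors[BASES[bi]],
                   width=0.85, edgecolor="none")
            if h > 0.12:
                ax.text(j + 1, bottom + h / 2, BASES[bi], ha="center",
                        va="center", fontsize=8, color="white", weight="bold")
            bottom += h
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.set_title(f"{motif.name}: total IC = {prof.total_ic:.2f} bits")
    return ax
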