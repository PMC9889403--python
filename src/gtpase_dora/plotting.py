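"""Matplotlib views of the standard experiment outputs.

Figure-style summaries: normalized dose-response curves, metric vs
activation-level scatter with binned means, and the paired AND/OR and
mG-vs-tG diagonal scatters.  Each function draws on a provided axes (or
creates one) and returns it, so panels compose freely.
"""

from __future__ import annotations

import numpy as np

from .dora import NormalizedCurves, normalize
from .steady_state import DoseResponseCurve


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_dose_response(curve: DoseResponseCurve, normalized: bool = True, ax=None):
    """Receptor and GTPase dose-response curves on a log dose axis."""
    ax = _ax(ax)
    if normalized:
        norm = normalize(curve)
        series = [("R*/R*_max", norm.u), ("mG*/mG*_max", norm.v_mG), ("tG*/tG*_max", norm.v_tG)]
        ax.set_ylabel("normalized activation")
    else:
        series = [("R*", curve.R_star), ("mG*", curve.mG_star), ("tG*", curve.tG_star)]
        ax.set_ylabel("fractional activation")
    for label, y in series:
        ax.semilogx(curve.S_grid, y, label=label)
    ax.set_xlabel("stimulus S")
    ax.legend()
    return ax


def plot_alignment(norm: NormalizedCurves, species: str = "mG", ax=None):
    """Normalized species curve against normalized receptor, with the
    diagonal; the enclosed area is the distance metric."""
    ax = _ax(ax)
    v = norm.v(species)
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect alignment")
    ax.plot(norm.u, v, label=f"{species}*")
    ax.fill_between(norm.u, norm.u, v, alpha=0.25)
    ax.set_xlabel("R*/R*_max")
    ax.set_ylabel(f"{species}*/{species}*_max")
    ax.legend()
    return ax


def plot_metric_vs_activation(results, species: str = "mG", n_bins: int = 10, ax=None):
    """Scatter of the distance metric against the mGTPase activation level,
    with binned means ± sd overlaid."""
    from .sweeps import binned_mean_metric

    ax = _ax(ax)
    act = [r.mG_activation for r in results]
    met = [getattr(r, f"metric_{species}") for r in results]
    ax.scatter(act, met, s=8, alpha=0.4)
    rows, _ = binned_mean_metric(results, n_bins=n_bins, species=species)
    if rows:
        centers, means, sds, _ = map(np.array, zip(*rows))
        ax.errorbar(centers, means, yerr=sds, color="r", ls="--", capsize=2)
    ax.set_xlabel("mG* activation level")
    ax.set_ylabel(f"distance metric ({species}*)")
    return ax


def plot_paired_metrics(x, y, xlabel: str, ylabel: str, ax=None):
    """Diagonal scatter for paired metrics (AND vs OR, or mG vs tG)."""
    ax = _ax(ax)
    x, y = np.asarray(x, float), np.asarray(y, float)
    lim = float(max(x.max(), y.max())) * 1.05
    ax.plot([0, lim], [0, lim], "b-", lw=1)
    ax.scatter(x, y, s=10, alpha=0.5)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax
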