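"""Convenience plots. The report data, not the figures, are the contract."""

from __future__ import annotations

import numpy as np

from .bayes import prior_density_curve

__all__ = ["plot_pass_rate_curves", "plot_prior_density"]


def plot_pass_rate_curves(curves, ax=None):
    """Pass rate versus per-quarter sample size, one line per curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        label = f"{curve.device} ({curve.method}"
        if curve.prior_scheme is not None:
            label += f", alpha={curve.prior_scheme}"
        label += ")"
        ax.plot(curve.sizes, curve.pass_rate, marker="o", label=label)
    ax.set_xlabel("samples per quarter")
    ax.set_ylabel("pass rate")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_prior_density(alphas=(5, 25, 100), grid=None, ax=None):
    """Inverse-gamma prior densities of sigma^2 for alpha = delta values."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(0.05, 3.0, 400) if grid is None else np.asarray(grid)
    for a in alphas:
        ax.plot(grid, prior_density_curve(a, a, grid), label=f"alpha = delta = {a}")
    ax.set_xlabel(r"$\sigma^2$")
    ax.set_ylabel("prior density")
    ax.legend()
    return ax
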