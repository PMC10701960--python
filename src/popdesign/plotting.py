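"""Minimal plotting helpers (scatter matrices and dose-response overlays).

Requires matplotlib (optional dependency, ``popdesign[plot]``).
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_dose_response(dose_responses, reference=None, ax=None, **kw):
    """Overlay one or more dose-response curves, optionally with a reference.

    ``dose_responses`` is a DoseResponse or an iterable of them.
    """
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    if hasattr(dose_responses, "doses"):
        dose_responses = [dose_responses]
    for dr in dose_responses:
        ax.plot(dr.doses, dr.outputs, color=kw.pop("color", "0.5"),
                alpha=kw.pop("alpha", 0.6), lw=1)
    if reference is not None:
        ax.plot(reference.doses, reference.values, "k-", lw=2, label="reference")
        ax.legend()
    ax.set_xlabel("aTc (nM)")
    ax.set_ylabel("Citrine (nM)")
    return ax


def plot_chain_marginals(chain, burn_in_frac: float = 0.5, bins: int = 40):
    """Histogram of each sampled dimension after burn-in removal."""
    plt = _plt()
    post = chain.burn_in(burn_in_frac)
    d = len(chain.names)
    fig, axes = plt.subplots(1, d, figsize=(3 * d, 2.5), squeeze=False)
    for j, name in enumerate(chain.names):
        axes[0, j].hist(post.samples[:, j], bins=bins, color="tab:orange")
        axes[0, j].set_xlabel(name)
    fig.tight_layout()
    return fig


def plot_pairwise(chain, burn_in_frac: float = 0.5, max_points: int = 5000,
                  color_by=None):
    """Scatter matrix of all two-dimensional projections of a chain."""
    plt = _plt()
    post = chain.burn_in(burn_in_frac)
    X = post.samples
    if X.shape[0] > max_points:
        X = X[:: X.shape[0] // max_points]
    d = X.shape[1]
    fig, axes = plt.subplots(d, d, figsize=(2.2 * d, 2.2 * d))
    for i in range(d):
        for j in range(d):
            ax = axes[i, j]
            if i == j:
                ax.hist(X[:, j], bins=30, color="tab:orange")
            else:
                ax.scatter(X[:, j], X[:, i], s=2, alpha=0.4,
                           c=None if color_by is None else color_by[:len(X)])
            if i == d - 1:
                ax.set_xlabel(chain.names[j])
            if j == 0:
                ax.set_ylabel(chain.names[i])
    fig.tight_layout()
    return fig
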