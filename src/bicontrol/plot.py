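"""Plot helpers: mean-normalized degree cdfs and the robustness/entropy
sweep."""

from __future__ import annotations

import numpy as np

from .degree import DegreeSequence, GeometricModel, normalized_ecdf


def plot_normalized_ecdf(degrees: DegreeSequence, model: GeometricModel | None = None, ax=None):
    """Overlay a degree sequence's mean-normalized ecdf on the normalized
    geometric cdf (log-log axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = normalized_ecdf(degrees)
    ax.loglog(pts[:, 0], pts[:, 1], "o", ms=3, label=f"data ({degrees.side})")
    if model is not None:
        ks = np.arange(1, int(20 * model.mu) + 1)
        ax.loglog(ks / model.mu, 1 - (1 - model.p) ** ks, "-", label="geometric cdf")
    ax.set_xlabel("k / <k>")
    ax.set_ylabel("cumulative probability")
    ax.legend()
    return ax


def plot_sweep(df, axes=None):
    """Robustness (left) and output states (right) against <k_in> from a
    ``fig3_sweep`` table."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_r, ax_o = axes
    for rule in ("OR", "AND", "MAJORITY"):
        col = f"R_sim_{rule}"
        if col in df:
            ax_r.plot(df["k_in"], df[col], "o-", label=rule)
        ocol = f"omega_sim_{rule}"
        if ocol in df:
            ax_o.semilogy(df["k_in"], df[ocol], "o-", label=rule)
    if "R_closed" in df:
        ax_r.plot(df["k_in"], df["R_closed"], "k--", label="closed form (OR)")
    if "log2_omega_closed" in df:
        ax_o.semilogy(df["k_in"], 2 ** df["log2_omega_closed"], "k--", label="estimate (OR)")
    ax_r.set_xlabel("<k_in>")
    ax_r.set_ylabel("robustness R")
    ax_o.set_xlabel("<k_in>")
    ax_o.set_ylabel("output states")
    ax_r.legend()
    return axes
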