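"""Plot helpers for acceptable-family diagnostics (matplotlib)."""

from __future__ import annotations

import numpy as np

from .family import AcceptableFamily, SubsetOOS

__all__ = ["plot_loss_intervals"]


def plot_loss_intervals(
    oos: list[SubsetOOS],
    fam: AcceptableFamily,
    level: float = 0.80,
    ax=None,
    jitter: float = 0.15,
    seed: int = 0,
):
    """Percent-increase-in-loss intervals by subset size.

    For every candidate subset, draws the central ``level`` interval and
    mean of the draw-wise percent increase in predictive loss over the
    anchor subset, with the anchor (``S_min``) and smallest acceptable
    subset (``S_small``) marked.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    rng = np.random.default_rng(seed)
    anchor = next(o for o in oos if o.subset == fam.s_min)
    denom = anchor.pred_loss_draws
    a = (1 - level) / 2
    for o in oos:
        d = 100.0 * (o.pred_loss_draws - denom) / denom
        x = len(o.subset) + jitter * rng.uniform(-1, 1)
        lo, hi = np.quantile(d, [a, 1 - a])
        member = o.subset in fam.members
        color = "C0" if member else "0.7"
        ax.plot([x, x], [lo, hi], color=color, lw=1, alpha=0.7)
        ax.plot(x, d.mean(), "o", color=color, ms=3)
    ax.axhline(fam.eta, color="k", lw=0.8, ls=":")
    ax.axvline(len(fam.s_min), color="0.4", ls="--", lw=1, label="S_min")
    ax.axvline(len(fam.s_small), color="0.4", ls="-", lw=1, label="S_small")
    ax.set_xlabel("subset size")
    ax.set_ylabel("% increase in predictive loss vs. anchor")
    ax.legend(loc="upper right", frameon=False)
    return ax
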