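"""Compromise-map plot with bootstrap prediction ellipses."""

from __future__ import annotations

import numpy as np

from .distatis import BootstrapEllipses, DistatisResult


def plot_compromise(result: DistatisResult,
                    ellipses: BootstrapEllipses | None = None,
                    groups=None, path: str | None = None):
    """Scatter the compromise factor scores (axes 1-2); optionally overlay
    95 % bootstrap prediction ellipses and colour by group.  Returns the
    matplotlib axes; writes SVG/PNG when ``path`` is given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    F = result.factor_scores
    fig, ax = plt.subplots(figsize=(5, 5))
    if groups is None:
        groups = ["all"] * F.shape[0]
    levels = sorted(set(groups))
    cmap = plt.get_cmap("tab10")
    for gi, g in enumerate(levels):
        idx = [i for i, x in enumerate(groups) if x == g]
        ax.scatter(F[idx, 0], F[idx, 1], s=40, marker="s",
                   color=cmap(gi % 10), label=str(g))
        if ellipses is not None:
            for i in idx:
                pts = ellipses.ellipse_points(i)
                ax.fill(pts[:, 0], pts[:, 1], color=cmap(gi % 10), alpha=0.15)
    tau = result.explained_variance_ratio
    ax.set_xlabel(f"Axis 1 ({100 * tau[0]:.0f}% variance)")
    if len(tau) > 1:
        ax.set_ylabel(f"Axis 2 ({100 * tau[1]:.0f}% variance)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    if len(levels) > 1:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return ax
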