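"""Quiver-plot views of flow fields, learned templates and vigilance sweeps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_flow", "plot_templates", "plot_vigilance_grid"]


def plot_flow(field, ax=None, color="tab:blue", scale=None, title=None):
    """Quiver plot of a sparse flow field (FlowFrame or Reconstruction).

    Arrow directions follow the field; lengths are proportional to speed.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    u = field.speed * np.cos(field.direction)
    v = field.speed * np.sin(field.direction)
    ax.quiver(field.x, field.y, u, v, color=color, scale=scale, width=0.004)
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    if title:
        ax.set_title(title)
    return ax


def plot_templates(results, max_templates=20, bins=(16, 16), ncols=5):
    """Grid of quiver plots, one per learned template.

    Each panel is the generative reconstruction of a one-hot template
    activation — the flow pattern the template codes for.
    """
    import matplotlib.pyplot as plt

    c = min(results.n_templates, max_templates)
    nrows = int(np.ceil(c / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows),
                             squeeze=False)
    for j in range(nrows * ncols):
        ax = axes[j // ncols][j % ncols]
        if j >= c:
            ax.axis("off")
            continue
        a = np.zeros(results.n_templates)
        a[j] = 1.0
        recon = results.reconstruct(a, bins=bins, sharpen=False)
        plot_flow(recon, ax=ax, title=f"template {j}")
        ax.set_xlabel("")
        ax.set_ylabel("")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    return fig


def plot_vigilance_grid(sweep):
    """Heatmaps of heading MAE and template count over (rho1, rho2)."""
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.6))
    for ax, grid, label in (
        (ax1, sweep["heading_mae"], "heading MAE (deg)"),
        (ax2, sweep["n_templates"], "templates"),
    ):
        im = ax.imshow(grid, origin="lower", aspect="auto")
        ax.set_xticks(range(len(sweep["rho2_values"])),
                      [f"{r:g}" for r in sweep["rho2_values"]])
        ax.set_yticks(range(len(sweep["rho1_values"])),
                      [f"{r:g}" for r in sweep["rho1_values"]])
        ax.set_xlabel("layer-2 vigilance")
        ax.set_ylabel("layer-1 vigilance")
        ax.set_title(label)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    return fig
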