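"""Heatmap rendering for detection grids and power-law surfaces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; callers only write files
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_alpha_surface", "plot_detection_grid"]


def _pivot_heatmap(ax, frame, index, columns, values, cmap, vmin=None,
                   vmax=None):
    piv = frame.pivot_table(index=index, columns=columns, values=values)
    im = ax.imshow(
        piv.to_numpy(), origin="lower", aspect="auto", cmap=cmap,
        vmin=vmin, vmax=vmax,
        extent=(piv.columns.min(), piv.columns.max(),
                piv.index.min(), piv.index.max()),
    )
    return im


def plot_alpha_surface(surface: pd.DataFrame, path, threshold: float = 0.5):
    """Heatmap of the power-law exponent α over (R_sphere, f_sphere).

    The contour at the stick exponent (default 1/2) marks where the sphere
    becomes visible in the high-b decay.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    im = _pivot_heatmap(ax, surface, "fsphere", "rsphere", "alpha", "viridis")
    piv = surface.pivot_table(index="fsphere", columns="rsphere",
                              values="alpha")
    ax.contour(piv.columns, piv.index, piv.to_numpy(), levels=[threshold],
               colors="w", linewidths=1.5)
    fig.colorbar(im, ax=ax, label=r"power-law exponent $\alpha$")
    ax.set_xlabel(r"$R_\mathrm{sphere}$ ($\mu$m)")
    ax.set_ylabel(r"$f_\mathrm{sphere}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_detection_grid(summary: pd.DataFrame, path, snr: float | None = None):
    """Heatmap of the detection fraction over (R_sphere, f_sphere).

    ``summary`` is the cell-level table from ``DetectionGrid.cell_summary``;
    pass ``snr`` to select one noise level when several were swept.
    """
    frame = summary
    if snr is not None:
        frame = frame[np.isclose(frame["snr"], snr)]
    fig, ax = plt.subplots(figsize=(6, 4))
    im = _pivot_heatmap(ax, frame, "fsphere", "rsphere",
                        "detection_fraction", "RdBu_r", vmin=0.0, vmax=1.0)
    fig.colorbar(im, ax=ax, label="detection fraction (p < 0.05)")
    ax.set_xlabel(r"$R_\mathrm{sphere}$ ($\mu$m)")
    ax.set_ylabel(r"$f_\mathrm{sphere}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
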