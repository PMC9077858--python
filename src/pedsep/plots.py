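"""Thin optional plotting layer over the tabular outputs.

Everything here renders artifacts the stats module already computed;
no inference happens in this module.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_ofi_curves(curves: pd.DataFrame, path: str) -> None:
    """Daily mean OFI with 95% CI bands per phenotype."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for ph, g in curves.groupby("phenotype"):
        g = g.sort_values("day")
        ax.plot(g["day"], g["mean_ofi"], label=str(ph))
        ax.fill_between(g["day"], g["lo"], g["hi"], alpha=0.2)
    ax.set_xlabel("day in PICU")
    ax.set_ylabel("mean organ failure index")
    ax.legend(title="phenotype")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mortality_curves(curves: pd.DataFrame, path: str) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for ph, g in curves.groupby("phenotype"):
        g = g.sort_values("day")
        ax.step(g["day"], 100 * g["cum_mortality"], where="post",
                label=str(ph))
    ax.set_xlabel("day")
    ax.set_ylabel("cumulative mortality (%)")
    ax.legend(title="phenotype")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_log_ratio_heatmap(mat: pd.DataFrame, path: str) -> None:
    """Biomarker log-median-ratio heatmap (rows/columns pre-ordered)."""
    fig, ax = plt.subplots(figsize=(4 + 0.3 * mat.shape[1],
                                    1 + 0.3 * len(mat)))
    vmax = float(np.nanmax(np.abs(mat.to_numpy()))) or 1.0
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns)
    ax.set_yticks(range(len(mat)), mat.index)
    fig.colorbar(im, ax=ax, label="log(phenotype median / cohort median)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_interaction_grid(grid: pd.DataFrame, path: str) -> None:
    """Therapy-interaction odds-ratio heatmap; blank cells stay white."""
    fig, ax = plt.subplots(figsize=(1 + 0.45 * grid.shape[1],
                                    1 + 0.45 * len(grid)))
    logs = np.log(grid.to_numpy(dtype=float))
    vmax = float(np.nanmax(np.abs(logs))) or 1.0
    im = ax.imshow(logs, cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90)
    ax.set_yticks(range(len(grid)), grid.index)
    fig.colorbar(im, ax=ax, label="log odds ratio of mortality")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
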