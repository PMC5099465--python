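"""Field and network figures (PNG), mirroring the usual presentation:
oxygen-tension heat maps with a mmHg colour bar, flow-velocity maps, and
box plots of pattern evaluations."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .geometry import Label, TissueGrid, VascularNetwork
from .hemodynamics import FlowSolution


def save_field_png(field: np.ndarray, grid: TissueGrid, path: str | Path,
                   label: str = "oxygen tension (mmHg)", cmap: str = "jet",
                   vmin: float | None = None, vmax: float | None = None) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    extent = (0, grid.shape[1] * grid.spacing, 0, grid.shape[0] * grid.spacing)
    im = ax.imshow(field, origin="lower", extent=extent, cmap=cmap,
                   vmin=vmin, vmax=vmax, interpolation="nearest")
    burned = np.ma.masked_where(grid.labels != Label.BURNED, np.ones(grid.shape))
    ax.imshow(burned, origin="lower", extent=extent, cmap="gray_r",
              vmin=0, vmax=1, alpha=0.9, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_flow_png(network: VascularNetwork, flow: FlowSolution,
                  path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    vel = [flow.segment_velocity[s.id] for s in network.segments if not s.occluded]
    vmax = max(vel) if vel else 1.0
    cmap = plt.get_cmap("jet")
    for s in network.segments:
        a, b = network.nodes[s.node_a], network.nodes[s.node_b]
        if s.occluded:
            ax.plot([a.x, b.x], [a.y, b.y], color="0.85", lw=1.0, ls=":")
        else:
            v = flow.segment_velocity[s.id]
            ax.plot([a.x, b.x], [a.y, b.y], color=cmap(v / vmax),
                    lw=max(1.0, s.diameter / 6))
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, vmax))
    fig.colorbar(sm, ax=ax, label="flow velocity (µm/s)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_boxplot_png(table, value_col: str, group_col: str,
                     path: str | Path, ylabel: str) -> None:
    import pandas as pd  # noqa: F401

    fig, ax = plt.subplots(figsize=(6, 4))
    groups = list(table[group_col])
    ax.errorbar(range(len(groups)), table[value_col],
                yerr=[table[value_col] - table["ischemia_q25"],
                      table["ischemia_q75"] - table[value_col]]
                if "ischemia_q25" in table else None,
                fmt="s", capsize=4)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([str(g) for g in groups])
    ax.set_xlabel(group_col)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
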