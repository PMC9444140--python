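"""Matplotlib helpers for quick inspection of simulation results."""

from __future__ import annotations

import numpy as np


def plot_field(mesh, values, ax=None, title=None, cbar_label=None, cmap="viridis"):
    """Pseudocolour map of an (nr, nz) cell field in the (z, r) plane."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    pm = ax.pcolormesh(mesh.z_faces * 1e6, mesh.r_faces * 1e6,
                       np.asarray(values), cmap=cmap, shading="flat")
    for r in (mesh.geometry.R0, mesh.geometry.r_endo_outer,
              mesh.geometry.r_bl_outer):
        ax.axhline(r * 1e6, color="w", lw=0.6, alpha=0.7)
    ax.set_xlabel("z (μm)")
    ax.set_ylabel("r (μm)")
    if title:
        ax.set_title(title)
    cb = ax.figure.colorbar(pm, ax=ax)
    if cbar_label:
        cb.set_label(cbar_label)
    return ax


def plot_timeseries(result, ax=None):
    """Region-averaged glucose and mean lumen speed against time."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, series in result.region_mean.items():
        ax.plot(result.times, series, label=name)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("glucose (mM)")
    ax.legend(fontsize=8)
    ax2 = ax.twinx()
    ax2.plot(result.times, result.mean_lumen_speed * 1e3, "k--", alpha=0.5)
    ax2.set_ylabel("mean lumen speed (mm/s)")
    return ax
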