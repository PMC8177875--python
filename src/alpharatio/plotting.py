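"""Thin optional plotting layer over analysis reports (requires matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_group_psd", "plot_sensor_topography"]


def plot_group_psd(report, ax=None, fmax: float = 90.0):
    """Overlay the per-group mean signal-average PSD with SEM shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = report.psd_group_mean
    f = df["frequency_hz"].to_numpy()
    keep = (f > 0) & (f <= fmax)
    for col in df.columns:
        if col.endswith("_mean"):
            group = col[: -len("_mean")]
            mean = df[col].to_numpy()
            sem = df[f"{group}_sem"].to_numpy()
            ax.plot(f[keep], mean[keep], label=group)
            ax.fill_between(f[keep], (mean - sem)[keep], (mean + sem)[keep], alpha=0.3)
    ax.set_yscale("log")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (signal$^2$/Hz)")
    ax.legend()
    return ax


def plot_sensor_topography(values, channel_meta, ax=None, cmap: str = "RdBu_r"):
    """Scatter a per-channel statistic on the 2-D sensor layout."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vmax = float(np.max(np.abs(values))) or 1.0
    sc = ax.scatter(
        channel_meta["x"], channel_meta["y"], c=values, cmap=cmap, vmin=-vmax, vmax=vmax, s=80
    )
    ax.set_aspect("equal")
    ax.set_axis_off()
    plt.colorbar(sc, ax=ax)
    return ax
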