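"""Matplotlib renderings of the standard outputs (time courses, polar
histograms, kymograph heat maps)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kymo import Kymograph
from .metrics import MetricSeries, PolarHistogram

__all__ = ["plot_timeseries", "plot_polar", "plot_kymograph"]


def plot_timeseries(series: MetricSeries, path) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    panels = [("speed", "speed (um/min)"),
              ("x_velocity", "x velocity (um/min)"),
              ("directionality", "directionality"),
              ("coordination", "coordination")]
    for ax, (attr, label) in zip(axes.ravel(), panels):
        ax.plot(series.time, getattr(series, attr))
        ax.set_ylabel(label)
        ax.set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_polar(hist: PolarHistogram, path) -> None:
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    width = np.diff(hist.bin_edges)
    ax.bar(hist.bin_centers, hist.frequency, width=width, bottom=0.0,
           edgecolor="k", linewidth=0.5)
    ax.set_title("velocity angle distribution")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_kymograph(kymo: Kymograph, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    vmax = np.nanmax(np.abs(kymo.values)) or 1.0
    extent = (0, kymo.values.shape[1] * kymo.col_width,
              kymo.values.shape[0] * kymo.row_duration, 0)
    im = ax.imshow(kymo.values, aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax, extent=extent)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("time (min)")
    fig.colorbar(im, ax=ax, label=f"{kymo.quantity} (um/min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
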