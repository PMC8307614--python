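"""Scalar and distributional migration metrics on velocity fields.

Two order parameters summarise how a monolayer moves relative to the
horizontal axis (the axis of an applied electric field, when present):

* **directionality** — the mean cosine of the angle theta between each
  velocity vector and the +x axis, ``(1/N) * sum_i cos(theta_i)``.  It runs
  from -1 (all motion leftward, antiparallel to the field) through 0
  (no net horizontal alignment) to +1 (all motion rightward).
* **coordination** — the polarization order parameter from active-matter
  theory, ``|| (1/N) * sum_i v_i / ||v_i|| ||``: the magnitude of the mean
  unit velocity vector.  1 means every vector points the same way
  (perfect coordination), 0 means wholly isotropic motion.

Both are computed over the *valid* vectors of a field only; zero-magnitude
vectors are excluded (both definitions divide by the vector norm), using a
magnitude floor of 1e-9 um/min.  ``N`` is the number of vectors that
survive these filters.

Additional summaries: mean speed, mean x-velocity, a nearest-neighbour
velocity correlation (cosine similarity of each vector with the mean of its
valid 4-connected grid neighbours), pooled polar angle histograms, and
per-frame time series with optional moving-average smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedMetricError
from .fields import VelocityField

__all__ = [
    "MetricSeries", "PolarHistogram",
    "directionality", "coordination", "mean_speed", "mean_x_velocity",
    "neighbor_correlation", "angle_distribution", "metric_timeseries",
    "max_migration_speed", "value_at_time",
]

#: vectors shorter than this (um/min) are treated as zero magnitude and
#: excluded from angle-based metrics
MAGNITUDE_FLOOR = 1e-9


def _valid_vectors(fld: VelocityField, nonzero: bool = True):
    """Return (u, v) in um/min over valid (and optionally nonzero) nodes."""
    u = fld.u_um_min[fld.valid]
    v = fld.v_um_min[fld.valid]
    if nonzero:
        mag = np.hypot(u, v)
        keep = mag > MAGNITUDE_FLOOR
        u, v = u[keep], v[keep]
    return u, v


def directionality(fld: VelocityField) -> float:
    """Mean cosine of the angle to the +x axis over valid nonzero vectors."""
    u, v = _valid_vectors(fld)
    if u.size == 0:
        raise UndefinedMetricError("directionality undefined: no valid nonzero vectors")
    return float(np.mean(u / np.hypot(u, v)))


def coordination(fld: VelocityField) -> float:
    """Polarization order parameter: magnitude of the mean unit vector."""
    u, v = _valid_vectors(fld)
    if u.size == 0:
        raise UndefinedMetricError("coordination undefined: no valid nonzero vectors")
    mag = np.hypot(u, v)
    return float(np.hypot(np.mean(u / mag), np.mean(v / mag)))


def mean_speed(fld: VelocityField) -> float:
    """Mean vector magnitude in um/min over valid vectors (zeros included)."""
    u, v = _valid_vectors(fld, nonzero=False)
    if u.size == 0:
        raise UndefinedMetricError("mean_speed undefined: no valid vectors")
    return float(np.mean(np.hypot(u, v)))


def mean_x_velocity(fld: VelocityField) -> float:
    """Mean signed x-component in um/min (+x is toward the cathode)."""
    u, _ = _valid_vectors(fld, nonzero=False)
    if u.size == 0:
        raise UndefinedMetricError("mean_x_velocity undefined: no valid vectors")
    return float(np.mean(u))


def neighbor_correlation(fld: VelocityField) -> float:
    """Mean cosine similarity of each vector with its neighbourhood mean.

    For every valid node with at least one valid 4-connected grid
    neighbour, the mean vector of those neighbours is formed and the cosine
    of the angle between the node's vector and that mean is taken; the
    metric is the average over contributing nodes.  Nodes whose own vector
    or neighbourhood mean is (numerically) zero are excluded.
    """
    u = np.where(fld.valid, fld.u_um_min, np.nan)
    v = np.where(fld.valid, fld.v_um_min, np.nan)
    ny, nx = u.shape
    # stack the four neighbours with NaN padding
    pad_u = np.full((ny + 2, nx + 2), np.nan)
    pad_v = np.full((ny + 2, nx + 2), np.nan)
    pad_u[1:-1, 1:-1] = u
    pad_v[1:-1, 1:-1] = v
    shifts = [(0, 1), (2, 1), (1, 0), (1, 2)]
    nb_u = np.stack([pad_u[r:r + ny, c:c + nx] for r, c in shifts])
    nb_v = np.stack([pad_v[r:r + ny, c:c + nx] for r, c in shifts])
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", "Mean of empty slice")
        mean_u = np.nanmean(nb_u, axis=0)
        mean_v = np.nanmean(nb_v, axis=0)
    own_mag = np.hypot(u, v)
    nb_mag = np.hypot(mean_u, mean_v)
    ok = (np.isfinite(own_mag) & np.isfinite(nb_mag)
          & (own_mag > MAGNITUDE_FLOOR) & (nb_mag > MAGNITUDE_FLOOR))
    if not ok.any():
        raise UndefinedMetricError("neighbor_correlation undefined: no neighbour pairs")
    cos = (u[ok] * mean_u[ok] + v[ok] * mean_v[ok]) / (own_mag[ok] * nb_mag[ok])
    return float(np.mean(np.clip(cos, -1.0, 1.0)))


@dataclass
class PolarHistogram:
    """Normalized distribution of velocity-vector angles over (-pi, pi]."""

    bin_edges: np.ndarray   # length n_bins + 1, radians
    frequency: np.ndarray   # length n_bins, fractions summing to 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if abs(self.frequency.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if (self.frequency < 0).any():
            raise ValueError("frequencies must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left_rad": self.bin_edges[:-1],
            "bin_right_rad": self.bin_edges[1:],
            "frequency": self.frequency,
        })


def angle_distribution(fields, n_bins: int = 24) -> PolarHistogram:
    """Pooled polar histogram of vector angles relative to the +x axis.

    Angles are ``atan2(v, u)``; bins are ``n_bins`` equal intervals
    covering (-pi, pi] and frequencies are fractions of the pooled vector
    count.  Zero-magnitude and invalid vectors are excluded.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    if isinstance(fields, VelocityField):
        fields = [fields]
    angles = []
    for fld in fields:
        u, v = _valid_vectors(fld)
        if u.size:
            angles.append(np.arctan2(v, u))
    if not angles:
        raise UndefinedMetricError("angle distribution undefined: no valid nonzero vectors")
    pooled = np.concatenate(angles)
    counts, edges = np.histogram(pooled, bins=n_bins, range=(-math.pi, math.pi))
    return PolarHistogram(edges, counts / counts.sum())


@dataclass
class MetricSeries:
    """Per-frame metric summaries; undefined frames are NaN, never 0."""

    time: np.ndarray                 # min
    speed: np.ndarray                # um/min
    x_velocity: np.ndarray           # um/min
    directionality: np.ndarray       # [-1, 1]
    coordination: np.ndarray         # [0, 1]
    neighbor_correlation: np.ndarray  # [-1, 1]
    n_valid: np.ndarray              # count per frame

    def __post_init__(self) -> None:
        lengths = {len(getattr(self, f)) for f in (
            "time", "speed", "x_velocity", "directionality", "coordination",
            "neighbor_correlation", "n_valid")}
        if len(lengths) != 1:
            raise ValueError("all series must share length")

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.time,
            "speed_um_min": self.speed,
            "x_velocity_um_min": self.x_velocity,
            "directionality": self.directionality,
            "coordination": self.coordination,
            "neighbor_correlation": self.neighbor_correlation,
            "n_valid": self.n_valid,
        })


_SCALARS = {
    "speed": mean_speed,
    "x_velocity": mean_x_velocity,
    "directionality": directionality,
    "coordination": coordination,
    "neighbor_correlation": neighbor_correlation,
}


def metric_timeseries(fields, smoothing_window: int = 3) -> MetricSeries:
    """Apply all scalar metrics per frame, with optional smoothing.

    Each metric is evaluated on each field independently; frames on which
    a metric is undefined carry NaN.  With ``smoothing_window`` > 1 a
    centred moving average (NaN-aware) is applied to every metric column.
    Time is ``frame_index * frame_interval`` of each field.
    """
    fields = list(fields)
    if not fields:
        raise ConfigurationError("metric_timeseries needs at least one field")
    cols: dict[str, list[float]] = {k: [] for k in _SCALARS}
    n_valid = []
    for fld in fields:
        for name, fn in _SCALARS.items():
            try:
                cols[name].append(fn(fld))
            except UndefinedMetricError:
                cols[name].append(np.nan)
        n_valid.append(fld.n_valid)
    time = np.array([i * f.frame_interval for i, f in enumerate(fields)])
    data = {k: np.asarray(vals, dtype=float) for k, vals in cols.items()}
    if smoothing_window and smoothing_window > 1:
        for k, vals in data.items():
            data[k] = (pd.Series(vals)
                       .rolling(smoothing_window, center=True, min_periods=1)
                       .mean().to_numpy())
    return MetricSeries(time=time, n_valid=np.asarray(n_valid), **data)


def max_migration_speed(series: MetricSeries) -> float:
    """Maximum over frames of the (smoothed) spatial-mean speed."""
    if np.all(np.isnan(series.speed)):
        raise UndefinedMetricError("no defined speed values in series")
    return float(np.nanmax(series.speed))


def value_at_time(series: MetricSeries, time_min: float,
                  column: str = "directionality") -> float:
    """Metric value at the single frame nearest the requested time."""
    idx = int(np.argmin(np.abs(series.time - time_min)))
    return float(getattr(series, column)[idx])
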