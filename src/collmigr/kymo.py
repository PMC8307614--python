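"""Space-time kymographs, tissue segmentation and edge tracking.

An x-velocity kymograph averages the signed horizontal velocity over the
y-axis and over time bins, giving a (time x space) heat map of motion
along the field axis: rows are ``row_duration`` minutes (default 10 min/row)
and columns are ``col_width`` um of monolayer (default 42 um, a few cell
diameters).

Edge tracking segments the texture-rich tissue from the smooth background
(local standard deviation + Otsu threshold), keeps the largest connected
component, and summarises each boundary as the per-row extreme x position's
median over rows — robust to fingers and streamers.  Displacement is
measured relative to the first frame, so a retracting leading edge yields
a negative displacement series.  The wound-closure rate is the negative
slope of a least-squares line through the inter-tissue gap width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, InputError, UndefinedEdgeError
from .fields import ImageSequence, VelocityField

__all__ = [
    "Kymograph", "EdgeTrace", "WoundClosureResult",
    "xvelocity_kymograph", "segment_tissue", "edge_positions",
    "edge_displacement_series", "wound_closure_rate",
]


@dataclass
class Kymograph:
    """Heat-map of a quantity binned in time (rows) and x (columns)."""

    values: np.ndarray      # (n_time_bins, n_x_bins); NaN = no data
    row_duration: float     # min
    col_width: float        # um
    quantity: str = "x_velocity"

    def __post_init__(self) -> None:
        if self.row_duration <= 0 or self.col_width <= 0:
            raise ConfigurationError("row_duration and col_width must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        nt, nx = self.values.shape
        rows = np.repeat(np.arange(nt), nx)
        cols = np.tile(np.arange(nx), nt)
        return pd.DataFrame({
            "time_bin": rows,
            "x_bin": cols,
            "t_min": rows * self.row_duration,
            "x_um": cols * self.col_width,
            "value": self.values.ravel(),
        })


@dataclass
class EdgeTrace:
    """Leading/trailing tissue-edge positions over time.

    ``displacement`` is the leading-edge displacement relative to frame 0
    (negative = retraction); the trailing-edge displacement is carried
    alongside.  Frames whose edge could not be determined are NaN.
    """

    time: np.ndarray            # min
    leading_x: np.ndarray       # um, rightmost boundary
    trailing_x: np.ndarray      # um, leftmost boundary
    displacement: np.ndarray    # um, leading_x - leading_x[0]
    trailing_displacement: np.ndarray

    def __post_init__(self) -> None:
        n = {len(self.time), len(self.leading_x), len(self.trailing_x),
             len(self.displacement), len(self.trailing_displacement)}
        if len(n) != 1:
            raise ValueError("edge-trace series must share length")
        if np.isfinite(self.displacement[0]) and abs(self.displacement[0]) > 1e-9:
            raise ValueError("displacement must be relative to frame 0")

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.time,
            "leading_x_um": self.leading_x,
            "trailing_x_um": self.trailing_x,
            "leading_displacement_um": self.displacement,
            "trailing_displacement_um": self.trailing_displacement,
        })


def xvelocity_kymograph(fields: list[VelocityField], row_duration: float = 10.0,
                        col_width: float = 42.0) -> Kymograph:
    """Average u (um/min) into time rows and x columns.

    Field ``i`` is assigned time ``i * frame_interval``; all valid vectors
    of the fields falling in a time bin are pooled and averaged per x bin.
    Bins with no valid vectors are NaN.
    """
    fields = list(fields)
    if not fields:
        raise ConfigurationError("xvelocity_kymograph needs at least one field")
    interval = fields[0].frame_interval
    if row_duration < interval:
        raise ConfigurationError(
            f"row_duration ({row_duration} min) shorter than the frame "
            f"interval ({interval} min)")

    total_t = len(fields) * interval
    n_rows = int(np.ceil(total_t / row_duration - 1e-9))
    x_max = max(float(f.x_um[f.valid].max()) for f in fields if f.valid.any())
    n_cols = int(np.floor(x_max / col_width)) + 1

    sums = np.zeros((n_rows, n_cols))
    counts = np.zeros((n_rows, n_cols))
    for i, fld in enumerate(fields):
        row = min(int(i * interval / row_duration), n_rows - 1)
        x = fld.x_um[fld.valid]
        u = fld.u_um_min[fld.valid]
        col = np.minimum((x / col_width).astype(int), n_cols - 1)
        np.add.at(sums[row], col, u)
        np.add.at(counts[row], col, 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return Kymograph(values, row_duration, col_width, "x_velocity")


def _local_std(frame: np.ndarray, window: int) -> np.ndarray:
    mean = ndimage.uniform_filter(frame, window, mode="reflect")
    mean_sq = ndimage.uniform_filter(frame * frame, window, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return np.sqrt(var)


def segment_tissue(frame: np.ndarray, texture_window: int = 13,
                   threshold: str = "otsu",
                   fixed_value: float | None = None) -> np.ndarray:
    """Binary tissue mask from local image texture.

    Phase-contrast tissue is texture-rich while free substrate is smooth,
    so the local standard deviation over ``texture_window`` px is
    thresholded (Otsu by default; pass ``threshold='fixed'`` with
    ``fixed_value`` for synthetic images), the largest connected component
    is kept and holes are filled.

    Degenerate frames are handled without exceptions: a blank frame or a
    frame of spatially uncorrelated noise (no tissue anywhere) yields an
    empty mask with a warning; a frame that is texture throughout yields a
    full mask.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape[0] <= texture_window or frame.shape[1] <= texture_window:
        raise InputError("frame must be larger than texture_window")

    global_sd = frame.std()
    if global_sd == 0:
        warnings.warn("blank frame: returning empty mask", stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)

    sd = _local_std(frame, texture_window)

    if threshold == "fixed":
        if fixed_value is None:
            raise ConfigurationError("fixed threshold requires fixed_value")
        mask = sd > fixed_value
    elif threshold == "otsu":
        # spatially uncorrelated noise loses nearly all variance under a
        # small blur; real texture (correlated) does not
        smooth_ratio = ndimage.gaussian_filter(frame, 2.0).std() / global_sd
        if smooth_ratio < 0.4:
            warnings.warn("frame appears to contain no tissue texture; "
                          "returning empty mask", stacklevel=2)
            return np.zeros(frame.shape, dtype=bool)
        thr = threshold_otsu(sd)
        mask = sd > thr
        hi = sd[mask].mean() if mask.any() else 0.0
        lo = sd[~mask].mean() if (~mask).any() else 0.0
        if lo > 0 and hi / lo < 2.0:
            # no clear texture/background contrast: frame is tissue throughout
            return np.ones(frame.shape, dtype=bool)
    else:
        raise ConfigurationError(f"unknown threshold mode {threshold!r}")

    if not mask.any():
        warnings.warn("segmentation found no tissue", stacklevel=2)
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    # the windowed SD dilates the tissue by ~window/2 at free boundaries;
    # erode by the same amount (image borders treated as tissue)
    k = texture_window // 2
    if k > 0:
        mask = ndimage.binary_erosion(mask, iterations=k, border_value=1)
    return mask


def edge_positions(mask: np.ndarray, side: str = "leading",
                   pixel_size: float = 1.0) -> float:
    """Median-over-rows boundary position of a tissue mask, in um.

    ``leading`` is the rightmost tissue extent per row (the column index
    *after* the last tissue pixel, so a mask filling columns 0..k-1 has
    its leading edge at k px); ``trailing`` is the leftmost tissue pixel.
    Rows without tissue are ignored.
    """
    if side not in ("leading", "trailing"):
        raise ConfigurationError("side must be 'leading' or 'trailing'")
    mask = np.asarray(mask, dtype=bool)
    rows_with = mask.any(axis=1)
    if not rows_with.any():
        raise UndefinedEdgeError("empty mask has no edge")
    ncols = mask.shape[1]
    if side == "leading":
        per_row = ncols - np.argmax(mask[rows_with, ::-1], axis=1)
    else:
        per_row = np.argmax(mask[rows_with], axis=1)
    return float(np.median(per_row)) * pixel_size


def edge_displacement_series(seq: ImageSequence, texture_window: int = 13,
                             threshold: str = "otsu",
                             fixed_value: float | None = None) -> EdgeTrace:
    """Segment every frame and track both tissue edges over time.

    Frames whose segmentation yields no edge become NaN entries rather
    than aborting the trace.
    """
    if seq.n_frames < 2:
        raise InputError("edge tracking needs at least 2 frames")
    lead = np.full(seq.n_frames, np.nan)
    trail = np.full(seq.n_frames, np.nan)
    for t in range(seq.n_frames):
        try:
            mask = segment_tissue(seq[t], texture_window, threshold, fixed_value)
            lead[t] = edge_positions(mask, "leading", seq.pixel_size)
            trail[t] = edge_positions(mask, "trailing", seq.pixel_size)
        except UndefinedEdgeError:
            warnings.warn(f"no edge found in frame {t}", stacklevel=2)
    time = np.arange(seq.n_frames) * seq.frame_interval
    return EdgeTrace(time, lead, trail, lead - lead[0], trail - trail[0])


@dataclass
class WoundClosureResult:
    """Closure-rate estimate for a two-tissue wound geometry."""

    rate_um_min: float              # -slope of the gap width
    closure_time_min: float | None  # first time with gap <= 0, if reached
    gap_um: np.ndarray              # gap width per frame
    time_min: np.ndarray


def wound_closure_rate(left_tissue: EdgeTrace,
                       right_tissue: EdgeTrace) -> WoundClosureResult:
    """Closure rate of the gap between two facing tissues.

    The gap is the right tissue's trailing (left) edge minus the left
    tissue's leading (right) edge; the rate is the negative least-squares
    slope of gap(t).  Both traces must share the same time base and the
    initial gap must be positive.
    """
    if len(left_tissue) != len(right_tissue) or not np.allclose(
            left_tissue.time, right_tissue.time):
        raise InputError("edge traces must share a common time base")
    gap = right_tissue.trailing_x - left_tissue.leading_x
    time = left_tissue.time
    ok = np.isfinite(gap)
    if ok.sum() < 2:
        raise InputError("need at least two finite gap measurements")
    if not (gap[ok][0] > 0):
        raise InputError("initial gap must be positive")
    slope = np.polyfit(time[ok], gap[ok], 1)[0]
    closed = ok & (gap <= 0)
    closure_time = float(time[closed][0]) if closed.any() else None
    return WoundClosureResult(-float(slope), closure_time, gap, time)
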