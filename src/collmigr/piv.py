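"""Particle image velocimetry by windowed FFT cross-correlation.

Successive image pairs are divided into square interrogation windows
(default 32 px with 50% overlap; at a typical calibration of ~1.3 um/px a
32-px window spans ~42 um of monolayer, i.e. a few cell diameters).  Each
window pair is mean-subtracted and cross-correlated via the FFT; the
correlation peak gives the integer displacement and a three-point Gaussian
fit per axis refines it to subpixel precision.  Nodes whose correlation
peak is not sufficiently above the second-highest peak (outside a 3-px
exclusion zone) are marked invalid, as are zero-variance windows.

Sign convention: +u is rightward (+x) motion; +v is *upward* motion in
physical coordinates.  Image arrays are row-major top-down, so the row
component of the correlation lag is negated when stored.

Vector hygiene: :func:`filter_outliers` applies the normalized median test
over the 8-neighbourhood, invalidating (never interpolating) spurious
vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .fields import ImageSequence, VelocityField

__all__ = ["PivParams", "compute_piv", "filter_outliers", "piv_movie"]


@dataclass(frozen=True)
class PivParams:
    """Interrogation and filtering parameters.

    window_size : px, >= 8 (powers of two make the FFT cheap)
    overlap : fraction of window shared by adjacent windows, in [0, 0.75]
    subpixel : 'gaussian3pt' (default; least peak-locking) or 'parabolic'
    outlier_threshold : normalized-median-test cutoff (dimensionless)
    min_signal_to_noise : peak-to-second-peak ratio below which a node is
        marked invalid
    correlation : 'linear' (default) zero-pads the windows and normalizes
        each lag by its overlap area, which is unbiased for ordinary
        non-periodic textures; 'circular' correlates without padding and
        is exact when the texture is periodic within the window
    """

    window_size: int = 32
    overlap: float = 0.5
    subpixel: str = "gaussian3pt"
    outlier_threshold: float = 2.0
    min_signal_to_noise: float = 1.3
    correlation: str = "linear"

    def __post_init__(self) -> None:
        if self.window_size < 8:
            raise ConfigurationError("window_size must be >= 8 px")
        if not 0.0 <= self.overlap <= 0.75:
            raise ConfigurationError("overlap must lie in [0, 0.75]")
        if self.subpixel not in ("gaussian3pt", "parabolic"):
            raise ConfigurationError(f"unknown subpixel estimator {self.subpixel!r}")
        if self.outlier_threshold <= 0:
            raise ConfigurationError("outlier_threshold must be positive")
        if self.min_signal_to_noise < 1:
            raise ConfigurationError("min_signal_to_noise must be >= 1")
        if self.correlation not in ("linear", "circular"):
            raise ConfigurationError(f"unknown correlation mode {self.correlation!r}")

    @property
    def step(self) -> int:
        return max(1, int(round(self.window_size * (1.0 - self.overlap))))


def _subpixel_offset(cm1: float, c0: float, cp1: float, method: str) -> float:
    """Refine a 1-D peak given its value and two neighbours."""
    if method == "gaussian3pt" and cm1 > 0 and c0 > 0 and cp1 > 0:
        denom = 2.0 * np.log(cm1) - 4.0 * np.log(c0) + 2.0 * np.log(cp1)
        if denom != 0:
            return float((np.log(cm1) - np.log(cp1)) / denom)
    # parabolic fit: also the fallback when log-fit is inapplicable
    denom = 2.0 * (cm1 - 2.0 * c0 + cp1)
    if denom != 0:
        return float((cm1 - cp1) / denom)
    return 0.0


def _correlate_pair(wa: np.ndarray, wb: np.ndarray, mode: str = "linear"):
    """FFT cross-correlation of two mean-subtracted windows.

    ``linear`` zero-pads the windows to twice their size (so texture
    adjacent to the window cannot alias into small lags) and normalizes
    each lag by its overlap area, removing the triangular envelope that
    otherwise biases peaks toward zero displacement.  ``circular``
    correlates without padding; for a texture that is periodic within the
    window the plane is then an exactly even autocorrelation about the
    true lag, so the subpixel fit returns the shift exactly.

    Both modes return a centred plane of lags within +/- window/2, with
    zero lag at index (ws//2, ws//2).
    """
    ws = wa.shape[0]
    if mode == "circular":
        fa = np.fft.rfft2(wa)
        fb = np.fft.rfft2(wb)
        corr = np.fft.irfft2(np.conj(fa) * fb, s=wa.shape)
        return np.fft.fftshift(corr)
    size = 2 * ws
    fa = np.fft.rfft2(wa, s=(size, size))
    fb = np.fft.rfft2(wb, s=(size, size))
    corr = np.fft.fftshift(np.fft.irfft2(np.conj(fa) * fb, s=(size, size)))
    lag = np.arange(size) - size // 2
    overlap = np.maximum(ws - np.abs(lag), 1)
    corr = corr / (overlap[:, None] * overlap[None, :])
    lo, hi = size // 2 - ws // 2, size // 2 + ws // 2
    return corr[lo:hi, lo:hi]


def _peak_snr(corr: np.ndarray, peak_idx: tuple[int, int]) -> float:
    """Ratio of primary peak to highest peak outside a 3-px exclusion zone."""
    py, px = peak_idx
    peak = corr[py, px]
    masked = corr.copy()
    y0, y1 = max(0, py - 3), min(corr.shape[0], py + 4)
    x0, x1 = max(0, px - 3), min(corr.shape[1], px + 4)
    masked[y0:y1, x0:x1] = -np.inf
    second = masked.max()
    if not np.isfinite(second) or second <= 0:
        return np.inf
    return float(peak / second)


def compute_piv(frame_a: np.ndarray, frame_b: np.ndarray,
                params: PivParams = PivParams(),
                pixel_size: float = 1.0,
                frame_interval: float = 1.0) -> VelocityField:
    """Velocity field of the motion from ``frame_a`` to ``frame_b``.

    Raises :class:`InputError` on shape mismatch or frames smaller than the
    interrogation window.  Zero-variance windows become invalid nodes, not
    exceptions.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"frame shapes differ: {a.shape} vs {b.shape}")
    ws = params.window_size
    if a.shape[0] < ws or a.shape[1] < ws:
        raise InputError(f"frames ({a.shape}) smaller than window ({ws} px)")

    step = params.step
    rows = np.arange(0, a.shape[0] - ws + 1, step)
    cols = np.arange(0, a.shape[1] - ws + 1, step)
    ny, nx = len(rows), len(cols)
    u = np.zeros((ny, nx))
    v = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    snr = np.zeros((ny, nx))
    center = ws // 2

    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            wa = a[r:r + ws, c:c + ws]
            wb = b[r:r + ws, c:c + ws]
            sa, sb = wa.std(), wb.std()
            if sa == 0 or sb == 0:      # featureless window: no signal
                continue
            corr = _correlate_pair(wa - wa.mean(), wb - wb.mean(),
                                   params.correlation)
            py, px = np.unravel_index(np.argmax(corr), corr.shape)
            node_snr = _peak_snr(corr, (py, px))
            dy = float(py - center)
            dx = float(px - center)
            # subpixel refinement, skipped when the peak touches the border
            if 0 < py < ws - 1:
                dy += _subpixel_offset(corr[py - 1, px], corr[py, px],
                                       corr[py + 1, px], params.subpixel)
            if 0 < px < ws - 1:
                dx += _subpixel_offset(corr[py, px - 1], corr[py, px],
                                       corr[py, px + 1], params.subpixel)
            u[i, j] = dx
            v[i, j] = -dy           # image rows point down; physical +y is up
            snr[i, j] = node_snr
            valid[i, j] = node_snr >= params.min_signal_to_noise

    gx, gy = np.meshgrid(cols + (ws - 1) / 2.0, rows + (ws - 1) / 2.0)
    return VelocityField(gx, gy, u, v, valid, pixel_size, frame_interval, snr=snr)


def filter_outliers(fld: VelocityField,
                    params: PivParams = PivParams()) -> VelocityField:
    """Normalized median test over the 8-neighbourhood.

    Each valid vector's residual to the component-wise median of its valid
    neighbours is normalized by the median absolute neighbour residual plus
    a 0.1 px robustness floor; vectors whose normalized residual exceeds
    ``params.outlier_threshold`` are invalidated.  No replacement or
    interpolation is performed.  Fields with fewer than 9 valid nodes are
    returned unchanged with a warning.
    """
    out = fld.copy()
    if fld.n_valid < 9:
        warnings.warn("fewer than 9 valid vectors; outlier filter skipped",
                      stacklevel=2)
        return out
    ny, nx = fld.u.shape
    new_valid = out.valid.copy()
    for i in range(ny):
        for j in range(nx):
            if not fld.valid[i, j]:
                continue
            i0, i1 = max(0, i - 1), min(ny, i + 2)
            j0, j1 = max(0, j - 1), min(nx, j + 2)
            sel = fld.valid[i0:i1, j0:j1].copy()
            sel[i - i0, j - j0] = False
            if not sel.any():
                continue
            nu = fld.u[i0:i1, j0:j1][sel]
            nv = fld.v[i0:i1, j0:j1][sel]
            med_u, med_v = np.median(nu), np.median(nv)
            resid = np.hypot(fld.u[i, j] - med_u, fld.v[i, j] - med_v)
            nb_resid = np.median(np.hypot(nu - med_u, nv - med_v))
            if resid / (nb_resid + 0.1) > params.outlier_threshold:
                new_valid[i, j] = False
    out.valid = new_valid
    return out


def piv_movie(seq: ImageSequence,
              params: PivParams = PivParams()) -> list[VelocityField]:
    """PIV + outlier filtering on every successive frame pair.

    Returns ``n_frames - 1`` fields.  A failure on one pair yields an
    all-invalid field for that pair (recorded via a warning), never an
    exception for the whole movie.
    """
    if seq.n_frames < 2:
        raise InputError("piv_movie needs at least 2 frames")
    fields: list[VelocityField] = []
    template: VelocityField | None = None
    for t in range(seq.n_frames - 1):
        try:
            fld = compute_piv(seq[t], seq[t + 1], params,
                              pixel_size=seq.pixel_size,
                              frame_interval=seq.frame_interval)
            fld = filter_outliers(fld, params)
            template = fld
        except InputError as exc:
            warnings.warn(f"PIV failed on frame pair {t}: {exc}", stacklevel=2)
            if template is None:
                raise
            fld = template.copy()
            fld.u[:] = 0.0
            fld.v[:] = 0.0
            fld.valid[:] = False
        fields.append(fld)
    return fields
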