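"""Core data containers: calibrated velocity fields and image sequences.

A :class:`VelocityField` holds one frame's gridded 2-D velocity vectors.
Components are stored in px/frame in the *physical* convention (+u is
rightward motion along +x, +v is upward motion; the image row axis points
down, so PIV row-lags are negated before they are stored here).  Calibrated
values in um/min are exposed as properties::

    u_um_min = u_px_frame * pixel_size / frame_interval

An :class:`ImageSequence` is a calibrated grayscale time-lapse stack
(frames x rows x cols) with a pixel size in um/px and a frame interval in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["VelocityField", "ImageSequence"]


@dataclass
class VelocityField:
    """Gridded velocity vectors for a single frame pair.

    Parameters
    ----------
    grid_x, grid_y:
        Window-centre coordinates in pixels, shape ``(ny, nx)``.  ``grid_y``
        follows the image row axis (increasing downward); metrics only use
        the velocity components, which are already in physical convention.
    u, v:
        Velocity components in px/frame, physical convention (+v up).
    valid:
        Boolean mask; invalid nodes are excluded from every downstream
        metric (they reduce the vector count N rather than being
        interpolated).
    pixel_size:
        um per pixel, > 0.
    frame_interval:
        Minutes per frame, > 0.
    snr:
        Optional per-node correlation signal-to-noise ratio.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    snr: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {self.grid_x.shape, self.grid_y.shape, self.u.shape,
                  self.v.shape, self.valid.shape}
        if len(shapes) != 1:
            raise InputError(f"velocity-field arrays have mismatched shapes: {shapes}")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InputError("pixel_size and frame_interval must be positive")
        if not np.all(np.isfinite(self.u[self.valid])) or not np.all(
                np.isfinite(self.v[self.valid])):
            raise InputError("u and v must be finite wherever valid")

    # -- calibration ------------------------------------------------------
    @property
    def scale(self) -> float:
        """px/frame -> um/min conversion factor."""
        return self.pixel_size / self.frame_interval

    @property
    def u_um_min(self) -> np.ndarray:
        return self.u * self.scale

    @property
    def v_um_min(self) -> np.ndarray:
        return self.v * self.scale

    @property
    def x_um(self) -> np.ndarray:
        return self.grid_x * self.pixel_size

    @property
    def y_um(self) -> np.ndarray:
        return self.grid_y * self.pixel_size

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_velocities(cls, u, v, valid=None, pixel_size: float = 1.0,
                        frame_interval: float = 1.0, grid_spacing: float = 1.0,
                        snr=None) -> "VelocityField":
        """Build a field from component arrays on a default regular grid.

        Convenient for metrics on precomputed or simulated velocities; the
        grid coordinates are window indices times ``grid_spacing``.
        """
        u = np.atleast_2d(np.asarray(u, dtype=float))
        v = np.atleast_2d(np.asarray(v, dtype=float))
        ny, nx = u.shape
        gx, gy = np.meshgrid(np.arange(nx) * grid_spacing,
                             np.arange(ny) * grid_spacing)
        if valid is None:
            valid = np.ones_like(u, dtype=bool)
        return cls(gx, gy, u, v, np.atleast_2d(valid), pixel_size,
                   frame_interval, snr=snr)

    def copy(self) -> "VelocityField":
        return VelocityField(self.grid_x.copy(), self.grid_y.copy(),
                             self.u.copy(), self.v.copy(), self.valid.copy(),
                             self.pixel_size, self.frame_interval,
                             snr=None if self.snr is None else self.snr.copy())


@dataclass
class ImageSequence:
    """Calibrated grayscale time-lapse stack."""

    frames: np.ndarray          # (n_frames, rows, cols)
    pixel_size: float = 1.0     # um/px
    frame_interval: float = 1.0  # min

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InputError("frames must be a 3-D (time, rows, cols) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InputError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]
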