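"""File I/O: TIFF stacks with sidecar calibration, CSV interchange.

All interchange formats are plain text (CSV) so results remain
inspectable and language-neutral; TIFF calibration travels in a sidecar
JSON (``<stack>.json``) because TIFF tag conventions for pixel size and
frame interval vary between acquisition systems.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .fields import ImageSequence, VelocityField

__all__ = [
    "read_image_stack", "write_image_stack",
    "write_fields", "read_fields",
    "write_table",
]

FIELD_COLUMNS = ["frame", "grid_ix", "grid_iy", "x_um", "y_um",
                 "u_um_min", "v_um_min", "valid", "snr"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_image_stack(path, pixel_size: float | None = None,
                     frame_interval: float | None = None) -> ImageSequence:
    """Read a single- or multi-page grayscale TIFF as an ImageSequence.

    Calibration is taken from the explicit arguments when given, else from
    a sidecar JSON next to the stack (``<name>.tif.json`` with keys
    ``pixel_size_um`` and ``frame_interval_min``).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image stack not found: {path}")
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # truncated/corrupt file -> parse error
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise InputError(f"expected a grayscale stack, got shape {frames.shape}")

    if pixel_size is None or frame_interval is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise InputError(
                f"no calibration given and no sidecar {sidecar.name}; "
                "provide pixel_size (um/px) and frame_interval (min)")
        meta = json.loads(sidecar.read_text())
        pixel_size = pixel_size or meta.get("pixel_size_um")
        frame_interval = frame_interval or meta.get("frame_interval_min")
        if pixel_size is None or frame_interval is None:
            raise InputError(f"sidecar {sidecar.name} lacks pixel_size_um "
                             "or frame_interval_min")
    return ImageSequence(frames.astype(float), float(pixel_size),
                         float(frame_interval))


def write_image_stack(seq: ImageSequence, path) -> Path:
    """Write a 16-bit TIFF stack plus calibration sidecar JSON."""
    path = Path(path)
    frames = seq.frames
    lo, hi = frames.min(), frames.max()
    scaled = np.zeros_like(frames) if hi == lo else (frames - lo) / (hi - lo)
    tifffile.imwrite(path, (scaled * 65535).astype(np.uint16),
                     photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps({
        "pixel_size_um": seq.pixel_size,
        "frame_interval_min": seq.frame_interval,
    }, indent=2, sort_keys=True) + "\n")
    return path


def fields_to_dataframe(fields: list[VelocityField]) -> pd.DataFrame:
    rows = []
    for t, fld in enumerate(fields):
        ny, nx = fld.u.shape
        iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        snr = fld.snr if fld.snr is not None else np.full((ny, nx), np.nan)
        rows.append(pd.DataFrame({
            "frame": t,
            "grid_ix": ix.ravel(),
            "grid_iy": iy.ravel(),
            "x_um": fld.x_um.ravel(),
            "y_um": fld.y_um.ravel(),
            "u_um_min": fld.u_um_min.ravel(),
            "v_um_min": fld.v_um_min.ravel(),
            "valid": fld.valid.ravel().astype(int),
            "snr": snr.ravel(),
        }))
    return pd.concat(rows, ignore_index=True)


def write_fields(fields: list[VelocityField], path,
                 pixel_size: float | None = None,
                 frame_interval: float | None = None) -> Path:
    """Serialize a velocity-field list as CSV (plus calibration sidecar)."""
    path = Path(path)
    df = fields_to_dataframe(fields)
    df.to_csv(path, index=False, float_format="%.10g")
    cal = {
        "pixel_size_um": pixel_size if pixel_size is not None else fields[0].pixel_size,
        "frame_interval_min": (frame_interval if frame_interval is not None
                               else fields[0].frame_interval),
    }
    _sidecar_path(path).write_text(json.dumps(cal, indent=2, sort_keys=True) + "\n")
    return path


def read_fields(path) -> list[VelocityField]:
    """Read velocity fields written by :func:`write_fields`.

    Unknown columns are ignored with a warning; NaN velocities at valid
    nodes or inconsistent grids raise a parse error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"fields file not found: {path}")
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in FIELD_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns {unknown} in {path.name}",
                      stacklevel=2)
        df = df.drop(columns=unknown)
    missing = [c for c in FIELD_COLUMNS if c not in df.columns and c != "snr"]
    if missing:
        raise InputError(f"fields file {path.name} missing columns {missing}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta["pixel_size_um"])
        frame_interval = float(meta["frame_interval_min"])
    else:
        pixel_size, frame_interval = 1.0, 1.0

    scale = pixel_size / frame_interval
    fields = []
    for t, grp in df.groupby("frame", sort=True):
        ny = int(grp["grid_iy"].max()) + 1
        nx = int(grp["grid_ix"].max()) + 1
        if len(grp) != ny * nx:
            raise InputError(f"frame {t}: grid is not complete ({len(grp)} rows "
                             f"for a {ny}x{nx} grid)")
        grp = grp.sort_values(["grid_iy", "grid_ix"])

        def grid(col):
            return grp[col].to_numpy().reshape(ny, nx)

        valid = grid("valid").astype(bool)
        u = grid("u_um_min") / scale
        v = grid("v_um_min") / scale
        if np.isnan(u[valid]).any() or np.isnan(v[valid]).any():
            raise InputError(f"frame {t}: NaN velocity at a valid node")
        u = np.nan_to_num(u)
        v = np.nan_to_num(v)
        snr = grid("snr") if "snr" in grp.columns else None
        fields.append(VelocityField(
            grid("x_um") / pixel_size, grid("y_um") / pixel_size,
            u, v, valid, pixel_size, frame_interval, snr=snr))
    return fields


def write_table(df: pd.DataFrame, path) -> Path:
    """Deterministic CSV writer used for all tabular outputs."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
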