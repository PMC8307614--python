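"""End-to-end orchestration: stack -> PIV -> metrics -> kymograph -> edges.

:func:`run_pipeline` runs the whole analysis on a calibrated image stack
and writes a structured results bundle (fields.csv, metrics.csv,
polar.csv, kymo.csv, edges.csv, summary.json, run.log).  Outputs are
deterministic for a fixed input and configuration; the configuration hash
is recorded in the summary so bundles can be traced to their settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigurationError, InputError
from .io import read_image_stack, write_fields, write_table
from .kymo import edge_displacement_series, xvelocity_kymograph
from .metrics import (angle_distribution, max_migration_speed,
                      metric_timeseries, value_at_time)
from .piv import PivParams, piv_movie

logger = logging.getLogger("collmigr")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one end-to-end analysis run.

    ``stimulation_onset`` (min) marks the boundary between the control and
    stimulation epochs; the summary reports the directionality at the
    single frame nearest onset + 4 h, and the maximum smoothed speed over
    the whole movie.
    """

    input_path: str
    pixel_size: float | None = None      # um/px
    frame_interval: float | None = None  # min
    piv: PivParams = field(default_factory=PivParams)
    smoothing_window: int = 3
    polar_bins: int = 24
    kymo_row_min: float = 10.0
    kymo_col_um: float = 42.0
    stimulation_onset: float = 0.0       # min
    output_dir: str = "results"
    seed: int = 0
    track_edges: bool = True

    def __post_init__(self) -> None:
        if self.stimulation_onset < 0:
            raise ConfigurationError("stimulation_onset must be >= 0")
        for name in ("pixel_size", "frame_interval"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ConfigurationError(f"{name} must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("piv"), dict):
            d["piv"] = PivParams(**d["piv"])
        return cls(**d)

    @classmethod
    def from_json_file(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Digest of the analysis settings (excludes the output location)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run PIV, metrics, kymograph and edge tracking; write the bundle.

    Returns the summary dictionary that is also written as summary.json.
    Fails fast (before writing anything) on unreadable input or missing
    calibration.
    """
    seq = read_image_stack(config.input_path, config.pixel_size,
                           config.frame_interval)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    collected: list[str] = []
    try:
        logger.info("collmigr %s | config %s", __version__, config.config_hash)
        logger.info("input %s: %d frames of %s, %.4g um/px, %.4g min/frame",
                    config.input_path, seq.n_frames, seq.shape,
                    seq.pixel_size, seq.frame_interval)

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fields = piv_movie(seq, config.piv)
            series = metric_timeseries(fields, config.smoothing_window)
            polar = angle_distribution(fields, config.polar_bins)
            kymo = xvelocity_kymograph(fields, config.kymo_row_min,
                                       config.kymo_col_um)
            edges = None
            if config.track_edges:
                edges = edge_displacement_series(seq)
        collected = [str(w.message) for w in caught]
        for msg in collected:
            logger.warning(msg)

        write_fields(fields, outdir / "fields.csv")
        write_table(series.to_dataframe(), outdir / "metrics.csv")
        write_table(polar.to_dataframe(), outdir / "polar.csv")
        write_table(kymo.to_dataframe(), outdir / "kymo.csv")
        if edges is not None:
            write_table(edges.to_dataframe(), outdir / "edges.csv")

        t_report = config.stimulation_onset + 240.0  # 4 h into stimulation
        summary = {
            "collmigr_version": __version__,
            "config_hash": config.config_hash,
            "n_frames": seq.n_frames,
            "n_fields": len(fields),
            "pixel_size_um": seq.pixel_size,
            "frame_interval_min": seq.frame_interval,
            "max_speed_um_min": _safe(max_migration_speed, series),
            "directionality_at_4h": (
                value_at_time(series, t_report, "directionality")
                if series.time[-1] >= t_report else None),
            "mean_coordination": _nanmean(series.coordination),
            "mean_directionality": _nanmean(series.directionality),
            "mean_x_velocity_um_min": _nanmean(series.x_velocity),
            "final_leading_displacement_um": (
                float(edges.displacement[-1]) if edges is not None
                and np.isfinite(edges.displacement[-1]) else None),
            "n_warnings": len(collected),
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        (outdir / "config.json").write_text(config.to_json() + "\n")
        logger.info("bundle written to %s", outdir)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def _safe(fn, *args):
    try:
        return float(fn(*args))
    except (InputError, ValueError):
        return None


def _nanmean(arr) -> float | None:
    arr = np.asarray(arr, dtype=float)
    if np.all(np.isnan(arr)):
        return None
    return float(np.nanmean(arr))
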