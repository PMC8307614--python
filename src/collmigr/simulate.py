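"""Synthetic monolayers with tunable collectivity, and image renderers.

The generator is a Vicsek-style active-matter model: point agents move at
a fixed speed and, each step, turn toward the mean heading of their
neighbours within an interaction radius, subject to uniform angular noise.
A single ``coupling`` parameter weights the neighbour-alignment term and
stands in for the strength of cell-cell adhesion (experimentally tuned via
extracellular calcium / E-cadherin); an optional ``field_bias`` term pulls
headings toward +x and stands in for a DC electric-field command.  Agent
speed decreases linearly with coupling (floored at 10% of base speed),
reproducing the empirical trade-off in which more coordinated tissues
migrate more slowly.

Heading update for agent i (all terms are unit vectors, then re-normalized
by taking the angle):

    target_i = e(theta_i) + coupling * <e(theta_j)>_{j in nbhd(i)} + field_bias * x_hat
    theta_i' = angle(target_i) + eta,   eta ~ Uniform[-a, +a],
    a = min(noise / (1 + coupling), pi)

where ``nbhd(i)`` includes i itself.  The angular-noise amplitude is
damped by the coupling: physically, strong junctional coupling suppresses
directional fluctuations of individual cells as well as aligning them, and
numerically this makes the steady-state order parameter increase with
coupling over its whole range instead of saturating.  coupling = 0 reduces
to a heading random walk (isotropic at large noise); large coupling with
zero noise drives all headings to a common value; large field_bias aligns
headings with +x regardless of neighbours.

The module also renders synthetic image data with known ground truth:
:func:`render_speckle` warps a Gaussian-blob speckle texture by a
prescribed displacement field (for PIV validation) and
:func:`make_edge_scenario` produces a textured "tissue" whose free right
edge advances, stays static, or retracts at a programmed rate (for the
segmentation / edge-tracking pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import binned_statistic_2d

from .errors import ConfigurationError, InputError
from .fields import ImageSequence, VelocityField

__all__ = [
    "SimulationConfig", "AgentTrajectory",
    "simulate_monolayer", "trajectory_to_field", "trajectory_order_parameters",
    "render_speckle", "make_edge_scenario",
]

BOUNDARY_MODES = ("periodic", "free_x_edges")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the tunable-collectivity monolayer model.

    Defaults emulate a confluent keratinocyte monolayer patch: ~1 cell per
    (20 um)^2 in a 400x400 um box, interaction radius of one cell diameter,
    base speed 1 um/min, sampled every 5 min.
    """

    n_agents: int = 400
    box_width: float = 400.0        # um
    box_height: float = 400.0       # um
    coupling: float = 1.0           # neighbour-alignment weight (>= 0)
    noise: float = 1.6              # base angular noise half-width, rad, <= pi
    field_bias: float = 0.0         # weight pulling headings toward +x
    base_speed: float = 1.0         # um/min
    speed_coupling_slope: float = 0.1   # fractional speed loss per coupling unit
    interaction_radius: float = 60.0    # um (supracellular correlation scale)
    dt: float = 5.0                 # min per frame
    n_frames: int = 108             # 9 h at 5 min/frame
    seed: int = 0
    boundary_mode: str = "periodic"

    def __post_init__(self) -> None:
        if self.n_agents <= 0 or self.n_frames <= 0:
            raise ConfigurationError("n_agents and n_frames must be positive")
        for name in ("box_width", "box_height", "base_speed",
                     "interaction_radius", "dt"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("coupling", "noise", "field_bias", "speed_coupling_slope"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.noise > np.pi:
            raise ConfigurationError("noise must be <= pi")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ConfigurationError(
                f"boundary_mode must be one of {BOUNDARY_MODES}")

    @property
    def agent_speed(self) -> float:
        """um/min; linear decrease with coupling, floored at 10% base."""
        return max(self.base_speed * (1.0 - self.speed_coupling_slope * self.coupling),
                   0.1 * self.base_speed)

    @property
    def noise_amplitude(self) -> float:
        """Effective angular-noise half-width: base noise damped by coupling."""
        return min(self.noise / (1.0 + self.coupling), float(np.pi))

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class AgentTrajectory:
    """Per-frame agent states of one simulated monolayer."""

    positions: np.ndarray   # (n_frames, n_agents, 2) um
    headings: np.ndarray    # (n_frames, n_agents) rad in (-pi, pi]
    speeds: np.ndarray      # (n_frames, n_agents) um/min
    config: SimulationConfig

    def __post_init__(self) -> None:
        nf, na = self.headings.shape
        if nf != self.config.n_frames or na != self.config.n_agents:
            raise InputError("trajectory shape inconsistent with config")
        if self.positions.shape != (nf, na, 2) or self.speeds.shape != (nf, na):
            raise InputError("trajectory arrays have mismatched shapes")
        if (self.speeds < 0).any():
            raise InputError("speeds must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.headings.shape[0]

    @property
    def n_agents(self) -> int:
        return self.headings.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        nf, na = self.headings.shape
        frames = np.repeat(np.arange(nf), na)
        agents = np.tile(np.arange(na), nf)
        return pd.DataFrame({
            "frame": frames,
            "agent_id": agents,
            "x_um": self.positions[:, :, 0].ravel(),
            "y_um": self.positions[:, :, 1].ravel(),
            "heading_rad": self.headings.ravel(),
            "speed_um_min": self.speeds.ravel(),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: SimulationConfig) -> "AgentTrajectory":
        nf = int(df["frame"].max()) + 1
        na = int(df["agent_id"].max()) + 1
        df = df.sort_values(["frame", "agent_id"])
        pos = np.stack([df["x_um"].to_numpy().reshape(nf, na),
                        df["y_um"].to_numpy().reshape(nf, na)], axis=-1)
        return cls(pos, df["heading_rad"].to_numpy().reshape(nf, na),
                   df["speed_um_min"].to_numpy().reshape(nf, na), config)


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Map angles to (-pi, pi]."""
    out = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def _neighbor_mean_unit(pos: np.ndarray, headings: np.ndarray,
                        cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Mean unit heading vector over each agent's neighbourhood (self incl.)."""
    n = len(headings)
    cx, sx = np.cos(headings), np.sin(headings)
    if cfg.boundary_mode == "periodic":
        tree = cKDTree(pos, boxsize=(cfg.box_width, cfg.box_height))
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(cfg.interaction_radius, output_type="ndarray")
    sum_c = cx.copy()
    sum_s = sx.copy()
    count = np.ones(n)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(sum_c, i, cx[j])
        np.add.at(sum_c, j, cx[i])
        np.add.at(sum_s, i, sx[j])
        np.add.at(sum_s, j, sx[i])
        np.add.at(count, i, 1.0)
        np.add.at(count, j, 1.0)
    return sum_c / count, sum_s / count


def simulate_monolayer(config: SimulationConfig) -> AgentTrajectory:
    """Run the alignment model; bit-identical output for identical config."""
    rng = np.random.default_rng(config.seed)
    nf, na = config.n_frames, config.n_agents
    w, h = config.box_width, config.box_height

    positions = np.empty((nf, na, 2))
    headings = np.empty((nf, na))
    speed = config.agent_speed
    speeds = np.full((nf, na), speed)

    positions[0, :, 0] = rng.uniform(0.0, w, na)
    positions[0, :, 1] = rng.uniform(0.0, h, na)
    headings[0] = _wrap_angle(rng.uniform(-np.pi, np.pi, na))

    amp = config.noise_amplitude
    for t in range(1, nf):
        pos = positions[t - 1]
        th = headings[t - 1]
        mean_c, mean_s = _neighbor_mean_unit(pos, th, config)
        tx = np.cos(th) + config.coupling * mean_c + config.field_bias
        ty = np.sin(th) + config.coupling * mean_s
        mag = np.hypot(tx, ty)
        target = np.where(mag > 1e-12, np.arctan2(ty, tx), th)
        if amp > 0:
            target = target + rng.uniform(-amp, amp, na)
        th_new = _wrap_angle(target)
        step = speed * config.dt
        new_pos = pos + step * np.stack([np.cos(th_new), np.sin(th_new)], axis=-1)
        if config.boundary_mode == "periodic":
            new_pos[:, 0] = np.mod(new_pos[:, 0], w)
            new_pos[:, 1] = np.mod(new_pos[:, 1], h)
        else:   # free_x_edges: x unbounded, y periodic
            new_pos[:, 1] = np.mod(new_pos[:, 1], h)
        positions[t] = new_pos
        headings[t] = th_new

    return AgentTrajectory(positions, headings, speeds, config)


def trajectory_order_parameters(traj: AgentTrajectory,
                                discard_fraction: float = 0.5) -> dict:
    """Time-averaged agent-level summaries of one simulation.

    Discards the initial transient (``discard_fraction`` of the frames)
    and returns the mean polarization order parameter (magnitude of the
    mean unit heading vector per frame), the mean agent speed (um/min) and
    the mean directionality (cosine of heading to +x).
    """
    start = int(discard_fraction * traj.n_frames)
    h = traj.headings[start:]
    coord = np.hypot(np.cos(h).mean(axis=1), np.sin(h).mean(axis=1)).mean()
    return {
        "coordination": float(coord),
        "speed": float(traj.speeds[start:].mean()),
        "directionality": float(np.cos(h).mean()),
    }


def trajectory_to_field(traj: AgentTrajectory, frame: int,
                        grid_spacing: float = 40.0) -> VelocityField:
    """Bin frame-to-frame agent velocities onto a regular grid.

    Velocity of each agent is its displacement to the next frame divided by
    ``dt`` (periodic boundaries use the minimal-image displacement); grid
    cells average the agents they contain and cells with no agents are
    marked invalid.  The returned field carries unit calibration, so its
    px/frame values are numerically um/min.
    """
    cfg = traj.config
    if not 0 <= frame < traj.n_frames - 1:
        raise InputError(f"frame {frame} out of range for velocity extraction")
    disp = traj.positions[frame + 1] - traj.positions[frame]
    if cfg.boundary_mode == "periodic":
        disp[:, 0] -= cfg.box_width * np.round(disp[:, 0] / cfg.box_width)
    disp[:, 1] -= cfg.box_height * np.round(disp[:, 1] / cfg.box_height)
    vel = disp / cfg.dt

    pos = traj.positions[frame]
    x_edges = np.arange(0.0, cfg.box_width + grid_spacing, grid_spacing)
    y_edges = np.arange(0.0, cfg.box_height + grid_spacing, grid_spacing)
    stat_u, _, _, _ = binned_statistic_2d(
        pos[:, 0], pos[:, 1], vel[:, 0], "mean", bins=[x_edges, y_edges])
    stat_v, _, _, _ = binned_statistic_2d(
        pos[:, 0], pos[:, 1], vel[:, 1], "mean", bins=[x_edges, y_edges])
    count, _, _, _ = binned_statistic_2d(
        pos[:, 0], pos[:, 1], vel[:, 0], "count", bins=[x_edges, y_edges])
    # binned_statistic_2d returns (x, y)-indexed arrays; transpose to (row, col)
    u = stat_u.T
    v = stat_v.T
    valid = count.T > 0
    u = np.where(valid, u, 0.0)
    v = np.where(valid, v, 0.0)
    cx = 0.5 * (x_edges[:-1] + x_edges[1:])
    cy = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx, gy = np.meshgrid(cx, cy)
    return VelocityField(gx, gy, u, v, valid, pixel_size=1.0, frame_interval=1.0)


def _speckle_texture(shape: tuple[int, int], rng: np.random.Generator,
                     density: float, radius: float) -> np.ndarray:
    """Random Gaussian-blob texture, normalized to roughly [0, 1]."""
    h, w = shape
    n_blobs = max(1, int(density * h * w))
    img = np.zeros(shape)
    rows = rng.integers(0, h, n_blobs)
    cols = rng.integers(0, w, n_blobs)
    amps = rng.uniform(0.5, 1.5, n_blobs)
    np.add.at(img, (rows, cols), amps)
    img = ndimage.gaussian_filter(img, radius, mode="wrap")
    rng_span = img.max() - img.min()
    if rng_span > 0:
        img = (img - img.min()) / rng_span
    return img


def render_speckle(displacement_field, shape: tuple[int, int],
                   n_frames: int, seed: int = 0,
                   speckle_density: float = 0.02, speckle_radius: float = 2.0,
                   pixel_size: float = 1.0, frame_interval: float = 1.0,
                   piv_window: int = 32) -> ImageSequence:
    """Speckle movie advected by a prescribed per-pixel displacement field.

    ``displacement_field`` is ``(u, v)`` in px/frame, physical convention
    (+v up); scalars broadcast to uniform motion.  Frame 0 is a random
    Gaussian-blob texture; each subsequent frame is the previous one warped
    by the field with bilinear interpolation and periodic wrapping.  A
    warning is emitted if displacements exceed a quarter of ``piv_window``,
    beyond which PIV recovery is not guaranteed.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    h, w = shape
    u, v = displacement_field
    u = np.broadcast_to(np.asarray(u, dtype=float), shape)
    v = np.broadcast_to(np.asarray(v, dtype=float), shape)
    max_disp = float(np.max(np.hypot(u, v)))
    if max_disp > piv_window / 4.0:
        warnings.warn(
            f"max displacement {max_disp:.2f} px exceeds window/4 = "
            f"{piv_window / 4:.1f} px; PIV recovery not guaranteed",
            stacklevel=2)

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h, w))
    frames[0] = _speckle_texture(shape, rng, speckle_density, speckle_radius)
    if n_frames > 1:
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        # new(r, c) = old(r + v, c - u): +v physical up = -row
        sample_r = rr + v
        sample_c = cc - u
        for t in range(1, n_frames):
            frames[t] = ndimage.map_coordinates(
                frames[t - 1], [sample_r, sample_c], order=1, mode="wrap")
    return ImageSequence(frames, pixel_size, frame_interval)


def make_edge_scenario(mode: str, rate: float, shape: tuple[int, int] = (128, 256),
                       n_frames: int = 11, seed: int = 0,
                       pixel_size: float = 1.0, frame_interval: float = 1.0,
                       ) -> tuple[ImageSequence, np.ndarray]:
    """Textured tissue with a free right edge that moves at a known rate.

    The tissue occupies the left portion of the frame (high-contrast
    speckle texture); the background is low-amplitude per-frame noise.  The
    true edge x-position moves by ``+rate`` (advance), 0 (static) or
    ``-rate`` (retract) px/frame.  Returns the image sequence and the
    ground-truth per-frame edge position in px.
    """
    if mode not in ("advance", "static", "retract"):
        raise ConfigurationError("mode must be advance, static or retract")
    if rate < 0:
        raise ConfigurationError("rate must be >= 0")
    h, w = shape
    sign = {"advance": 1.0, "static": 0.0, "retract": -1.0}[mode]
    start = {"advance": 0.4 * w, "static": 0.5 * w, "retract": 0.6 * w}[mode]
    edges = start + sign * rate * np.arange(n_frames)
    if edges.min() < 8 or edges.max() > w - 8:
        raise ConfigurationError("edge leaves the frame; reduce rate or n_frames")

    rng = np.random.default_rng(seed)
    # dense fine speckle: a confluent monolayer's texture is homogeneous at
    # the scale of the segmentation window, which keeps the detected edge
    # position free of texture-dependent offsets
    texture = _speckle_texture(shape, rng, density=0.5, radius=1.2)
    cols = np.arange(w)
    frames = np.empty((n_frames, h, w))
    for t, edge in enumerate(edges):
        bg = 0.05 * rng.standard_normal((h, w))
        frames[t] = np.where(cols[None, :] < edge, texture, bg)
    return ImageSequence(frames, pixel_size, frame_interval), edges
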