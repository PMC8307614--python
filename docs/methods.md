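# Methods

This note describes the models and numerical choices behind `collmigr`:
what each stage computes, the assumptions it makes, the defaults and why,
and what the synthetic ground truths do and do not establish about real
microscopy data.

## Velocity fields and calibration

A `VelocityField` stores one frame pair's gridded velocities in px/frame
and exposes µm/min through the exact conversion
`u_um_min = u_px_frame · pixel_size / frame_interval`.  All components are
kept in the *physical* convention: +u is rightward motion along the field
axis, +v is upward.  Image arrays are row-major top-down, so the row
component of a correlation lag is negated once, at the PIV stage; every
downstream metric then works in physical coordinates without special
cases.

Invalid grid nodes (featureless windows, low correlation signal-to-noise,
outliers) are excluded from every metric — they reduce the vector count N
rather than being interpolated.  Interpolation hides failure modes and
correlates neighbouring vectors; exclusion keeps each retained vector an
independent measurement.

## PIV

Interrogation windows (default 32 px, 50% overlap) are mean-subtracted and
cross-correlated via the FFT.  Two correlation modes exist:

- **linear** (default): windows are zero-padded to twice their size and
  each lag is normalized by its overlap area.  Plain circular correlation
  is biased toward zero displacement on ordinary textures, because image
  content just outside the window — spatially correlated with the window's
  own content — aliases into small lags (we measured ~6% underestimation
  of a 4 px shift on speckle).  Zero-padding removes the aliasing and the
  overlap normalization removes the triangular envelope.
- **circular**: no padding.  For a texture that is periodic within the
  window the correlation plane is an exactly even autocorrelation about
  the true lag, so integer shifts are recovered to machine precision; this
  mode exists for that diagnostic.

The integer peak is refined per axis by a three-point Gaussian fit
(log-parabola), falling back to a plain parabolic fit when a neighbouring
correlation value is non-positive.  Peaks touching the search-plane border
are not refined.  The search is limited to lags within ±window/2;
displacements above window/4 are outside the design envelope and the
speckle renderer warns when asked to produce them.

A node's signal-to-noise ratio is the primary peak over the highest peak
outside a 3 px exclusion zone; nodes below 1.3 are invalid.  The
normalized median test (8-neighbourhood, residual normalized by the median
absolute neighbour residual + 0.1 px, threshold 2) then invalidates
spurious vectors.  With a calibration near 1.3 µm/px the default window
spans ~42 µm of monolayer — a few cell diameters, the scale at which
epithelial motion is locally coherent.

Window size, overlap, the subpixel estimator and both gate values are
declared defaults, not values inferred from any particular dataset.

## Migration metrics

Directionality is the mean of cos θᵢ = uᵢ/‖v⃗ᵢ‖ over valid nonzero
vectors; coordination is the magnitude of the mean unit vector.  Both
divide by the vector norm, so vectors shorter than 1e-9 µm/min are
excluded as directionless.  Both metrics are invariant to rescaling all
magnitudes; coordination is invariant to global rotation, and for a field
whose vectors all lie on the x-axis, coordination equals |directionality|.

Time series apply each metric per frame; frames where a metric is
undefined carry NaN (never 0 — zero is a meaningful value).  Optional
smoothing is a centred moving average, default 3 frames.  "Maximum
migration speed" is defined as the maximum over time of the smoothed
spatial-mean speed, and per-epoch report values ("directionality 4 h after
stimulation onset") take the single frame nearest the requested time.
Coordination is computed per frame and then averaged over time where a
summary is needed, not on pooled vectors.

The neighbour velocity correlation is the cosine similarity between each
vector and the mean of its valid 4-connected grid neighbours, averaged
over nodes with at least one neighbour.  Estimators based on per-component
Pearson correlation or larger neighbourhoods are plausible alternatives;
this one was chosen for being local, bounded in [−1, 1] and magnitude-free.

Polar angle distributions pool atan2(vᵢ, uᵢ) over all valid nonzero
vectors of the supplied fields into equal bins over (−π, π], normalized to
fractions.

## Kymographs and edges

The x-velocity kymograph averages calibrated u over the y-axis and over
time bins: rows are 10 min and columns 42 µm by default, so each cell
summarises a strip of monolayer over a stimulation-scale interval.  Cells
with no valid vectors are missing (NaN), not zero.

Tissue segmentation assumes phase-contrast tissue is texture-rich and the
free substrate smooth: the local standard deviation over a 13 px window is
thresholded (Otsu), the largest connected component kept, holes filled.
Two degenerate cases are handled explicitly.  A frame of spatially
uncorrelated noise (no tissue) is detected by how much variance survives a
2 px Gaussian blur — white noise loses >60% of its standard deviation,
real texture does not — and yields an empty mask with a warning.  A frame
that is texture throughout (no contrast between the Otsu classes) yields a
full mask.  Because the windowed SD dilates the tissue by about half the
window at a free boundary, the mask is finally eroded by window/2 with
image borders treated as tissue; the residual edge-position bias is below
the segmentation tolerance and, being constant in time, cancels entirely
in displacement series.

An edge position summarises a mask as the median over image rows of the
per-row extreme tissue extent (the column *after* the last tissue pixel
for the leading edge, the first tissue column for the trailing edge).  The
median is robust to fingers and streamers affecting a minority of rows.
Displacements are relative to the first frame; a retracting leading edge
is negative by construction.

The wound-closure rate fits a least-squares line to the gap width between
the right tissue's trailing edge and the left tissue's leading edge and
reports its negative slope; the closure time is the first sample with a
non-positive gap.  Frames with undefined edges are skipped by the fit.

## The synthetic monolayer model

The generator is a Vicsek-style alignment model.  Agent i updates its
heading θᵢ each step as

    target_i = e(θᵢ) + J · ⟨e(θⱼ)⟩_{j∈nbhd(i)} + b · x̂
    θᵢ' = angle(target_i) + η,   η ~ Uniform[−a, +a],
    a = min(noise / (1 + J), π)

where e(·) is the unit vector of an angle, the neighbourhood is all agents
within the interaction radius (self included), J ≥ 0 is the coupling and
b ≥ 0 the field bias.  Speed is J-dependent but constant in time:
`max(base_speed·(1 − slope·J), 0.1·base_speed)`.  Positions advance by
speed·dt along the new heading; boundaries are periodic (or periodic in y
only, with free x, in `free_x_edges` mode, where the neighbour search is
then non-periodic).

Two choices matter and were genuinely open:

- **Coupling damps the noise amplitude.**  With a fixed angular-noise
  amplitude, the steady-state polarization saturates once alignment
  dominates, so the order parameter is nearly flat in J above ~1 and its
  seed-to-seed fluctuations (±0.1 at 400 agents) swamp the trend the model
  exists to produce; the speed–coupling trade-off then even bends it
  downward, because slower agents mix and order more slowly.  Damping the
  amplitude as 1/(1+J) is the minimal mechanism that keeps the
  order-disorder crossover spread across a usable coupling range: strong
  junctional coupling both aligns a cell with its neighbours and
  suppresses its independent directional fluctuations.  With it, mean
  coordination rises monotonically across J ∈ {0, 0.5, 1, 2, 5} for every
  10-seed set we simulated, while mean speed falls deterministically.
- **The field bias is an additive unit vector toward +x**, not a force on
  positions: headings stay on the unit circle, the bias is dimensionless
  and competes directly with the alignment terms, and b ≫ J aligns the
  tissue with the field regardless of its internal state.

Defaults describe a confluent keratinocyte patch: 400 agents in a
400×400 µm box (one ~20 µm cell per cell area), base speed 1 µm/min,
frames every 5 min, 108 frames (a 9 h experiment), interaction radius
60 µm (the supracellular scale over which epithelial velocities are
correlated), base noise 1.6 rad, speed slope 0.1 (about a twofold speed
range across the coupling grid).  One seed drives initialization and all
noise; identical config + seed gives bit-identical trajectories.

`trajectory_to_field` turns frame-to-frame displacements (minimal-image
under periodic boundaries) into gridded fields by per-cell averaging, with
empty cells invalid — the same container the PIV stage produces, so every
metric runs identically on simulated and imaged data.

### What the synthetic data does and does not show

The speckle renderer advects a Gaussian-blob texture by a prescribed
displacement field with bilinear interpolation and periodic wrapping; the
edge scenarios move a hard texture boundary at a programmed rate over a
low-amplitude noise background.  These establish that the PIV, metric and
edge pipelines recover known kinematics to stated tolerances.  They do not
emulate phase-contrast optics (halos, contrast inversions), intensity
drift, cell division or death, out-of-plane motion, or deformable tissue
texture; real-data accuracy will be worse than the synthetic tolerances,
and the simulator's coupling parameter is an abstract collectivity dial —
it has no quantitative mapping to a calcium concentration or E-cadherin
level.  The edge scenarios are kinematic stand-ins only: nothing about
retraction mechanics is modelled.

## Determinism and I/O

Every random choice flows from an explicit integer seed through
`numpy.random.default_rng`.  The pipeline writes CSV with a fixed float
format and JSON with sorted keys, so identical input + configuration
reproduce every output byte; the summary records a SHA-256 digest of the
analysis settings (output location excluded) plus package and library
versions.  TIFF calibration travels in a sidecar JSON because TIFF tag
conventions for pixel size and frame interval are not portable.

## Problem sizes

The validation suite uses 256² px speckle pairs (15×15 vector grids),
128×256 px edge scenarios of 11 frames, and simulations of 400 agents for
108–150 frames with 10 seeds per condition — sizes at which every stated
tolerance is met and the whole suite runs in well under a minute on one
core.

## Known limitations

Single-pass PIV only (no window deformation or multi-pass refinement), so
shear larger than a few px per window is outside the envelope.  The
segmentation assumes one dominant tissue per frame and a texture-free
background.  The wound-closure estimator assumes an approximately linear
gap trajectory over the fitted interval.  `free_x_edges` mode ignores the
y-periodicity in the neighbour search.
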