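# collmigr

Quantification of collective cell migration under directed (electrotactic)
control.

When an epithelial monolayer is driven by a DC electric field, the questions
a time-lapse experiment must answer are quantitative: how fast do cells move,
how well is their motion aligned with the field, how coordinated is the
tissue internally, and what do its free edges do?  `collmigr` implements the
full desk-side analysis chain for such experiments — and a synthetic data
generator with known ground truth, so every stage of the chain can be
validated without microscopy data.

## What it computes

Given successive phase-contrast frames, particle image velocimetry (windowed
FFT cross-correlation, three-point Gaussian subpixel peak fit, normalized
median outlier test) produces gridded velocity fields v⃗ᵢ.  Two order
parameters summarise each field of N valid vectors:

- **Directionality** = (1/N) Σᵢ cos θᵢ, with θᵢ the angle between v⃗ᵢ and the
  horizontal field axis; −1 means all motion antiparallel to the field, +1
  all parallel.
- **Coordination** = ‖(1/N) Σᵢ v⃗ᵢ/‖v⃗ᵢ‖‖, the polarization order parameter
  of active-matter theory; 1 is a perfectly coordinated tissue, 0 isotropic
  motion.

Around these: mean speed and signed x-velocity, nearest-neighbour velocity
correlation, pooled polar angle histograms, x-velocity heat-map kymographs
(10 min/row, ~42 µm/column by default), texture-based tissue segmentation
with leading/trailing edge displacement traces, and a wound-closure rate
estimator for two facing tissues.

The synthetic module is a Vicsek-style active-matter model: agents align
with neighbours at a strength set by a single `coupling` parameter (a stand-
in for calcium/E-cadherin–dependent adhesion), an optional `field_bias`
pulls headings toward +x (the field command), and speed decreases with
coupling — reproducing the empirical trade-off in which more cohesive
tissues coordinate better but migrate slower and resist external steering.
It also renders speckle movies advected by a prescribed displacement field
(PIV ground truth) and tissue images whose free edge advances, holds or
retracts at a programmed rate (edge-pipeline ground truth).

## Worked example

```python
import numpy as np
import collmigr as cm

# speckle movie drifting at a known subpixel velocity
seq = cm.render_speckle((2.5, -1.5), (256, 256), 2, seed=1,
                        pixel_size=1.3, frame_interval=5.0)
fld = cm.compute_piv(seq[0], seq[1], cm.PivParams(window_size=32, overlap=0.5))
print(np.median(fld.u[fld.valid]), np.median(fld.v[fld.valid]))
# 2.511873112817183 -1.547038890296602   (truth: 2.5, -1.5 px/frame)

print(cm.directionality(fld), cm.coordination(fld))
# 0.8522865132129357 0.9978453250535642
```

The recovered median displacement is within ~0.05 px of the programmed
drift; directionality near +0.85 says the motion is largely along +x
(cos of the ~31° drift angle), and coordination near 1 says nearly all
vectors share one direction.

More narrative examples live in `examples/` (simulator trends, metric time
courses under a field switch, kymographs and edge tracking, the end-to-end
pipeline); each prints the numbers it computes and what they mean.

## Command line

A thin CLI wraps the library for shell use:

```
collmigr piv --stack movie.tif --pixel-size 1.3 --frame-interval 5 --out fields.csv
collmigr metrics --fields fields.csv --smooth 3 --out metrics.csv
collmigr kymo --fields fields.csv --row-min 10 --col-um 42 --out kymo.csv
collmigr edges --stack movie.tif --pixel-size 1.3 --frame-interval 5 --out edges.csv
collmigr run --config run.json      # the whole chain, one results bundle
```

All interchange is plain CSV with a JSON sidecar for calibration; reruns
with the same configuration are byte-identical.

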