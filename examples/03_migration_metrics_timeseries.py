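"""Directionality and coordination time courses under a field command.

Simulates an unstimulated epoch followed by an epoch with a +x field bias
(the electrotactic command), converts agent motion to gridded velocity
fields, and prints the per-epoch migration metrics.  Directionality jumps
once the bias switches on; coordination reflects neighbour coupling in
both epochs.
"""

import numpy as np

import collmigr as cm

base = cm.SimulationConfig(coupling=1.0, n_frames=36, seed=4)  # 3 h control
stim = base.with_(field_bias=2.0, seed=5, n_frames=72)         # 6 h stimulated

fields = []
for cfg in (base, stim):
    traj = cm.simulate_monolayer(cfg)
    fields += [cm.trajectory_to_field(traj, f, grid_spacing=40.0)
               for f in range(cfg.n_frames - 1)]

series = cm.metric_timeseries(fields, smoothing_window=3)
onset = base.n_frames - 1
for label, sl in [("control", slice(0, onset)),
                  ("stimulated", slice(onset, None))]:
    print(f"{label:>10}: directionality={np.nanmean(series.directionality[sl]):+.2f}  "
          f"coordination={np.nanmean(series.coordination[sl]):.2f}  "
          f"speed={np.nanmean(series.speed[sl]):.2f} um/min")

hist = cm.angle_distribution(fields[onset:], n_bins=12)
peak = hist.bin_centers[np.argmax(hist.frequency)]
print(f"\nstimulated-angle mode at {np.degrees(peak):+.0f} deg "
      f"({hist.frequency.max():.0%} of vectors); 0 deg = field axis (+x).")
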