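"""Validate PIV against a speckle movie with known motion.

Renders a speckle texture drifting at a programmed subpixel velocity,
runs the windowed FFT cross-correlation PIV on one frame pair, and
compares the median recovered displacement with the truth.
"""

import numpy as np

import collmigr as cm

truth = (2.5, -1.5)  # px/frame: rightward and downward
seq = cm.render_speckle(truth, (256, 256), 2, seed=1,
                        pixel_size=1.3, frame_interval=5.0)
fld = cm.compute_piv(seq[0], seq[1], cm.PivParams(window_size=32, overlap=0.5),
                     pixel_size=1.3, frame_interval=5.0)

u_med = np.median(fld.u[fld.valid])
v_med = np.median(fld.v[fld.valid])
print(f"programmed displacement : u={truth[0]:+.2f}, v={truth[1]:+.2f} px/frame")
print(f"recovered (median)      : u={u_med:+.2f}, v={v_med:+.2f} px/frame")
print(f"calibrated x-velocity   : {np.median(fld.u_um_min[fld.valid]):+.3f} um/min"
      f"  ({fld.n_valid}/{fld.valid.size} windows valid)")
print("\nA recovery error below ~0.1 px confirms the subpixel peak fit; the "
      "calibrated value is px/frame * pixel_size / frame_interval.")
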