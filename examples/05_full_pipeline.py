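"""End-to-end run: TIFF stack in, structured results bundle out.

Writes a calibrated synthetic movie to disk, runs the whole chain
(PIV -> metrics -> polar histogram -> kymograph -> edge tracking) through
one configuration object, and prints the machine-readable summary.
"""

import json
import tempfile
from pathlib import Path

import collmigr as cm

tmp = Path(tempfile.mkdtemp(prefix="collmigr_"))
stack = tmp / "movie.tif"
seq = cm.render_speckle((2.0, 0.0), (128, 128), 8, seed=3,
                        pixel_size=1.3, frame_interval=5.0)
cm.write_image_stack(seq, stack)

summary = cm.run_pipeline(cm.RunConfig(input_path=str(stack),
                                       output_dir=str(tmp / "results"),
                                       stimulation_onset=0.0, seed=0))
print(json.dumps(summary, indent=2, sort_keys=True))
print(f"\nbundle written to {tmp / 'results'}; mean_x_velocity_um_min should "
      "be ~ +0.52 (the programmed drift), and rerunning with the same "
      "config reproduces every CSV byte for byte.")
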