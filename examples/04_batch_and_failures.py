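"""Batch measurement over repeated captures, with a sabotaged frame.

A pig walking through the weigh channel yields several frame pairs; the
per-animal girth is the mean over the frames that survive the pipeline.
A deliberately empty side view shows the failure bookkeeping.
"""

import numpy as np

from girthkit import pipeline, synthpig
from girthkit.types import PipelineConfig, PointCloud

cfg = PipelineConfig(seed=7)
pig = synthpig.make_pig(synthpig.PigSpec(seed=2))
tops, sides = [], []
for k in range(3):
    scan = synthpig.render_two_views(pig, seed=200 + k)
    tops.append(scan.top)
    sides.append(scan.side)
# sabotage a fourth frame
tops.append(tops[0])
sides.append(PointCloud(np.zeros((0, 3)), frame_label="sensor_side"))

out = pipeline.run_pipeline(tops, sides, cfg, preprocessed=True)
for fr in out.frames:
    print(f"frame {fr.index}: "
          + (f"{fr.girth.girth_cm:.1f} cm" if fr.ok else f"FAILED ({fr.error})"))
print(f"animal girth: {out.mean_girth_cm:.1f} cm over {out.n_ok} frames "
      f"(truth {pig.ground_truth['girth_cm']:.1f} cm)")
print(f"failures by stage: {out.failures}")
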