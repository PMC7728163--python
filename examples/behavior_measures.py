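"""The nine postural/movement measures on a motif track.

Simulates a track cycling through the five built-in motifs and prints the
mean of each raw measure per motif segment: each motif should top the
measure it is built around (run -> locomotion, rear -> rear, freezes ->
freeze, freeze-bent -> bend, turn -> rotation).
"""

import numpy as np

import ethopose as ep
from ethopose import synthetic as syn
from ethopose.features import MEASURE_NAMES

scene = syn.make_scene(seed=2, noise_px=0.0)
program = [("run", 2.0), ("rear", 2.0), ("freeze_straight", 2.0),
           ("freeze_bent", 2.0), ("turn", 2.0)]
track = syn.simulate_track(scene, program)
raw = ep.compute_measures(track["params"], scene.truth_model)

print(f"{'motif':>16} " + " ".join(f"{m:>10}" for m in MEASURE_NAMES))
for k, (motif, _) in enumerate(program):
    seg = raw[30 * k : 30 * (k + 1)]
    print(f"{motif:>16} " + " ".join(f"{v:10.2f}" for v in seg.mean(axis=0)))

norm = ep.quantile_normalize(raw[None])[0]
print("\nafter quantile normalization every measure spans [0, 1]:")
print("min:", np.round(norm.min(axis=0), 2))
print("max:", np.round(norm.max(axis=0), 2))
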