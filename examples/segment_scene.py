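"""Segment one synthetic cardiomyocyte scene end to end.

Generates a default spread-regime dual-channel scene with known ground
truth, runs preprocess -> nucleus seeds -> EnFCM mask -> propagation, and
scores the result against the planted cell masks.
"""

from cardioseg import SceneParams, generate_scene, pixel_prf, segment_pair

pair, truth = generate_scene(SceneParams(seed=1))
seeds, cells, log = segment_pair(pair)

prf = pixel_prf(cells.as_binary(), truth.cell_labels.as_binary())
print(f"planted cells : {truth.cell_labels.n_objects}")
print(f"detected seeds: {seeds.n_objects}")
print(f"segmented     : {cells.n_objects}")
print(f"pixel precision {prf['precision']:.3f}  recall {prf['recall']:.3f}  "
      f"F {prf['f_score']:.3f}")
for stage in log["stages"]:
    print("  ", stage)

# The F-score compares every segmented foreground pixel with the planted
# truth; values near 0.95 mean the cell outlines are recovered almost
# exactly, with the remaining disagreement at blurred cell rims.
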