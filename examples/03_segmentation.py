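"""Segment a section into stroma / gland / lumen / hotspots and score it
against the phantom's ground truth.
"""

import numpy as np

import laims as L

phantom = L.generate_phantom(seed=3)
maps = L.apply_protocol(phantom, L.default_protocols()["FF"])
ls = L.simulate_linescans(maps, L.AcquisitionConfig(), seed=3)
p = L.lines_to_map(ls, "31P", 15.0)
zn = L.lines_to_map(ls, "64Zn", 15.0)

seg = L.segment_section(p, zn)
print(f"crop {seg.params.crop_shape_px} px at origin {seg.crop_origin} "
      "(1500 x 2250 µm at 15 µm/px)")
print("class pixel counts:", seg.class_counts())

truth = L.crop_to_roi(phantom.label_grid, seg.params.crop_shape_px,
                      seg.crop_origin)
pred = np.where(seg.hotspot, L.HOTSPOT, seg.labels.astype(int))
acc = float(np.mean(pred == truth))
hot = truth == L.HOTSPOT
sens = float(np.mean(pred[hot] == L.HOTSPOT))
print(f"\npixel accuracy vs ground truth: {acc:.1%}")
print(f"hotspot sensitivity: {sens:.1%} "
      "(luminal pixels above Q0.75 + 1.5*IQR of the clipped 64Zn data)")
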