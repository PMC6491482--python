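"""Pixel-level evaluation of an automatic mask against a reference.

Shows the four agreement scores (recall, precision, F1, Jaccard), the
count agreement helper, and the inner/outer shell stratification that
asks whether errors concentrate near the spheroid border.
"""
import numpy as np

from spherostack import confusion, count_agreement, scores, shell_scores
from spherostack.types import BinaryMask

PX = 0.345  # µm per pixel

yy, xx = np.ogrid[:200, :200]
membrane = BinaryMask((yy - 100) ** 2 + (xx - 100) ** 2 <= 80**2, PX)
manual = BinaryMask((yy - 100) ** 2 + (xx - 100) ** 2 <= 70**2, PX)

# an automatic mask that slightly over-segments near the spheroid border
auto_arr = (yy - 100) ** 2 + (xx - 100) ** 2 <= 73**2
automatic = BinaryMask(auto_arr, PX)

counts = confusion(manual, automatic)
rep = scores(counts)
print(f"TP={counts.tp} FP={counts.fp} FN={counts.fn}")
print(f"recall={rep.recall:.4f} precision={rep.precision:.4f} "
      f"F1={rep.f1:.4f} Jaccard={rep.jaccard:.4f}")

diff, rel = count_agreement(80, 84)
print(f"count agreement for 80 reference vs 84 detected: "
      f"difference {diff:+d}, relative error {rel:+.3f}")

inner, outer = shell_scores(manual, automatic, membrane, shell_width_um=10.0)
print(f"core  (inner): precision={inner.precision:.4f} recall={inner.recall:.4f}")
print(f"shell (outer): precision={outer.precision:.4f} recall={outer.recall:.4f}")
# The over-segmentation sits near the spheroid border, so only the outer
# shell's precision drops; the core is scored perfect.
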