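"""Plan the full-lung mosaic: 3 x 3 x 7 wide-field scans.

Builds the acquisition plan used for a whole juvenile-rat lung — 10.8 mm
wide-field scans whose valid inscribed square steps 7.2 mm horizontally,
3.0 mm tall stepping 2.75 mm vertically — and predicts the total wall time
from the per-step timing model.
"""

from mosaictomo import build_plan, estimate_duration, valid_regions
from mosaictomo.plan import PAPER_TIMING

plan = build_plan((3, 3, 7), (10.8, 10.8, 3.0), (7.2, 2.75),
                  pixel_size_um=2.75)
total, events = estimate_duration(plan, PAPER_TIMING)

n_v = sum(e["kind"] == "move" and e["axis"] == "vertical" for e in events)
n_h = sum(e["kind"] == "move" and e["axis"] == "horizontal" for e in events)
print(f"tiles: {plan.n_tiles}  (zigzag order, vertical axis fastest)")
print(f"mosaic extent: {plan.total_extent_mm[0]:.1f} x "
      f"{plan.total_extent_mm[1]:.1f} x {plan.total_extent_mm[2]:.1f} mm")
print(f"moves: {n_v} vertical, {n_h} horizontal")
print(f"predicted duration: {total:.0f} s = {total/60:.1f} min "
      "(must stay under ~22 min before tissue degradation)")

side, diam = valid_regions(10.8 / 2.75e-3)
print(f"valid data per scan: circle {diam:.0f} px across, "
      f"inscribed square {side} px "
      "(mosaic steps are sized against the square)")
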