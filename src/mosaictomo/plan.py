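"""Mosaic acquisition planning.

A large sample is covered by a 3D grid of overlapping wide-field tomographic
scans ("tiles").  Because fresh soft tissue degrades within tens of minutes,
the scan order and per-step durations matter: the planner produces a zigzag
order that always moves to an adjacent unmeasured tile (vertical axis
fastest, serpentine in the horizontal plane) and predicts the wall-clock
timeline of the whole acquisition from a small timing model.

Coordinate conventions: x = width (index i), y = length (index j),
z = height (index k, increasing upward).  Plan coordinates are mm, detector
coordinates are pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "TimingModel", "TilePose", "MosaicPlan",
    "build_plan", "estimate_duration", "valid_regions", "overlap_map",
    "scan_rotation_time_s", "physical_extent_mm", "dataset_size_tb",
    "PAPER_TIMING",
]


def scan_rotation_time_s(rotation_deg: float,
                         angular_speed_deg_s: float) -> float:
    """Pure rotation time of a continuous scan (no readout overhead)."""
    if angular_speed_deg_s <= 0:
        raise ValueError("angular speed must be > 0")
    return rotation_deg / angular_speed_deg_s


def physical_extent_mm(n_vox: int, pixel_size_um: float) -> float:
    """Physical length of ``n_vox`` voxels in mm."""
    return n_vox * pixel_size_um * 1e-3


def dataset_size_tb(shape_vox: tuple[int, ...],
                    bytes_per_voxel: int = 2) -> float:
    """Storage footprint of a voxel volume in TB (decimal, 1e12 bytes)."""
    n = 1
    for s in shape_vox:
        n *= int(s)
    return n * bytes_per_voxel / 1e12


@dataclass
class TimingModel:
    """Per-step durations of the acquisition loop.

    ``scan_time_s`` is the full wall time of one tomographic scan including
    script/readout overhead (not just ``rotation_range / angular_speed``).
    Motions are modelled as constant-speed translation plus a fixed settle
    overhead; if measured per-move averages are available they can be given
    via ``vertical_move_s`` / ``horizontal_move_s`` and take precedence.
    """

    scan_time_s: float = 9.0
    vertical_speed_um_s: float = 550.0
    horizontal_speed_um_s: float = 220.0
    move_overhead_s: float = 3.0
    calibration_time_s: float = 0.0
    vertical_move_s: float | None = None
    horizontal_move_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("scan_time_s", "vertical_speed_um_s",
                     "horizontal_speed_um_s", "move_overhead_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TimingModel.{name} must be > 0")
        if self.calibration_time_s < 0:
            raise ValueError("TimingModel.calibration_time_s must be >= 0")

    def move_duration_s(self, distance_mm: float, axis: str) -> float:
        """Duration of one translation along ``axis`` ('vertical'/'horizontal')."""
        if axis == "vertical":
            if self.vertical_move_s is not None:
                return self.vertical_move_s
            speed = self.vertical_speed_um_s
        elif axis == "horizontal":
            if self.horizontal_move_s is not None:
                return self.horizontal_move_s
            speed = self.horizontal_speed_um_s
        else:
            raise ValueError(f"unknown move axis {axis!r}")
        return distance_mm * 1000.0 / speed + self.move_overhead_s


#: Timing with the beamline's published per-step averages.
PAPER_TIMING = TimingModel(
    scan_time_s=9.0,
    vertical_speed_um_s=550.0,
    horizontal_speed_um_s=220.0,
    move_overhead_s=3.0,
    calibration_time_s=0.0,
    vertical_move_s=8.0,
    horizontal_move_s=35.5,
)


@dataclass
class TilePose:
    grid_index: tuple[int, int, int]
    position_mm: tuple[float, float, float]
    order_index: int
    predicted_start_s: float = 0.0


@dataclass
class MosaicPlan:
    grid_shape: tuple[int, int, int]
    tile_extent_mm: tuple[float, float, float]
    step_mm: tuple[float, float]          # (horizontal_step, vertical_step)
    tiles: list[TilePose] = field(default_factory=list)
    pixel_size_um: float = 2.75

    @property
    def n_tiles(self) -> int:
        nx, ny, nz = self.grid_shape
        return nx * ny * nz

    @property
    def total_extent_mm(self) -> tuple[float, float, float]:
        """Physical bounding box of the mosaic (tile extents plus steps)."""
        nx, ny, nz = self.grid_shape
        h, v = self.step_mm
        w, l, t = self.tile_extent_mm
        return ((nx - 1) * h + w, (ny - 1) * h + l, (nz - 1) * v + t)

    def tiles_in_order(self) -> list[TilePose]:
        return sorted(self.tiles, key=lambda p: p.order_index)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MosaicPlan":
        d = json.loads(text)
        tiles = [TilePose(grid_index=tuple(t["grid_index"]),
                          position_mm=tuple(t["position_mm"]),
                          order_index=t["order_index"],
                          predicted_start_s=t["predicted_start_s"])
                 for t in d["tiles"]]
        return cls(grid_shape=tuple(d["grid_shape"]),
                   tile_extent_mm=tuple(d["tile_extent_mm"]),
                   step_mm=tuple(d["step_mm"]),
                   tiles=tiles,
                   pixel_size_um=d["pixel_size_um"])


def _zigzag_indices(nx: int, ny: int, nz: int) -> list[tuple[int, int, int]]:
    """Serpentine over the horizontal (i,j) plane, z fastest and zigzagged.

    Every consecutive pair of visited tiles is grid-adjacent, so each motion
    step is a single-axis translation to the nearest unmeasured tile.
    """
    order: list[tuple[int, int, int]] = []
    col = 0
    for i in range(nx):
        js = range(ny) if i % 2 == 0 else range(ny - 1, -1, -1)
        for j in js:
            ks = range(nz) if col % 2 == 0 else range(nz - 1, -1, -1)
            for k in ks:
                order.append((i, j, k))
            col += 1
    return order


def build_plan(grid_shape: tuple[int, int, int],
               tile_extent_mm: tuple[float, float, float],
               step_mm: tuple[float, float],
               pixel_size_um: float = 2.75,
               timing: TimingModel | None = None) -> MosaicPlan:
    """Lay out a mosaic of wide-field scans on a regular step lattice.

    Parameters
    ----------
    grid_shape : (nx, ny, nz) number of tiles along width, length, height.
    tile_extent_mm : physical size (w, l, h) of a single reconstructed tile.
    step_mm : (horizontal_step, vertical_step) centre-to-centre spacing;
        must not exceed the tile extent (tiles must overlap or abut).
    pixel_size_um : detector/voxel pixel size, used for pixel bookkeeping.
    timing : optional timing model used to fill each tile's predicted start
        time (defaults to the published per-step averages).
    """
    nx, ny, nz = grid_shape
    if min(nx, ny, nz) < 1:
        raise ValueError("grid dimensions must be >= 1")
    h, v = step_mm
    if h <= 0 or v <= 0:
        raise ValueError("steps must be > 0")
    w, l, t = tile_extent_mm
    if h > w or h > l or v > t:
        raise ValueError(
            "no overlap: step_mm exceeds tile extent "
            f"(horizontal {h} vs ({w},{l}), vertical {v} vs {t})")

    tiles = [TilePose(grid_index=(i, j, k),
                      position_mm=(i * h, j * h, k * v),
                      order_index=n)
             for n, (i, j, k) in enumerate(_zigzag_indices(nx, ny, nz))]
    plan = MosaicPlan(grid_shape=(nx, ny, nz),
                      tile_extent_mm=(w, l, t),
                      step_mm=(h, v),
                      tiles=tiles,
                      pixel_size_um=pixel_size_um)
    _, events = estimate_duration(plan, timing or PAPER_TIMING)
    starts = {e["order_index"]: e["t_start_s"] for e in events if e["kind"] == "scan"}
    for tile in plan.tiles:
        tile.predicted_start_s = starts[tile.order_index]
    return plan


def estimate_duration(plan: MosaicPlan,
                      timing: TimingModel) -> tuple[float, list[dict]]:
    """Predict total acquisition wall time and the per-event breakdown.

    The timeline is: one calibration block (darks + flats, recorded once
    before the mosaic), then alternating scan and single-axis move events
    following the plan's zigzag order.  Returns ``(total_s, events)`` where
    each event is a dict with ``kind`` ('calibration', 'scan', 'move'),
    ``t_start_s``, ``duration_s`` and, for moves, ``axis`` and
    ``distance_mm``; scans carry their ``order_index`` and ``grid_index``.
    """
    h, v = plan.step_mm
    t = 0.0
    events: list[dict] = []
    if timing.calibration_time_s > 0:
        events.append({"kind": "calibration", "t_start_s": t,
                       "duration_s": timing.calibration_time_s})
        t += timing.calibration_time_s
    prev = None
    for tile in plan.tiles_in_order():
        if prev is not None:
            diff = [a - b for a, b in zip(tile.grid_index, prev.grid_index)]
            moved = [ax for ax, d in enumerate(diff) if d != 0]
            if len(moved) != 1 or abs(diff[moved[0]]) != 1:
                raise ValueError(
                    f"plan order is not zigzag between {prev.grid_index} "
                    f"and {tile.grid_index}")
            axis = "vertical" if moved[0] == 2 else "horizontal"
            dist = v if axis == "vertical" else h
            dur = timing.move_duration_s(dist, axis)
            events.append({"kind": "move", "axis": axis, "distance_mm": dist,
                           "t_start_s": t, "duration_s": dur})
            t += dur
        events.append({"kind": "scan", "order_index": tile.order_index,
                       "grid_index": tile.grid_index,
                       "t_start_s": t, "duration_s": timing.scan_time_s})
        t += timing.scan_time_s
        prev = tile
    return t, events


def valid_regions(tile_diameter_px: float) -> tuple[int, float]:
    """Largest square and circular regions containing valid data.

    A tomographic reconstruction is only complete inside the circle swept by
    the detector; the largest inscribed square has side ``diameter / sqrt(2)``
    (floored to whole pixels).  Returns ``(square_side_px, circle_diameter_px)``.
    """
    if tile_diameter_px <= 0:
        raise ValueError("tile diameter must be > 0")
    return int(math.floor(tile_diameter_px / math.sqrt(2.0))), tile_diameter_px


def overlap_map(plan: MosaicPlan) -> dict[tuple[tuple[int, int, int], tuple[int, int, int]], dict]:
    """Per-adjacent-pair overlap extents in mm and pixels.

    For every pair of tiles whose grid indices differ by exactly 1 along a
    single axis, reports the shared region's bounding box in both tiles'
    local (mm) coordinates.  Both key orderings ``(a, b)`` and ``(b, a)`` are
    present and mirrored.  Pairs with zero overlap (step equal to the tile
    extent) are reported with ``overlap_mm == 0``; non-adjacent tiles have
    no entry.
    """
    h, v = plan.step_mm
    w, l, t = plan.tile_extent_mm
    extent = (w, l, t)
    step = (h, h, v)
    by_index = {tile.grid_index: tile for tile in plan.tiles}
    out: dict = {}
    axes_names = ("x", "y", "z")
    for a in plan.tiles:
        for ax in range(3):
            nb = list(a.grid_index)
            nb[ax] += 1
            b = by_index.get(tuple(nb))
            if b is None:
                continue
            ov_mm = extent[ax] - step[ax]
            if ov_mm < 0:
                continue
            ov_px = ov_mm * 1000.0 / plan.pixel_size_um
            # bounding box in each tile's local frame: full extent on the
            # other axes, the shared slab along the stepped axis.
            lo_a = [0.0, 0.0, 0.0]
            hi_a = list(extent)
            lo_b = [0.0, 0.0, 0.0]
            hi_b = list(extent)
            lo_a[ax] = extent[ax] - ov_mm   # far edge of tile a
            lo_b[ax] = 0.0
            hi_b[ax] = ov_mm
            info_ab = {"axis": axes_names[ax], "overlap_mm": ov_mm,
                       "overlap_px": ov_px,
                       "bbox_a_mm": (tuple(lo_a), tuple(hi_a)),
                       "bbox_b_mm": (tuple(lo_b), tuple(hi_b))}
            info_ba = {"axis": axes_names[ax], "overlap_mm": ov_mm,
                       "overlap_px": ov_px,
                       "bbox_a_mm": (tuple(lo_b), tuple(hi_b)),
                       "bbox_b_mm": (tuple(lo_a), tuple(hi_a))}
            out[(a.grid_index, b.grid_index)] = info_ab
            out[(b.grid_index, a.grid_index)] = info_ba
    return out
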