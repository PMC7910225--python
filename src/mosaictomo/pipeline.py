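"""End-to-end pipeline: simulate -> preprocess -> retrieve -> reconstruct ->
stitch -> segment.

Geometry bookkeeping (all in voxels of size ``plan.pixel_size_um``):

* each tile's *valid reconstruction circle* has diameter ``tile_diameter_vox``;
* the tile volume kept for stitching is the inscribed square
  (side ``floor(diameter / sqrt(2))``) over the full tile height;
* mosaic steps are square side (or height) minus ``overlap_vox``;
* the simulator cuts a cylindrical core of radius ``diameter/2 + margin``
  around each tile centre, so every projection is complete (no interior-
  tomography truncation) and neighbouring tiles see identical overlap
  structure.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from mosaictomo.config import PipelineConfig
from mosaictomo.flatfield import (fit_flat_basis, correct_dynamic,
                                  correct_static)
from mosaictomo.io import ProjectionSet, TileVolume
from mosaictomo.phantom import Phantom, make_foam_phantom
from mosaictomo.phase import OpticsConfig, paganin_retrieve
from mosaictomo.plan import MosaicPlan, TimingModel, build_plan
from mosaictomo.recon import find_center, reconstruct_extended_fov
from mosaictomo.sim import (DeformationModel, IlluminationModel,
                            simulate_mosaic)
from mosaictomo.stitch import (StitchResult, artifact_statistics,
                               blend_mosaic, block_match_field,
                               coarse_pairwise_shift, filter_and_smooth_field,
                               globally_position_tiles, DisplacementField)
from mosaictomo.segment import SegmentationResult, segment_airways

__all__ = ["PipelineResult", "run_pipeline", "make_plan_from_config",
           "make_phantom_for_plan", "preprocess_projection_set",
           "reconstruct_tile", "stitch_tiles"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    plan: MosaicPlan
    phantom: Phantom
    tiles: list[TileVolume]
    stitched: StitchResult
    segmentation: SegmentationResult
    report: dict = field(default_factory=dict)


def make_timing(cfg: PipelineConfig) -> TimingModel:
    p = cfg.plan
    return TimingModel(scan_time_s=p.scan_time_s,
                       vertical_speed_um_s=p.vertical_speed_um_s,
                       horizontal_speed_um_s=p.horizontal_speed_um_s,
                       move_overhead_s=p.move_overhead_s,
                       calibration_time_s=p.calibration_time_s)


def make_plan_from_config(cfg: PipelineConfig) -> tuple[MosaicPlan, dict]:
    p = cfg.plan
    vox_mm = p.pixel_size_um * 1e-3
    square = int(math.floor(p.tile_diameter_vox / math.sqrt(2.0)))
    if p.overlap_vox >= square or p.overlap_vox >= p.tile_height_vox:
        raise ValueError("overlap larger than the tile's valid extent")
    step_h = (square - p.overlap_vox) * vox_mm
    step_v = (p.tile_height_vox - p.overlap_vox) * vox_mm
    extent = (square * vox_mm, square * vox_mm, p.tile_height_vox * vox_mm)
    plan = build_plan(p.grid_shape, extent, (step_h, step_v),
                      pixel_size_um=p.pixel_size_um, timing=make_timing(cfg))
    derived = {"square_vox": square,
               "fov_diameter_mm": p.tile_diameter_vox * vox_mm,
               "step_h_vox": square - p.overlap_vox,
               "step_v_vox": p.tile_height_vox - p.overlap_vox}
    return plan, derived


def make_phantom_for_plan(cfg: PipelineConfig, plan: MosaicPlan,
                          pad_vox: int = 3) -> Phantom:
    """Foam phantom just covering every tile's scanned core."""
    p, s = cfg.plan, cfg.sim
    vox_mm = p.pixel_size_um * 1e-3
    r_blk = p.tile_diameter_vox / 2.0 + s.margin_px
    poses = np.array([t.position_mm for t in plan.tiles])   # (n, 3) x,y,z
    lo_mm = poses.min(axis=0)
    hi_mm = poses.max(axis=0)
    lo = lo_mm - np.array([r_blk, r_blk, p.tile_height_vox / 2.0]) * vox_mm \
        - pad_vox * vox_mm
    hi = hi_mm + np.array([r_blk, r_blk, p.tile_height_vox / 2.0]) * vox_mm \
        + pad_vox * vox_mm
    shape_xyz = np.ceil((hi - lo) / vox_mm).astype(int) + 1
    shape = (int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0]))  # z,y,x
    # scale tissue attenuation so the body diameter has beamline-like
    # optical depth (desk-scale phantoms would otherwise be transparent)
    body_diam_m = 0.92 * min(shape[1], shape[2]) * vox_mm * 1e-3
    mu_tissue = s.body_optical_depth / body_diam_m
    ph = make_foam_phantom(shape, voxel_size_um=p.pixel_size_um,
                           target_air_fraction=s.target_air_fraction,
                           wall_thickness_um=s.wall_thickness_um,
                           seed=cfg.seed, mu_tissue=mu_tissue)
    ph.origin_mm = (float(lo[0]), float(lo[1]), float(lo[2]))
    return ph


def preprocess_projection_set(pset: ProjectionSet, optics: OpticsConfig,
                              n_components: int = 5, margin_cols: int = 10,
                              dynamic: bool = True) -> np.ndarray:
    """Dark/flat-correct and phase-retrieve a projection set to mu*T."""
    dark_mean = pset.darks.mean(axis=0)
    K = min(n_components, pset.flats.shape[0] - 1)
    model = fit_flat_basis(pset.flats, dark_mean, K=K)
    # sample-free pixels: the outer wide-side columns (beyond the scanned
    # core) stay at unit transmission in half-acquisition geometry
    bg = np.zeros(pset.detector_shape, dtype=bool)
    bg[:, -margin_cols:] = True
    out = np.empty(pset.data.shape, dtype=np.float64)
    for i in range(pset.n_proj):
        if dynamic and K > 0:
            frame, _ = correct_dynamic(pset.data[i], model,
                                       background_region=bg)
        else:
            frame = correct_static(pset.data[i], model)
        _, muT = paganin_retrieve(frame, optics)
        out[i] = muT
    return out


def reconstruct_tile(muT: np.ndarray, pset: ProjectionSet,
                     cfg: PipelineConfig, square_vox: int,
                     plan: MosaicPlan) -> TileVolume:
    """Extended-FOV reconstruction of one tile, cropped to the valid square."""
    r = cfg.recon
    center = float(pset.axis_offset_px)
    if r.find_centers:
        hw, st = r.center_search_halfwidth_px, r.center_search_step_px
        center, _ = find_center(muT, None,
                                (center - hw, center + hw), st,
                                extended=True, eps_deg=r.eps_deg)
    vol = reconstruct_extended_fov(muT, center, eps_deg=r.eps_deg,
                                   overlap_mode=r.overlap_mode,
                                   filter_name=r.filter_name,
                                   pixel_size_um=pset.pixel_size_um)
    D = vol.shape[-1]
    c0 = (D - square_vox) // 2
    vol = vol[:, c0:c0 + square_vox, c0:c0 + square_vox]
    pose = next(t for t in plan.tiles if t.grid_index == pset.grid_index)
    vox_mm = pset.pixel_size_um * 1e-3
    nz = vol.shape[0]
    origin_mm = (pose.position_mm[0] - (square_vox - 1) / 2.0 * vox_mm,
                 pose.position_mm[1] - (square_vox - 1) / 2.0 * vox_mm,
                 pose.position_mm[2] - (nz - 1) / 2.0 * vox_mm)
    return TileVolume(volume=vol.astype(np.float32),
                      voxel_size_um=pset.pixel_size_um,
                      origin_mm=origin_mm, grid_index=pset.grid_index,
                      timestamp_s=pset.timestamp_s,
                      meta={"center_px": center, "eps_deg": r.eps_deg,
                            "overlap_mode": r.overlap_mode})


def _grid_neighbors(tiles: list[TileVolume]):
    by_index = {t.grid_index: k for k, t in enumerate(tiles)}
    pairs = []
    for gi, a in by_index.items():
        for ax in range(3):
            nb = list(gi)
            nb[ax] += 1
            b = by_index.get(tuple(nb))
            if b is not None:
                pairs.append((a, b))
    return pairs


def stitch_tiles(tiles: list[TileVolume], cfg: PipelineConfig,
                 non_rigid: bool = True,
                 std_threshold: float | None = None) -> StitchResult:
    """Pairwise registration, global positioning and blending of tiles."""
    s = cfg.stitch
    if std_threshold is None:
        # artifact definition relative to typical tissue grey level
        std_threshold = s.std_threshold_frac * float(
            np.percentile(np.abs(tiles[0].volume), 90))
    vox_mm = tiles[0].voxel_size_um * 1e-3
    origins_mm = np.array([[t.origin_mm[2], t.origin_mm[1], t.origin_mm[0]]
                           for t in tiles])   # (z, y, x)
    lo_mm = origins_mm.min(axis=0)
    nominal = (origins_mm - lo_mm) / vox_mm

    pairwise = {}
    pair_fields: list[tuple[int, int, np.ndarray, DisplacementField]] = []
    pair_report = []
    for a, b in _grid_neighbors(tiles):
        # reference = earlier acquisition; deformation grows with time
        if tiles[b].timestamp_s < tiles[a].timestamp_s:
            a, b = b, a
        off_nominal = nominal[b] - nominal[a]
        try:
            ps = coarse_pairwise_shift(
                tiles[a].volume, tiles[b].volume, off_nominal,
                search_radius_vox=s.max_displacement_vox)
        except ValueError as exc:
            log.warning("pair (%s, %s): %s", a, b, exc)
            continue
        refined, score, low_conf = ps.offset_vox, ps.score, ps.low_confidence
        pairwise[(a, b)] = (refined, 0.01 if low_conf else max(score, 0.01))
        entry = {"a": tiles[a].grid_index, "b": tiles[b].grid_index,
                 "offset": refined.tolist(), "score": score,
                 "low_confidence": low_conf}
        if non_rigid:
            df = block_match_field(tiles[a].volume, tiles[b].volume, refined,
                                   grid_spacing_vox=s.grid_spacing_vox,
                                   block_radius_vox=s.block_radius_vox,
                                   search_radius_vox=s.search_radius_vox,
                                   score_threshold=s.score_threshold,
                                   max_displacement_vox=s.max_displacement_vox)
            raw_valid = int(df.valid.sum())
            df = filter_and_smooth_field(df)
            # the rigid (mean) part of the pair's motion is measured more
            # accurately by phase correlation and already lives in the
            # offset; keep only the nonuniform residual as the warp
            if df.valid.any():
                df.shifts = df.shifts - df.shifts[df.valid].mean(axis=0)
            pair_fields.append((a, b, refined, df))
            entry["n_valid_points"] = raw_valid
        pair_report.append(entry)

    origins = globally_position_tiles(len(tiles), pairwise, nominal)
    # Fields were measured against the pairwise offsets; re-reference them
    # to the globally adjusted origins so cycle-closure residuals do not
    # leak into the warp.  Each field is additionally composed with the
    # reference tile's own accumulated warp (tiles processed in acquisition
    # order), so every tile is pulled toward the frame of the earliest
    # anchor rather than toward mutually inconsistent deformed references.
    fields: dict[int, DisplacementField] = {}
    order = np.argsort([t.timestamp_s for t in tiles])
    rank = {int(t): k for k, t in enumerate(order)}
    pair_fields.sort(key=lambda item: rank[item[1]])
    for a, b, pair_offset, df in pair_fields:
        delta = (origins[b] - origins[a]) - pair_offset
        shifts = df.shifts + delta
        if a in fields:
            shifts = shifts + fields[a].interpolate(
                df.points, sigma_vox=s.field_sigma_vox)
        off_global = origins[b] - origins[a]
        piece = DisplacementField(points=df.points - off_global,
                                  shifts=shifts, valid=df.valid,
                                  scores=df.scores,
                                  rigid_offset=np.zeros(3))
        if b in fields:
            prev = fields[b]
            piece = DisplacementField(
                points=np.concatenate([prev.points, piece.points]),
                shifts=np.concatenate([prev.shifts, piece.shifts]),
                valid=np.concatenate([prev.valid, piece.valid]),
                scores=np.concatenate([prev.scores, piece.scores]),
                rigid_offset=np.zeros(3))
        fields[b] = piece
    result = blend_mosaic([t.volume for t in tiles], origins,
                          fields=fields if non_rigid else None,
                          voxel_size_um=tiles[0].voxel_size_um,
                          ramp_vox=s.ramp_vox,
                          field_sigma_vox=s.field_sigma_vox)
    frac, per_slice, max_frac = artifact_statistics(
        result.std_map, std_threshold, result.overlap_mask)
    result.report.update({
        "pairs": pair_report,
        "origins_vox": origins.tolist(),
        "artifact_fraction": frac,
        "artifact_max_slice_fraction": max_frac,
        "mosaic_origin_mm": [float(lo_mm[2]), float(lo_mm[1]),
                             float(lo_mm[0])],  # x, y, z
    })
    return result


def run_pipeline(cfg: PipelineConfig,
                 phantom: Phantom | None = None) -> PipelineResult:
    """Run the whole chain on a synthetic mosaic acquisition.

    Deterministic given ``cfg.seed``; per-stage wall times, registration
    residuals, artifact statistics and the ground-truth comparison are
    collected in the result's report.
    """
    report: dict = {"config_hash": cfg.config_hash(), "timings_s": {}}
    t0 = time.perf_counter()

    plan, derived = make_plan_from_config(cfg)
    if phantom is None:
        phantom = make_phantom_for_plan(cfg, plan)
    report["phantom"] = dict(phantom.meta)
    report["ground_truth_air_mm3"] = phantom.air_volume_mm3
    report["timings_s"]["plan+phantom"] = time.perf_counter() - t0

    s = cfg.sim
    optics = OpticsConfig(energy_keV=cfg.optics.energy_keV,
                          propagation_distance_m=cfg.optics.propagation_distance_m,
                          pixel_size_um=cfg.plan.pixel_size_um,
                          delta=cfg.optics.delta, beta=cfg.optics.beta)
    deform = (DeformationModel(rate_vox_per_s=s.deform_rate_vox_per_s,
                               seed=cfg.seed + 1)
              if s.deform_rate_vox_per_s > 0 else None)
    t1 = time.perf_counter()
    # detector: narrow margin + axis + scanned-core radius + clear margin
    r_blk = int(math.ceil(cfg.plan.tile_diameter_vox / 2.0)) + s.margin_px
    det_width = s.axis_offset_px + r_blk + 24
    illum = IlluminationModel.make(
        (cfg.plan.tile_height_vox, det_width), n_components=s.drift_components,
        mean_counts=s.mean_counts, drift_amplitude=s.drift_amplitude,
        seed=cfg.seed + 2) if s.noise else None
    psets = simulate_mosaic(phantom, plan, optics, illum, deform,
                            n_proj=s.n_proj, seed=cfg.seed + 3,
                            eps_deg=s.eps_deg,
                            axis_offset_px=s.axis_offset_px,
                            detector_width_px=det_width,
                            margin_px=s.margin_px, noise=s.noise,
                            source_blur_px=s.source_blur_px,
                            n_darks=s.n_darks, n_flats=s.n_flats,
                            fov_mask=True)
    report["timings_s"]["simulate"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    tiles = []
    for pset in psets:
        muT = preprocess_projection_set(
            pset, optics, n_components=cfg.preprocess.n_components,
            margin_cols=cfg.preprocess.margin_cols,
            dynamic=cfg.preprocess.dynamic)
        tiles.append(reconstruct_tile(muT, pset, cfg,
                                      derived["square_vox"], plan))
    report["timings_s"]["preprocess+reconstruct"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    stitched = stitch_tiles(
        tiles, cfg,
        std_threshold=cfg.stitch.std_threshold_frac * phantom.mu_tissue)
    report["timings_s"]["stitch"] = time.perf_counter() - t3
    report["artifact_fraction"] = stitched.report["artifact_fraction"]

    t4 = time.perf_counter()
    seg = segment_airways(stitched.fused, tiles[0].voxel_size_um,
                          bone_threshold=(cfg.segment.bone_threshold_factor
                                          * phantom.mu_tissue),
                          cylinder_mask=cfg.segment.cylinder,
                          dilation_radius=cfg.segment.dilation_radius,
                          sharpness_amount=cfg.segment.sharpness_amount,
                          invalid_mask=(stitched.provenance == 255))
    report["timings_s"]["segment"] = time.perf_counter() - t4
    report["airway_volume_cm3"] = seg.volume_cm3
    report["airway_volume_mm3"] = seg.volume_cm3 * 1e3
    gt = phantom.air_volume_mm3
    if gt > 0:
        report["airway_volume_rel_err"] = abs(seg.volume_cm3 * 1e3 - gt) / gt
    report["timings_s"]["total"] = time.perf_counter() - t0
    return PipelineResult(plan=plan, phantom=phantom, tiles=tiles,
                          stitched=stitched, segmentation=seg, report=report)
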