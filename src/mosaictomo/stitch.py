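"""Non-rigid stitching of reconstructed tile volumes.

Neighbouring tiles are acquired minutes apart while the sample slowly
deforms, so a rigid alignment leaves residual structural mismatch in the
overlaps.  The pipeline here is: phase-correlation refinement of each
adjacent pair's nominal offset, local block matching (normalized
cross-correlation) on a control-point grid to measure a smooth displacement
field, outlier rejection and Gaussian smoothing of that field,
least-squares-consistent global tile positioning, and weighted blending into
one fused volume with a per-voxel standard-deviation map of overlapping
values (high std flags stitching mismatch).

All tile arrays are indexed ``[z, y, x]``; origins are voxel coordinates in
the common mosaic frame.  Pairwise fields deform the later-acquired tile of
each pair relative to the earlier one (mismatch grows with time separation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation

__all__ = [
    "DisplacementField", "StitchResult", "PairShift",
    "coarse_pairwise_shift", "block_match_field", "filter_and_smooth_field",
    "globally_position_tiles", "blend_mosaic", "artifact_statistics",
]


@dataclass
class DisplacementField:
    """Local shifts measured on a control-point grid in the reference tile.

    ``shifts[i]`` refines the rigid offset at ``points[i]`` (reference-tile
    voxel coordinates): the moving tile matches the reference at
    ``points[i] - rigid_offset + shifts[i]`` in its own frame.
    """

    points: np.ndarray              # (N, 3) voxel coords in reference tile
    shifts: np.ndarray              # (N, 3)
    valid: np.ndarray               # (N,) bool
    scores: np.ndarray              # (N,) NCC at the chosen shift
    rigid_offset: np.ndarray        # (3,) moving-origin minus reference-origin
    grid_shape: tuple[int, ...] = ()
    meta: dict = field(default_factory=dict)

    def interpolate(self, coords: np.ndarray, sigma_vox: float = 24.0,
                    prior_weight: float = 0.05) -> np.ndarray:
        """Gaussian-weighted interpolation of the valid shifts at ``coords``.

        ``coords`` is (M, 3) in the reference frame.  A small constant prior
        weight pulls the field to zero far from any valid control point, so
        the warp fades out away from the measured overlap.
        """
        out = np.zeros((coords.shape[0], 3))
        if not self.valid.any():
            return out
        pts = self.points[self.valid]
        sh = self.shifts[self.valid]
        d2 = ((coords[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-0.5 * d2 / sigma_vox ** 2)
        wsum = w.sum(axis=1) + prior_weight
        out = (w @ sh) / wsum[:, None]
        return out


@dataclass
class StitchResult:
    fused: np.ndarray               # (nz, ny, nx)
    std_map: np.ndarray             # same shape, 0 outside overlaps
    overlap_mask: np.ndarray        # bool, >= 2 tiles contribute
    provenance: np.ndarray          # uint8 tile id with max weight (255=none)
    voxel_size_um: float = 1.0
    origin_vox: np.ndarray = field(default_factory=lambda: np.zeros(3))
    report: dict = field(default_factory=dict)


def _overlap_slices(shape_a, shape_b, offset):
    """Integer overlap boxes of two arrays when b's origin sits at ``offset``
    in a's frame.  Returns (slices_a, slices_b) or None."""
    sl_a, sl_b = [], []
    for ax in range(3):
        o = int(round(offset[ax]))
        a0 = max(0, o)
        a1 = min(shape_a[ax], o + shape_b[ax])
        if a1 - a0 < 1:
            return None
        sl_a.append(slice(a0, a1))
        sl_b.append(slice(a0 - o, a1 - o))
    return tuple(sl_a), tuple(sl_b)


@dataclass
class PairShift:
    """Refined rigid registration of one tile pair."""

    offset_vox: np.ndarray          # b's origin in a's frame, refined
    content_shift_vox: np.ndarray   # translation of b's content relative to a
    score: float                    # NCC of the aligned overlaps
    low_confidence: bool


def coarse_pairwise_shift(tile_a: np.ndarray, tile_b: np.ndarray,
                          nominal_offset_vox,
                          search_radius_vox: float = 10.0,
                          min_overlap_vox: int = 64,
                          score_threshold: float = 0.1,
                          upsample: int = 10) -> PairShift:
    """Refine a pair's nominal rigid offset by phase correlation.

    ``nominal_offset_vox`` is tile b's origin in tile a's frame.  The phase-
    correlation peak of the nominally-aligned overlaps gives the sub-voxel
    translation of b's content relative to a (``content_shift_vox``); the
    refined origin offset is ``nominal - content_shift`` (content shifted by
    +s means the tile must be placed at -s to align).  If the correlation is
    below ``score_threshold`` (e.g. pure noise), the nominal offset is kept
    and the pair flagged low-confidence.
    """
    nominal = np.asarray(nominal_offset_vox, dtype=np.float64)
    ov = _overlap_slices(tile_a.shape, tile_b.shape, nominal)
    if ov is None:
        raise ValueError("tiles do not overlap at the nominal offset")
    sl_a, sl_b = ov
    wa = np.asarray(tile_a[sl_a], dtype=np.float64)
    wb = np.asarray(tile_b[sl_b], dtype=np.float64)
    if wa.size < min_overlap_vox:
        raise ValueError(
            f"overlap of {wa.size} voxels below minimum {min_overlap_vox}")
    resid, _, _ = phase_cross_correlation(wa, wb, upsample_factor=upsample,
                                          normalization=None)
    resid = np.asarray(resid, dtype=np.float64)
    if np.any(np.abs(resid) > search_radius_vox):
        resid = np.clip(resid, -search_radius_vox, search_radius_vox)
    refined = nominal + resid
    content_shift = -resid
    score = _ncc_at(tile_a, tile_b, refined)
    low_conf = score < score_threshold
    if low_conf:
        warnings.warn("phase correlation low confidence; keeping nominal "
                      f"offset (score {score:.3f})")
        refined = nominal
        content_shift = np.zeros(3)
        score = _ncc_at(tile_a, tile_b, refined)
    return PairShift(offset_vox=refined, content_shift_vox=content_shift,
                     score=float(score), low_confidence=bool(low_conf))


def _ncc_at(tile_a, tile_b, offset) -> float:
    ov = _overlap_slices(tile_a.shape, tile_b.shape, offset)
    if ov is None:
        return -1.0
    a = np.asarray(tile_a[ov[0]], dtype=np.float64).ravel()
    b = np.asarray(tile_b[ov[1]], dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom < 1e-12:
        return 0.0
    return float((a @ b) / denom)


def _parabolic_offset(vals: np.ndarray, axis_idx: tuple[int, ...]) -> np.ndarray:
    """Per-axis parabolic peak refinement of an nD correlation maximum."""
    out = np.zeros(len(axis_idx))
    for ax, k in enumerate(axis_idx):
        if 0 < k < vals.shape[ax] - 1:
            idx = list(axis_idx)
            idx[ax] = k - 1
            y0 = vals[tuple(idx)]
            idx[ax] = k
            y1 = vals[tuple(idx)]
            idx[ax] = k + 1
            y2 = vals[tuple(idx)]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                out[ax] = float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
    return out


def block_match_field(tile_a: np.ndarray, tile_b: np.ndarray,
                      rigid_shift,
                      grid_spacing_vox: int = 32,
                      block_radius_vox: int = 12,
                      search_radius_vox: int = 6,
                      score_threshold: float = 0.5,
                      max_displacement_vox: float = 10.0,
                      prominence_min: float = 0.02) -> DisplacementField:
    """Local displacement field between a tile pair by NCC block matching.

    For each control point on a regular grid inside the overlap (reference
    tile a's frame), a block of half-size ``block_radius_vox`` is matched
    against tile b in a window of ``search_radius_vox`` around the rigid
    alignment; the NCC peak (with parabolic sub-voxel refinement) gives the
    local shift.  Points with peak score below ``score_threshold`` or
    displacement above ``max_displacement_vox`` are flagged invalid.
    """
    rigid = np.asarray(rigid_shift, dtype=np.float64)
    ov = _overlap_slices(tile_a.shape, tile_b.shape, rigid)
    if ov is None:
        raise ValueError("tiles do not overlap at the rigid offset")
    sl_a, _ = ov
    global_std = float(np.asarray(tile_a).std()) + 1e-12
    br, sr = int(block_radius_vox), int(search_radius_vox)
    pts, shifts, valid, scores = [], [], [], []
    grid_axes = []
    for ax in range(3):
        # control points must leave room for the block in the reference
        # tile and the search window in the moving tile
        lo = max(sl_a[ax].start, br,
                 int(np.ceil(rigid[ax])) + br + sr)
        hi = min(sl_a[ax].stop - 1, tile_a.shape[ax] - br - 1,
                 int(np.floor(rigid[ax] + tile_b.shape[ax] - 1)) - br - sr)
        if hi < lo:
            mid = (sl_a[ax].start + sl_a[ax].stop) // 2
            grid_axes.append(np.array([mid]))
            continue
        n = max(1, int((hi - lo) // grid_spacing_vox) + 1)
        grid_axes.append(np.unique(np.linspace(lo, hi, n).round()
                                   .astype(int)))
    any_valid = False
    for pz in grid_axes[0]:
        for py in grid_axes[1]:
            for px in grid_axes[2]:
                p = np.array([pz, py, px], dtype=np.float64)
                blk_sl = tuple(slice(int(c) - br, int(c) + br + 1) for c in p)
                if any(s.start < 0 or s.stop > tile_a.shape[ax]
                       for ax, s in enumerate(blk_sl)):
                    pts.append(p)
                    shifts.append(np.zeros(3))
                    valid.append(False)
                    scores.append(0.0)
                    continue
                block = tile_a[blk_sl]
                q0 = p - rigid                       # b-frame match position
                win_sl = []
                bad = False
                for ax in range(3):
                    lo = int(round(q0[ax])) - br - sr
                    hi = int(round(q0[ax])) + br + sr + 1
                    # a clipped window would bias the match toward the
                    # reachable side; such points are left invalid instead
                    if lo < 0 or hi > tile_b.shape[ax]:
                        bad = True
                        break
                    win_sl.append(slice(lo, hi))
                if bad or block.std() < 0.05 * global_std:
                    pts.append(p)
                    shifts.append(np.zeros(3))
                    valid.append(False)
                    scores.append(0.0)
                    continue
                window = tile_b[tuple(win_sl)]
                ncc = match_template(np.ascontiguousarray(window, np.float64),
                                     np.ascontiguousarray(block, np.float64))
                k = np.unravel_index(np.argmax(ncc), ncc.shape)
                sub = _parabolic_offset(ncc, k)
                found = np.array([win_sl[ax].start + k[ax] + sub[ax] + br
                                  for ax in range(3)])
                d = found - q0
                score = float(ncc[k])
                # peak prominence: near-constant or self-similar blocks
                # produce multiple equal peaks and cannot be trusted
                masked = ncc.copy()
                nb = tuple(slice(max(0, k[ax] - 1),
                                 min(ncc.shape[ax], k[ax] + 2))
                           for ax in range(3))
                masked[nb] = -np.inf
                second = float(masked.max()) if np.isfinite(masked).any() \
                    else -np.inf
                prominent = score - second >= prominence_min
                # scores outside [-1, 1] arise from near-constant windows
                ok = (np.isfinite(score) and prominent
                      and score_threshold <= score <= 1.0001
                      and np.linalg.norm(d) <= max_displacement_vox)
                pts.append(p)
                shifts.append(d)
                valid.append(bool(ok))
                scores.append(score)
                any_valid = any_valid or ok
    if not any_valid:
        warnings.warn("block matching produced no valid control points")
    return DisplacementField(points=np.array(pts),
                             shifts=np.array(shifts),
                             valid=np.array(valid, dtype=bool),
                             scores=np.array(scores),
                             rigid_offset=rigid,
                             grid_shape=tuple(len(g) for g in grid_axes))


def filter_and_smooth_field(df: DisplacementField,
                            mad_factor: float = 5.0,
                            smooth_sigma_vox: float = 16.0) -> DisplacementField:
    """Reject outlier control points and smooth the field.

    Outliers are flagged per component by the robust rule
    ``|d - median| > mad_factor * MAD`` (computed over currently-valid
    points); each point's shift — including rejected and previously invalid
    points — is then replaced by Gaussian-weighted interpolation over the
    surviving points, which fills gaps and bounds the field's gradient.
    An all-invalid field is returned as the identity with a warning.
    """
    shifts = df.shifts.copy()
    valid = df.valid.copy()
    if valid.any():
        sel = shifts[valid]
        med = np.median(sel, axis=0)
        mad = np.median(np.abs(sel - med), axis=0)
        lim = mad_factor * np.maximum(mad, 1e-6)
        ok = np.all(np.abs(shifts - med) <= lim, axis=1)
        valid &= ok
    if not valid.any():
        warnings.warn("all control points invalid; returning identity field")
        return DisplacementField(points=df.points,
                                 shifts=np.zeros_like(df.shifts),
                                 valid=np.zeros(len(df.points), dtype=bool),
                                 scores=df.scores,
                                 rigid_offset=df.rigid_offset,
                                 grid_shape=df.grid_shape,
                                 meta={**df.meta, "identity": True})
    pts = df.points[valid]
    sel = shifts[valid]
    d2 = ((df.points[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-0.5 * d2 / smooth_sigma_vox ** 2)
    wsum = w.sum(axis=1)
    smoothed = (w @ sel) / wsum[:, None]
    return DisplacementField(points=df.points, shifts=smoothed,
                             valid=np.ones(len(df.points), dtype=bool),
                             scores=df.scores, rigid_offset=df.rigid_offset,
                             grid_shape=df.grid_shape,
                             meta={**df.meta, "smoothed": True,
                                   "n_rejected": int(df.valid.sum() - valid.sum())})


def globally_position_tiles(n_tiles: int,
                            pairwise: dict[tuple[int, int], tuple[np.ndarray, float]],
                            nominal_origins: np.ndarray) -> np.ndarray:
    """Least-squares-consistent absolute tile origins from pairwise offsets.

    ``pairwise[(a, b)] = (offset_ab, confidence)`` states that tile b's
    origin minus tile a's origin should equal ``offset_ab``.  Minimizes
    ``sum conf * |o_b - o_a - offset_ab|^2`` with tile 0 anchored at its
    nominal origin; disconnected components are anchored at their nominal
    origins with a warning.
    """
    nominal = np.asarray(nominal_origins, dtype=np.float64)
    # connected components of the measurement graph
    adj = [[] for _ in range(n_tiles)]
    for (a, b) in pairwise:
        adj[a].append(b)
        adj[b].append(a)
    comp_id = -np.ones(n_tiles, dtype=int)
    n_comp = 0
    for s in range(n_tiles):
        if comp_id[s] >= 0:
            continue
        stack = [s]
        comp_id[s] = n_comp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp_id[v] < 0:
                    comp_id[v] = n_comp
                    stack.append(v)
        n_comp += 1
    if n_comp > 1:
        warnings.warn(f"tile graph has {n_comp} components; anchoring each "
                      "at its nominal origin")
    origins = nominal.copy()
    for comp in range(n_comp):
        nodes = np.flatnonzero(comp_id == comp)
        if nodes.size == 1:
            continue
        idx = {t: i for i, t in enumerate(nodes)}
        anchor = nodes[0]
        m = nodes.size
        A_rows, b_rows, w_rows = [], [], []
        for (a, b), (off, conf) in pairwise.items():
            if comp_id[a] != comp:
                continue
            row = np.zeros(m)
            row[idx[b]] = 1.0
            row[idx[a]] = -1.0
            A_rows.append(row)
            b_rows.append(np.asarray(off, dtype=np.float64))
            w_rows.append(max(conf, 1e-6))
        # anchor
        row = np.zeros(m)
        row[idx[anchor]] = 1.0
        A_rows.append(row)
        b_rows.append(nominal[anchor])
        w_rows.append(1e6)
        A = np.array(A_rows)
        B = np.array(b_rows)
        W = np.sqrt(np.array(w_rows))[:, None]
        sol, *_ = np.linalg.lstsq(A * W, B * W, rcond=None)
        origins[nodes] = sol
    return origins


def blend_mosaic(tiles: list[np.ndarray],
                 origins: np.ndarray,
                 fields: dict[int, DisplacementField] | None = None,
                 voxel_size_um: float = 1.0,
                 ramp_vox: float = 8.0,
                 field_sigma_vox: float = 24.0,
                 fill_value: float = 0.0,
                 chunk_z: int = 32) -> StitchResult:
    """Fuse warped tiles into one volume with an overlap std map.

    Parameters
    ----------
    tiles : list of (nz, ny, nx) arrays, identical voxel size.
    origins : (n_tiles, 3) float voxel origins in the mosaic frame.
    fields : optional per-tile displacement fields (``fields[t]`` warps tile
        t, the later-acquired member of its pair(s); control points are
        stored in the reference tile's frame and converted here).  Tiles
        without an entry are used rigidly.
    ramp_vox : width of the linear weight ramp falling to zero at each tile
        border, giving seamless weighted averaging in overlaps.

    The per-voxel std map uses the population convention over the
    contributing warped values (two tiles differing by d give d/2) and is
    zero where fewer than two tiles contribute.  Voxels covered by no tile
    get ``fill_value`` and provenance id 255.
    """
    n_tiles = len(tiles)
    origins = np.asarray(origins, dtype=np.float64)
    lo = np.floor(origins.min(axis=0)).astype(int)
    hi = np.ceil(origins + [t.shape for t in tiles]).max(axis=0).astype(int)
    out_shape = tuple((hi - lo).astype(int))
    fused = np.zeros(out_shape, dtype=np.float64)
    wsum = np.zeros(out_shape, dtype=np.float64)
    vsum = np.zeros(out_shape, dtype=np.float64)
    v2sum = np.zeros(out_shape, dtype=np.float64)
    count = np.zeros(out_shape, dtype=np.int16)
    wmax = np.zeros(out_shape, dtype=np.float64)
    prov = np.full(out_shape, 255, dtype=np.uint8)

    for t, tile in enumerate(tiles):
        shape = np.array(tile.shape)
        o = origins[t] - lo
        # output bounding box this tile can touch
        g0 = np.maximum(np.floor(o).astype(int), 0)
        g1 = np.minimum(np.ceil(o + shape).astype(int), out_shape)
        if np.any(g1 <= g0):
            continue
        # per-axis ramp weight in tile-local coordinates
        def _ramp(n):
            c = np.arange(n, dtype=np.float64)
            return np.minimum(1.0, (np.minimum(c, n - 1 - c) + 0.5) / ramp_vox)
        for z0 in range(g0[0], g1[0], chunk_z):
            z1 = min(z0 + chunk_z, g1[0])
            zz, yy, xx = np.meshgrid(np.arange(z0, z1),
                                     np.arange(g0[1], g1[1]),
                                     np.arange(g0[2], g1[2]), indexing="ij")
            local = np.stack([zz - o[0], yy - o[1], xx - o[2]]).astype(np.float64)
            if fields is not None and t in fields:
                df = fields[t]
                ref_coords = (local + df.rigid_offset[:, None, None, None]
                              ).reshape(3, -1).T
                d = df.interpolate(ref_coords, sigma_vox=field_sigma_vox)
                local = local + d.T.reshape(local.shape)
            vals = ndimage.map_coordinates(tile, local, order=1,
                                           mode="constant", cval=np.nan)
            inside = np.isfinite(vals)
            wz = np.interp(local[0], np.arange(shape[0]), _ramp(shape[0]),
                           left=0, right=0)
            wy = np.interp(local[1], np.arange(shape[1]), _ramp(shape[1]),
                           left=0, right=0)
            wx = np.interp(local[2], np.arange(shape[2]), _ramp(shape[2]),
                           left=0, right=0)
            w = wz * wy * wx
            w[~inside] = 0.0
            vals = np.where(inside, vals, 0.0)
            sl = (slice(z0, z1), slice(g0[1], g1[1]), slice(g0[2], g1[2]))
            fused[sl] += w * vals
            wsum[sl] += w
            contrib = w > 1e-9
            vsum[sl] += np.where(contrib, vals, 0.0)
            v2sum[sl] += np.where(contrib, vals ** 2, 0.0)
            count[sl] += contrib
            better = w > wmax[sl]
            wmax[sl] = np.where(better, w, wmax[sl])
            prov_sl = prov[sl]
            prov_sl[better] = t
            prov[sl] = prov_sl

    covered = wsum > 1e-9
    fused = np.where(covered, fused / np.maximum(wsum, 1e-12), fill_value)
    overlap = count >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_v = vsum / np.maximum(count, 1)
        var = v2sum / np.maximum(count, 1) - mean_v ** 2
    std = np.where(overlap, np.sqrt(np.maximum(var, 0.0)), 0.0)
    report = {"n_tiles": n_tiles,
              "uncovered_voxels": int(np.count_nonzero(~covered)),
              "overlap_voxels": int(np.count_nonzero(overlap))}
    return StitchResult(fused=fused.astype(np.float32),
                        std_map=std.astype(np.float32),
                        overlap_mask=overlap, provenance=prov,
                        voxel_size_um=voxel_size_um,
                        origin_vox=lo.astype(np.float64), report=report)


def artifact_statistics(std_map: np.ndarray, threshold: float,
                        overlap_mask: np.ndarray | None = None
                        ) -> tuple[float, np.ndarray, float]:
    """Volume fraction of mismatch artifacts in the overlap regions.

    Returns ``(global_fraction, per_slice_fraction, max_slice_fraction)``
    where fractions count voxels with ``std > threshold`` relative to the
    overlap voxels (or all voxels if no mask is given); the per-slice profile
    runs along the first (z) axis.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    std = np.asarray(std_map)
    if overlap_mask is None:
        overlap_mask = np.ones_like(std, dtype=bool)
    hot = (std > threshold) & overlap_mask
    n_ov = np.count_nonzero(overlap_mask)
    global_frac = np.count_nonzero(hot) / n_ov if n_ov else 0.0
    per_slice_n = overlap_mask.reshape(std.shape[0], -1).sum(axis=1)
    per_slice_hot = hot.reshape(std.shape[0], -1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_slice = np.where(per_slice_n > 0, per_slice_hot / np.maximum(per_slice_n, 1), 0.0)
    return float(global_frac), per_slice, float(per_slice.max(initial=0.0))
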