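"""Forward simulation of wide-field mosaic acquisitions.

Emulates, at desk scale, everything the beamline does to a sample:

* parallel-beam line integrals over 360° with the rotation axis offset
  toward one detector edge (half-acquisition geometry),
* a small extra angular offset between complementary projection pairs
  (the second half-turn lags the nominal angle by a configurable epsilon),
* propagation-based edge enhancement via the single-material transport-of-
  intensity transfer function (the exact multiplicative inverse of the
  Paganin retrieval filter),
* an illumination field with low-rank temporal drift plus Poisson and
  Gaussian detector noise, and dark/flat calibration frames,
* slow, smooth tissue deformation growing linearly in time between tiles.

All randomness flows through explicit seeds, so identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from mosaictomo.phantom import Phantom
from mosaictomo.phase import OpticsConfig, tie_transfer, _pad_width
from mosaictomo.plan import MosaicPlan
from mosaictomo.io import ProjectionSet, write_projection_set

__all__ = [
    "IlluminationModel", "DeformationModel",
    "project_parallel", "apply_contrast_and_illumination",
    "simulate_scan", "simulate_mosaic",
    "DEFAULT_EPS_DEG",
]

#: complementary-pair angular offset observed at the beamline (degrees)
DEFAULT_EPS_DEG = 0.04565


# ---------------------------------------------------------------------------
# illumination

def _smooth_columns(n_cols: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n_cols)
    return ndimage.gaussian_filter1d(x, scale, mode="wrap")


@dataclass
class IlluminationModel:
    """Drifting illumination: mean flat plus K principal drift components.

    The per-frame flat field is ``mean_flat + sum_k c_k(t) * components[k]``
    where the coefficients follow a stationary AR(1) process with standard
    deviation ``coeff_sigma[k]`` and lag-one correlation ``coeff_rho``.
    Components are zero-mean spatial patterns with pronounced column
    structure (the drift mode that produces ring artifacts downstream).
    """

    mean_flat: np.ndarray                       # (rows, cols), counts, > 0
    components: np.ndarray                      # (K, rows, cols), zero-mean
    coeff_sigma: np.ndarray                     # (K,)
    coeff_rho: float = 0.95
    dark_mean: float = 100.0
    dark_sigma: float = 2.0
    read_sigma: float = 1.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if np.any(self.mean_flat <= 0):
            raise ValueError("mean flat must be > 0 everywhere")
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.ndim == 2:
            self.components = self.components[None]
        means = self.components.mean(axis=(1, 2))
        self.components = self.components - means[:, None, None]

    @property
    def K(self) -> int:
        return self.components.shape[0]

    @classmethod
    def make(cls, shape: tuple[int, int], n_components: int = 3,
             mean_counts: float = 5000.0, drift_amplitude: float = 0.05,
             seed: int = 0, **kw) -> "IlluminationModel":
        """Build a plausible illumination model.

        ``drift_amplitude`` is the per-component coefficient sigma as a
        fraction of ``mean_counts``; components are unit-RMS column-structured
        patterns, so the flat drifts by a few percent frame to frame.
        """
        rng = np.random.default_rng(seed)
        rows, cols = shape
        # smooth beam profile: broad Gaussian along columns, mild row slope
        c = np.linspace(-1, 1, cols)
        r = np.linspace(-1, 1, rows)
        prof = (0.85 + 0.15 * np.exp(-(c ** 2) / 0.8))[None, :] * \
               (1.0 + 0.05 * r)[:, None]
        mean_flat = mean_counts * prof
        comps = []
        for _ in range(n_components):
            col_pat = _smooth_columns(cols, scale=2.0, rng=rng)
            row_mod = 1.0 + 0.2 * _smooth_columns(rows, scale=8.0, rng=rng)
            pat = row_mod[:, None] * col_pat[None, :]
            pat -= pat.mean()
            pat /= np.sqrt(np.mean(pat ** 2))
            comps.append(pat)
        comps = np.array(comps)
        sig = drift_amplitude * mean_counts * np.array(
            [1.0 / (k + 1) for k in range(n_components)])
        return cls(mean_flat=mean_flat, components=comps, coeff_sigma=sig, **kw)

    def coefficient_series(self, n_frames: int,
                           rng: np.random.Generator) -> np.ndarray:
        """AR(1) coefficient sample paths, shape (n_frames, K)."""
        K = self.K
        c = np.zeros((n_frames, K))
        if K == 0 or n_frames == 0:
            return c
        innov = rng.standard_normal((n_frames, K))
        rho = self.coeff_rho
        c[0] = innov[0] * self.coeff_sigma
        s_innov = self.coeff_sigma * math.sqrt(max(1e-12, 1 - rho ** 2))
        for t in range(1, n_frames):
            c[t] = rho * c[t - 1] + s_innov * innov[t]
        return c

    def flat_at(self, coeffs: np.ndarray | None) -> np.ndarray:
        f = self.mean_flat.astype(np.float64).copy()
        if coeffs is not None and self.K:
            f += np.tensordot(np.asarray(coeffs), self.components, axes=(0, 0))
        return f

    def sample_darks(self, n: int, rng: np.random.Generator) -> np.ndarray:
        shape = (n,) + self.mean_flat.shape
        return self.dark_mean + self.dark_sigma * rng.standard_normal(shape)

    def sample_flats(self, n: int, rng: np.random.Generator) -> np.ndarray:
        coeffs = self.coefficient_series(n, rng)
        out = np.empty((n,) + self.mean_flat.shape)
        for t in range(n):
            signal = np.maximum(self.flat_at(coeffs[t]), 1e-3)
            if self.poisson:
                signal = rng.poisson(signal).astype(np.float64)
            out[t] = signal + self.dark_mean \
                + self.read_sigma * rng.standard_normal(signal.shape) \
                + self.dark_sigma * rng.standard_normal(signal.shape)
        return out


# ---------------------------------------------------------------------------
# deformation

@dataclass
class DeformationModel:
    """Smooth displacement field growing linearly in time.

    The field is a fixed, seeded, smooth random unit-RMS 3D vector field
    ``g(x)`` (control-point noise upsampled to the volume grid); the
    displacement applied at time t is ``d(x, t) = t * rate_vox_per_s * g(x)``,
    so it is zero at t = 0 and its magnitude grows at the configured rate.
    """

    rate_vox_per_s: float = 0.0
    control_spacing_vox: int = 24
    seed: int = 0
    smooth_sigma: float = 1.2
    pockets: list[tuple[tuple[float, float, float], float, float]] = \
        field(default_factory=list)   # (center_vox, radius_vox, rate)

    def base_field(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Unit-RMS smooth vector field, shape (3,) + shape."""
        rng = np.random.default_rng(self.seed)
        ctrl_shape = tuple(max(2, s // self.control_spacing_vox + 2)
                           for s in shape)
        g = rng.standard_normal((3,) + ctrl_shape)
        g = ndimage.gaussian_filter(g, (0,) + (self.smooth_sigma,) * 3,
                                    mode="nearest")
        zoom = tuple(s / c for s, c in zip(shape, ctrl_shape))
        out = np.stack([ndimage.zoom(g[a], zoom, order=1, mode="nearest",
                                     grid_mode=True) for a in range(3)])
        rms = np.sqrt(np.mean(out ** 2))
        return out / max(rms, 1e-12)

    def displacement(self, shape: tuple[int, int, int], t_s: float) -> np.ndarray:
        d = t_s * self.rate_vox_per_s * self.base_field(shape)
        for (cz, cy, cx), radius, rate in self.pockets:
            zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape),
                                     indexing="ij")
            dz, dy, dx = zz - cz, yy - cy, xx - cx
            r = np.sqrt(dz ** 2 + dy ** 2 + dx ** 2) + 1e-9
            amp = t_s * rate * np.exp(-(r / radius) ** 2)
            d[0] += amp * dz / r
            d[1] += amp * dy / r
            d[2] += amp * dx / r
        return d

    def warp(self, volume: np.ndarray, t_s: float) -> np.ndarray:
        """Warp a volume to its state at time ``t_s`` (identity at t=0)."""
        if t_s == 0.0 or (self.rate_vox_per_s == 0.0 and not self.pockets):
            return volume
        d = self.displacement(volume.shape, t_s)
        coords = np.indices(volume.shape, dtype=np.float64) + d
        return ndimage.map_coordinates(volume, coords, order=1,
                                       mode="nearest")


# ---------------------------------------------------------------------------
# projection

def project_parallel(phantom: Phantom | np.ndarray,
                     angles_deg: np.ndarray,
                     axis_offset_px: float,
                     detector_width_px: int,
                     voxel_size_um: float | None = None) -> np.ndarray:
    """Parallel-beam line integrals (optical depth) of a volume.

    The rotation axis is the vertical line through the (x, y) centre of the
    volume; it projects to detector column ``axis_offset_px``.  Detector rows
    coincide with volume z-slices.  The returned stack has shape
    ``(n_angles, nz, detector_width_px)`` and holds dimensionless optical
    depth (mu in 1/m integrated over meters).

    Implementation: volume-rotation plus column summation with bilinear
    resampling; the (y, x) plane is zero-padded to its diagonal so no mass
    leaves the grid during rotation.
    """
    if isinstance(phantom, Phantom):
        vol = phantom.volume
        voxel_size_um = phantom.voxel_size_um
    else:
        vol = np.asarray(phantom)
        if voxel_size_um is None:
            raise ValueError("voxel_size_um required for raw arrays")
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=np.float64))
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    if not 0 <= axis_offset_px <= detector_width_px - 1:
        raise ValueError("axis offset outside detector")
    nz, ny, nx = vol.shape
    diag = int(math.ceil(math.hypot(ny, nx))) + 2
    py0 = (diag - ny) // 2
    px0 = (diag - nx) // 2
    padded = np.zeros((nz, diag, diag), dtype=np.float64)
    padded[:, py0:py0 + ny, px0:px0 + nx] = vol
    # rotation-axis column in padded coordinates
    cx_pad = px0 + (nx - 1) / 2.0
    u = np.arange(detector_width_px, dtype=np.float64) - float(axis_offset_px)
    xpos = cx_pad + u
    i0 = np.floor(xpos).astype(int)
    frac = xpos - i0
    ok0 = (i0 >= 0) & (i0 < diag)
    ok1 = (i0 + 1 >= 0) & (i0 + 1 < diag)
    i0c = np.clip(i0, 0, diag - 1)
    i1c = np.clip(i0 + 1, 0, diag - 1)

    dl_m = voxel_size_um * 1e-6
    sino = np.empty((angles.size, nz, detector_width_px), dtype=np.float64)
    for a, ang in enumerate(angles):
        if ang % 360.0 == 0.0:
            rot = padded
        else:
            rot = ndimage.rotate(padded, ang, axes=(1, 2), reshape=False,
                                 order=1, prefilter=False, mode="constant")
        q = rot.sum(axis=1)           # (nz, diag)
        col = (q[:, i0c] * (1.0 - frac) * ok0 + q[:, i1c] * frac * ok1)
        sino[a] = col * dl_m
    return sino


# ---------------------------------------------------------------------------
# detector model

def apply_contrast_and_illumination(optical_depth: np.ndarray,
                                    optics: OpticsConfig,
                                    illum: IlluminationModel | None = None,
                                    coeffs: np.ndarray | None = None,
                                    rng: np.random.Generator | None = None,
                                    edge_enhance: bool = True,
                                    pad_px: int | None = None,
                                    clip_eps: float = 1e-6) -> np.ndarray:
    """Turn an optical-depth frame into a raw detector frame.

    Contact intensity ``exp(-OD)`` is edge-enhanced by multiplying its
    Fourier spectrum with ``1 + (z*delta/mu)|k|^2`` — exactly the inverse of
    the Paganin retrieval filter, same frequency convention — then scaled by
    the (possibly drifting) flat field, offset by the dark level, and
    corrupted with Poisson + Gaussian noise if ``rng`` is given.

    ``pad_px`` controls reflective padding before the Fourier transfer
    (default: the retrieval's rule); pass 0 for the strictly periodic
    transform that the retrieval inverts exactly.
    """
    od = np.asarray(optical_depth, dtype=np.float64)
    intensity = np.exp(-od)
    if edge_enhance:
        zdm = optics.propagation_distance_m * optics.delta / optics.mu_per_m
        pad = _pad_width(optics, pad_px)
        work = np.pad(intensity, pad, mode="reflect") if pad > 0 else intensity
        H = tie_transfer(work.shape, optics.pixel_size_m, zdm)
        work = np.fft.ifft2(np.fft.fft2(work) * H).real
        intensity = work[pad:-pad, pad:-pad] if pad > 0 else work
    n_neg = int(np.count_nonzero(intensity <= 0))
    if n_neg:
        intensity = np.maximum(intensity, clip_eps)
    if illum is None:
        return intensity
    signal = intensity * np.maximum(illum.flat_at(coeffs), 1e-3)
    if rng is not None:
        if illum.poisson:
            signal = rng.poisson(np.maximum(signal, 0.0)).astype(np.float64)
        signal = signal + illum.read_sigma * rng.standard_normal(signal.shape)
        dark = illum.dark_mean + illum.dark_sigma * rng.standard_normal(signal.shape)
    else:
        dark = illum.dark_mean
    return signal + dark


def scan_angles(n_proj: int, eps_deg: float = DEFAULT_EPS_DEG) -> np.ndarray:
    """360° angle list with the complementary-pair offset.

    The first half-turn is nominal (``i * 360/n``); the second half-turn
    carries an extra ``eps_deg``, so projections at theta and 180° + theta
    differ by exactly ``180 + eps_deg`` as observed in the recorded angle
    arrays.
    """
    base = np.arange(n_proj) * (360.0 / n_proj)
    ang = base.copy()
    ang[base >= 180.0] += eps_deg
    return ang


def simulate_scan(volume: np.ndarray, voxel_size_um: float,
                  optics: OpticsConfig, illum: IlluminationModel | None,
                  n_proj: int, axis_offset_px: float, detector_width_px: int,
                  rng: np.random.Generator,
                  eps_deg: float = DEFAULT_EPS_DEG,
                  noise: bool = True,
                  source_blur_px: float = 1.0,
                  n_darks: int = 50, n_flats: int = 300) -> ProjectionSet:
    """One wide-field 360° scan of a (sub)volume, with calibration frames.

    ``source_blur_px`` band-limits the projected optical depth (Gaussian
    sigma, pixels) before the contrast model, emulating the finite source
    size and scintillator response; without it, voxel-sharp edges would
    drive the quadratic edge-enhancement transfer to unphysical negative
    intensities.
    """
    angles = scan_angles(n_proj, eps_deg)
    od = project_parallel(volume, angles, axis_offset_px, detector_width_px,
                          voxel_size_um)
    if source_blur_px > 0:
        od = ndimage.gaussian_filter(od, (0, source_blur_px, source_blur_px))
    rows = volume.shape[0]
    if illum is not None:
        coeffs = illum.coefficient_series(n_proj, rng)
        data = np.empty_like(od)
        for i in range(n_proj):
            data[i] = apply_contrast_and_illumination(
                od[i], optics, illum, coeffs[i], rng if noise else None)
        darks = illum.sample_darks(n_darks, rng)
        flats = illum.sample_flats(n_flats, rng)
    else:
        data = np.empty_like(od)
        for i in range(n_proj):
            data[i] = apply_contrast_and_illumination(od[i], optics, None)
        darks = np.zeros((n_darks, rows, detector_width_px))
        flats = np.ones((n_flats, rows, detector_width_px))
    return ProjectionSet(data=data.astype(np.float32),
                         darks=darks.astype(np.float32),
                         flats=flats.astype(np.float32),
                         angles_deg=angles,
                         pixel_size_um=voxel_size_um,
                         timestamp_s=0.0,
                         grid_index=(0, 0, 0),
                         axis_offset_px=float(axis_offset_px))


def _tile_block(phantom_vol: np.ndarray, phantom: Phantom,
                pose_mm: tuple[float, float, float],
                tile_extent_mm: tuple[float, float, float],
                margin_px: int, fov_mask: bool = False) -> np.ndarray:
    """Cut the block scanned for one tile.

    The crop radius is the tile's circumscribed-circle radius (the valid
    reconstruction circle of the half-acquisition scan) plus a margin; with
    ``fov_mask`` the block is additionally masked to that cylinder so every
    projection of it is complete (no interior-tomography truncation).
    """
    vox_mm = phantom.voxel_size_um * 1e-3
    nz, ny, nx = phantom_vol.shape
    ox, oy, oz = phantom.origin_mm
    cx = (pose_mm[0] - ox) / vox_mm
    cy = (pose_mm[1] - oy) / vox_mm
    cz = (pose_mm[2] - oz) / vox_mm
    r_circ = math.hypot(tile_extent_mm[0], tile_extent_mm[1]) / 2.0 / vox_mm
    hw = r_circ + margin_px
    hh = tile_extent_mm[2] / 2.0 / vox_mm
    x0, x1 = int(round(cx - hw)), int(round(cx + hw))
    y0, y1 = int(round(cy - hw)), int(round(cy + hw))
    z0, z1 = int(round(cz - hh)), int(round(cz + hh))
    if x0 < 0 or y0 < 0 or z0 < 0 or x1 > nx or y1 > ny or z1 > nz:
        raise ValueError(
            f"tile at {pose_mm} mm extends outside the phantom bounds "
            f"(needed z[{z0}:{z1}] y[{y0}:{y1}] x[{x0}:{x1}] of {phantom_vol.shape})")
    block = phantom_vol[z0:z1, y0:y1, x0:x1]
    if fov_mask:
        by, bx = block.shape[1], block.shape[2]
        yy, xx = np.meshgrid(np.arange(by) - (by - 1) / 2.0,
                             np.arange(bx) - (bx - 1) / 2.0, indexing="ij")
        disk = yy ** 2 + xx ** 2 <= hw ** 2
        block = block * disk[None, :, :]
    return block


def simulate_mosaic(phantom: Phantom, plan: MosaicPlan,
                    optics: OpticsConfig,
                    illum: IlluminationModel | None,
                    deform: DeformationModel | None,
                    n_proj: int, seed: int,
                    eps_deg: float = DEFAULT_EPS_DEG,
                    axis_offset_px: int = 8,
                    detector_width_px: int | None = None,
                    margin_px: int = 4,
                    noise: bool = True,
                    source_blur_px: float = 1.0,
                    n_darks: int = 50, n_flats: int = 300,
                    fov_mask: bool = False,
                    out_dir=None) -> list:
    """Simulate every tile of a mosaic plan.

    Per tile: the phantom is warped by the deformation model evaluated at the
    tile's predicted start time, cropped to the tile's physical extent plus a
    margin, and scanned over 360° in half-acquisition geometry.  Tiles are
    packaged with calibration frames and their acquisition timestamp; if
    ``out_dir`` is given each tile is also written as an HDF5 file and the
    returned list holds file paths, otherwise in-memory ``ProjectionSet``.
    """
    if n_proj < 2:
        raise ValueError("n_proj must be >= 2")
    vox_mm = phantom.voxel_size_um * 1e-3
    if detector_width_px is None:
        detector_width_px = int(math.ceil(plan.tile_extent_mm[0] / 2.0 / vox_mm)) \
            + axis_offset_px + 2
    rng = np.random.default_rng(seed)
    tile_seeds = rng.integers(0, 2 ** 31 - 1, size=plan.n_tiles)
    outputs = []
    for tile in plan.tiles_in_order():
        t_s = tile.predicted_start_s
        warped = deform.warp(phantom.volume, t_s) if deform is not None \
            else phantom.volume
        block = _tile_block(warped, phantom, tile.position_mm,
                            plan.tile_extent_mm, margin_px,
                            fov_mask=fov_mask)
        tile_rng = np.random.default_rng(int(tile_seeds[tile.order_index]))
        pset = simulate_scan(block, phantom.voxel_size_um, optics, illum,
                             n_proj, axis_offset_px, detector_width_px,
                             tile_rng, eps_deg=eps_deg, noise=noise,
                             source_blur_px=source_blur_px,
                             n_darks=n_darks, n_flats=n_flats)
        pset.timestamp_s = float(t_s)
        pset.grid_index = tile.grid_index
        if out_dir is not None:
            import os
            i, j, k = tile.grid_index
            path = os.path.join(str(out_dir), f"tile_{i}_{j}_{k}.h5")
            write_projection_set(pset, path)
            outputs.append(path)
        else:
            outputs.append(pset)
    return outputs
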