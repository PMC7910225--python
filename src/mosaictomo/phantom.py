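"""Synthetic lung-like foam phantoms.

A phantom is a 3D attenuation map (1/m) on an isotropic voxel grid, indexed
``[z, y, x]`` with z increasing upward.  The standard phantom emulates the
essential features of a small-animal chest at micro-CT scale:

* a cylindrical soft-tissue "body",
* a foam-like "lung" region inside it: air bubbles carved by seeded random
  sphere packing (overlapping spheres, so the airspace is connected, as
  alveolar ducts connect real airspaces),
* a vertical "trachea" channel connecting the airspace to the top face,
* a few high-attenuation "bone" rods.

Ground truth (air mask and air volume) is recorded at generation time so the
segmentation stage can be validated quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phantom", "make_foam_phantom", "MU_TISSUE", "MU_BONE_FACTOR"]

#: soft-tissue linear attenuation at ~21 keV, 1/m
MU_TISSUE = 60.0
#: bone attenuation relative to tissue
MU_BONE_FACTOR = 5.0


@dataclass
class Phantom:
    """Attenuation phantom with ground-truth air bookkeeping."""

    volume: np.ndarray                 # mu in 1/m, shape (nz, ny, nx)
    voxel_size_um: float
    air_mask: np.ndarray               # bool, lung airspace voxels (mu == 0)
    lung_mask: np.ndarray | None = None   # region inside which foam was carved
    bone_mask: np.ndarray | None = None
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mu_tissue: float = MU_TISSUE
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    @property
    def air_volume_mm3(self) -> float:
        """Ground-truth airspace volume: mask count times voxel volume."""
        return float(np.count_nonzero(self.air_mask)) * self.voxel_volume_mm3

    def thickness_map_m(self, axis: int = 1) -> np.ndarray:
        """Single-material equivalent thickness along ``axis`` (meters)."""
        dl = self.voxel_size_um * 1e-6
        return self.volume.sum(axis=axis) * dl / self.mu_tissue


def _carve_sphere(mask: np.ndarray, center: np.ndarray, r: float) -> None:
    nz, ny, nx = mask.shape
    cz, cy, cx = center
    z0, z1 = max(0, int(cz - r) - 1), min(nz, int(cz + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(ny, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(nx, int(cx + r) + 2)
    zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    inside = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    mask[z0:z1, y0:y1, x0:x1] |= inside


def make_foam_phantom(shape_vox: tuple[int, int, int],
                      voxel_size_um: float = 2.75,
                      target_air_fraction: float = 0.6,
                      wall_thickness_um: float = 10.0,
                      seed: int = 0,
                      mu_tissue: float = MU_TISSUE,
                      n_bone_rods: int = 3,
                      body_radius_frac: float = 0.46,
                      lung_radius_frac: float = 0.78) -> Phantom:
    """Generate a reproducible foam phantom.

    Air bubbles (spheres with radii drawn between roughly 3 and 6 wall
    thicknesses) are carved from the lung region until the realized air
    fraction of that region reaches ``target_air_fraction``; overlaps are
    allowed so the airspace is a single connected foam.  A trachea channel
    connects the foam to the top face so connectivity-based segmentation has
    a physical seed.

    Raises ``ValueError`` when the requested fraction cannot be reached for
    the given wall thickness (packing budget exhausted).
    """
    if not 0.0 <= target_air_fraction < 1.0:
        raise ValueError("target_air_fraction must be in [0, 1)")
    nz, ny, nx = shape_vox
    rng = np.random.default_rng(seed)

    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_body = body_radius_frac * min(ny, nx)
    rho2 = (yy - cy) ** 2 + (xx - cx) ** 2
    body = rho2 <= r_body ** 2
    r_lung = lung_radius_frac * r_body
    lung = rho2 <= r_lung ** 2

    vol = np.zeros(shape_vox, dtype=np.float32)
    vol[body] = mu_tissue

    bone = np.zeros(shape_vox, dtype=bool)
    r_rod = max(2.0, 0.06 * min(ny, nx))
    for m in range(n_bone_rods):
        phi = 2.0 * np.pi * m / max(1, n_bone_rods) + 0.4
        rc = (r_body + r_lung) / 2.0
        bcy, bcx = cy + rc * np.sin(phi), cx + rc * np.cos(phi)
        bone |= (yy - bcy) ** 2 + (xx - bcx) ** 2 <= r_rod ** 2
    bone &= body
    vol[bone] = MU_BONE_FACTOR * mu_tissue

    air = np.zeros(shape_vox, dtype=bool)
    if target_air_fraction > 0.0:
        wall_vox = max(1.0, wall_thickness_um / voxel_size_um)
        r_lo, r_hi = 1.5 * wall_vox, 3.0 * wall_vox
        r_hi = min(r_hi, 0.25 * r_lung)
        r_lo = min(r_lo, 0.8 * r_hi)
        # keep a tissue margin of one wall against the lung border
        margin = r_lung - wall_vox
        n_lung = int(np.count_nonzero(lung))
        target_count = target_air_fraction * n_lung
        max_attempts = 4000 + int(200 * target_count
                                  / (4.0 / 3.0 * np.pi * r_lo ** 3))
        attempts = 0
        while np.count_nonzero(air & lung) < target_count:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "unreachable air fraction "
                    f"{target_air_fraction} for wall thickness "
                    f"{wall_thickness_um} um (packing budget exhausted)")
            r = rng.uniform(r_lo, r_hi)
            if margin - r <= 0:
                raise ValueError(
                    "unreachable air fraction: wall thickness too large for "
                    "the lung region")
            rad = rng.uniform(0, margin - r)
            phi = rng.uniform(0, 2 * np.pi)
            cz_s = rng.uniform(r + 1, nz - r - 2) if nz > 2 * (r + 2) else nz / 2
            center = np.array([cz_s, cy + rad * np.sin(phi),
                               cx + rad * np.cos(phi)])
            _carve_sphere(air, center, r)
        air &= lung
        # trachea: vertical channel from the top face into the foam
        r_tr = max(2.0, 1.5 * wall_vox)
        tr = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_tr ** 2
        tr &= zz >= nz // 2
        air |= tr
    air &= body
    air &= ~bone
    vol[air] = 0.0

    realized = (np.count_nonzero(air & lung) / max(1, np.count_nonzero(lung))
                if target_air_fraction > 0 else 0.0)
    return Phantom(volume=vol, voxel_size_um=voxel_size_um, air_mask=air,
                   lung_mask=lung, bone_mask=bone, mu_tissue=mu_tissue,
                   meta={"seed": seed,
                         "target_air_fraction": target_air_fraction,
                         "realized_air_fraction": realized,
                         "wall_thickness_um": wall_thickness_um})
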