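"""Dark-field and (static / dynamic) flat-field correction.

Short synchrotron scans see the illumination field drift during the scan
(e.g. monochromator vibrations); dividing by a single mean flat then leaves
fixed-pattern stripes in the sinogram which reconstruct into ring artifacts.
The dynamic correction models each projection's flat as the mean flat plus a
small number of principal components of the recorded flat stack and fits the
per-projection component weights on sample-free detector margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import medfilt

__all__ = [
    "FlatFieldModel", "fit_flat_basis", "correct_static", "correct_dynamic",
    "background_margin_mask", "stripe_metric", "ring_metric",
]


@dataclass
class FlatFieldModel:
    """Mean dark/flat plus K orthonormal eigen-flats with their eigenvalues."""

    dark_mean: np.ndarray           # (rows, cols)
    flat_mean: np.ndarray           # (rows, cols), dark-subtracted
    components: np.ndarray          # (K, rows, cols), orthonormal over pixels
    eigenvalues: np.ndarray         # (K,), nonincreasing

    @property
    def K(self) -> int:
        return self.components.shape[0]


def fit_flat_basis(flat_stack: np.ndarray, dark_mean: np.ndarray,
                   K: int = 5) -> FlatFieldModel:
    """Principal-component basis of a dark-subtracted flat-field stack.

    Uses the frame-space Gram matrix (an n_flats x n_flats eigenproblem, not
    pixels x pixels), equivalent to PCA of the pixel covariance.  Components
    come back in descending eigenvalue order; eigenvalues are the sample
    variances of the flats along each component.
    """
    flats = np.asarray(flat_stack, dtype=np.float64)
    n = flats.shape[0]
    if K > n - 1:
        raise ValueError(f"K={K} too large for {n} flats (need >= K+1)")
    dark = np.asarray(dark_mean, dtype=np.float64)
    X = (flats - dark).reshape(n, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered stack; right singular vectors are the eigen-flats
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S ** 2 / max(1, n - 1)
    shape = flats.shape[1:]
    comps = Vt[:K].reshape((K,) + shape)
    return FlatFieldModel(dark_mean=dark, flat_mean=mean.reshape(shape),
                          components=comps, eigenvalues=eigvals[:K])


def correct_static(raw_frame: np.ndarray, model: FlatFieldModel) -> np.ndarray:
    """Conventional correction: ``(raw - dark) / (flat - dark)``.

    The model's ``flat_mean`` is already dark-subtracted.  Raises if the
    denominator is not strictly positive everywhere.
    """
    denom = model.flat_mean
    n_bad = int(np.count_nonzero(denom <= 0))
    if n_bad:
        raise ValueError(
            f"flat - dark non-positive at {n_bad} pixels; cannot normalize")
    return (np.asarray(raw_frame, dtype=np.float64) - model.dark_mean) / denom


def background_margin_mask(shape: tuple[int, int], margin_cols: int = 20) -> np.ndarray:
    """Boolean mask selecting the outermost sample-free detector columns."""
    mask = np.zeros(shape, dtype=bool)
    m = min(margin_cols, shape[1] // 2)
    mask[:, :m] = True
    mask[:, shape[1] - m:] = True
    return mask


def correct_dynamic(raw_frame: np.ndarray, model: FlatFieldModel,
                    background_region: np.ndarray | None = None,
                    floor_frac: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Per-projection flat-field correction with fitted drift weights.

    The effective flat for this frame is ``flat_mean + sum_k w_k u_k`` where
    the weights are fitted to ``raw - dark`` against the basis restricted to
    ``background_region`` (sample-free pixels; default: the 20 outermost
    columns on each side).  Returns ``(corrected_frame, weights)``.  With
    K = 0 this reduces exactly to the static correction.

    The fit is least squares with an empirical-Bayes ridge: the pixel-noise
    variance is estimated from the plain fit's residual and the prior weight
    variances are the model's eigenvalues.  On noiseless frames the residual
    vanishes and the fit is exact; on noisy frames components that are
    poorly expressed inside the background region are shrunk toward zero
    instead of amplifying noise.
    """
    raw = np.asarray(raw_frame, dtype=np.float64)
    if background_region is None:
        background_region = background_margin_mask(raw.shape)
    bg = np.asarray(background_region, dtype=bool)
    if not bg.any():
        raise ValueError("background_region is empty")
    if model.K == 0:
        return correct_static(raw, model), np.zeros(0)
    resid = (raw - model.dark_mean - model.flat_mean)[bg]
    U = model.components[:, bg].T        # (n_bg, K)
    n_bg, K = U.shape
    try:
        w0, *_ = np.linalg.lstsq(U, resid, rcond=None)
        if not np.all(np.isfinite(w0)):
            raise np.linalg.LinAlgError("non-finite weights")
        dof = max(1, n_bg - K)
        sigma2 = float(((resid - U @ w0) ** 2).sum()) / dof
        lam = np.maximum(model.eigenvalues[:K], 1e-12)
        A = U.T @ U + np.diag(sigma2 / lam)
        w = np.linalg.solve(A, U.T @ resid)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError("non-finite weights")
    except np.linalg.LinAlgError:
        warnings.warn("dynamic flat fit singular; falling back to static")
        return correct_static(raw, model), np.zeros(model.K)
    eff_flat = model.flat_mean + np.tensordot(w, model.components, axes=(0, 0))
    floor = floor_frac * np.median(model.flat_mean)
    eff_flat = np.maximum(eff_flat, floor)
    return (raw - model.dark_mean) / eff_flat, w


def stripe_metric(sinogram: np.ndarray, detrend_kernel: int = 15,
                  per_frame: bool = True) -> float:
    """Stripe score of a transmission sinogram (n_proj x cols).

    Each projection's log profile is detrended with a running median
    (removing the smooth object structure); the score is the mean standard
    deviation of the residuals — the sinogram-domain precursor of ring
    artifacts.  Per-frame scoring responds to time-varying illumination
    error in every projection; with ``per_frame=False`` only the
    scan-averaged column profile is scored, which misses drift whose mean
    over the scan happens to cancel.
    """
    sino = np.asarray(sinogram, dtype=np.float64)
    logs = -np.log(np.maximum(sino, 1e-2))
    k = min(detrend_kernel, (logs.shape[-1] - 1) | 1)
    if per_frame:
        resid = np.stack([row - medfilt(row, kernel_size=k)
                          for row in np.atleast_2d(logs)])
        return float(np.mean(resid.std(axis=-1)))
    col_means = logs.mean(axis=0)
    return float(np.std(col_means - medfilt(col_means, kernel_size=k)))


def ring_metric(reconstructed_slice: np.ndarray,
                center: tuple[float, float] | None = None,
                n_theta: int = 360, medfilt_kernel: int = 11) -> float:
    """Ring-artifact score of a reconstructed slice.

    The slice is resampled to polar coordinates about ``center``; the
    angular-mean radial profile is compared against its own running median
    along radius.  Concentric rings are narrow radial features the median
    filter removes, so the mean absolute deviation between the two profiles
    grows with ring amplitude and is zero for constant slices.
    """
    img = np.asarray(reconstructed_slice, dtype=np.float64)
    ny, nx = img.shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    cy, cx = center
    rmax = int(min(cy, cx, ny - 1 - cy, nx - 1 - cx))
    if rmax < 3:
        return 0.0
    radii = np.arange(1, rmax)
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    yy = cy + radii[:, None] * np.sin(thetas)[None, :]
    xx = cx + radii[:, None] * np.cos(thetas)[None, :]
    polar = ndimage.map_coordinates(img, np.stack([yy, xx]), order=1)
    prof = polar.mean(axis=1)
    k = min(medfilt_kernel, (len(prof) - 1) | 1)
    if k < 3:
        return 0.0
    smooth = medfilt(prof, kernel_size=k)
    return float(np.mean(np.abs(prof - smooth)))
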