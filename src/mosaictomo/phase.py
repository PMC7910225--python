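"""Single-distance (Paganin) phase retrieval.

For a single-material object imaged a short distance z downstream, the
transport-of-intensity approximation relates the measured edge-enhanced
intensity I to the projected thickness T through a low-pass Fourier filter

    T = -(1/mu) * ln( F^-1 [ F[I/I0] / (1 + (z * delta / mu) |k|^2) ] )

with mu = 4*pi*beta/lambda and |k| the angular spatial frequency (rad/m).
The same transfer function, applied multiplicatively, is the forward model
used by the acquisition simulator, so forward + retrieval round-trips are
exact to numerical precision (shared helper :func:`tie_transfer`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["OpticsConfig", "tie_transfer", "paganin_retrieve", "PAPER_OPTICS"]

#: hc in eV*m
_HC_EV_M = 1.23984193e-6


@dataclass(frozen=True)
class OpticsConfig:
    """Beamline optics parameters for phase retrieval.

    delta and beta are the refractive-index decrement and absorption index
    of the (assumed single) material; the derived linear attenuation
    coefficient is ``mu = 4*pi*beta/lambda`` in 1/m.
    """

    energy_keV: float = 21.0
    propagation_distance_m: float = 0.1
    pixel_size_um: float = 2.75
    delta: float = 2.0e-7
    beta: float = 2.8e-10

    def __post_init__(self) -> None:
        for name in ("energy_keV", "propagation_distance_m", "pixel_size_um",
                     "delta", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"OpticsConfig.{name} must be > 0")

    @property
    def wavelength_m(self) -> float:
        return _HC_EV_M / (self.energy_keV * 1e3)

    @property
    def mu_per_m(self) -> float:
        """Linear attenuation coefficient 4*pi*beta/lambda in 1/m."""
        return 4.0 * np.pi * self.beta / self.wavelength_m

    @property
    def pixel_size_m(self) -> float:
        return self.pixel_size_um * 1e-6


#: Optics used throughout the examples: 21 keV, 100 mm propagation,
#: 2.75 um pixels, empirical delta/beta for lung tissue.
PAPER_OPTICS = OpticsConfig()


def tie_transfer(shape: tuple[int, int], pixel_size_m: float,
                 z_delta_over_mu: float) -> np.ndarray:
    """Single-material transfer function ``H = 1 + (z*delta/mu) |k|^2``.

    |k| is angular frequency in rad/m on the FFT grid of ``shape``.  This
    helper is the single source of the frequency convention: the simulator
    multiplies spectra by H (edge enhancement) and retrieval divides by H,
    which makes the pair exactly inverse on unpadded frames.
    """
    if z_delta_over_mu < 0:
        raise ValueError("z*delta/mu must be >= 0")
    ky = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=pixel_size_m)
    kx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=pixel_size_m)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    return 1.0 + z_delta_over_mu * k2


def _pad_width(optics: OpticsConfig, requested: int | None) -> int:
    if requested is not None:
        return int(requested)
    # characteristic blur length of the filter, in pixels
    length_m = np.sqrt(optics.propagation_distance_m * optics.delta
                       / optics.mu_per_m)
    return max(64, int(np.ceil(2.0 * length_m / optics.pixel_size_m)))


def paganin_retrieve(normalized_frame: np.ndarray, optics: OpticsConfig,
                     pad_px: int | None = None,
                     floor: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Retrieve thickness from a flat-field-normalized projection.

    Parameters
    ----------
    normalized_frame : 2D transmission image (values near [0, 1.2]).
        Non-positive pixels are floored at ``floor`` with a warning.
    optics : beam/sample parameters; the filter strength is
        ``z * delta / mu``.
    pad_px : reflective padding width applied before filtering to mitigate
        FFT wrap-around; default is ``max(64, 2*sqrt(z delta/mu)/pixel)``.
        Pass 0 for the exact (periodic) inverse of the simulator's forward
        transfer.

    Returns
    -------
    (T, muT) : thickness-equivalent map in meters and the dimensionless
        retrieved optical depth ``mu*T``.
    """
    frame = np.asarray(normalized_frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("expected a 2D frame")
    mu = optics.mu_per_m
    zdm = optics.propagation_distance_m * optics.delta / mu
    if zdm <= 0:
        raise ValueError("z*delta/mu must be positive")
    n_bad = int(np.count_nonzero(frame <= 0))
    if n_bad:
        warnings.warn("paganin_retrieve: non-positive pixels floored")
        frame = np.maximum(frame, floor)

    pad = _pad_width(optics, pad_px)
    if pad > 0:
        padded = np.pad(frame, pad, mode="reflect")
    else:
        padded = frame
    H = tie_transfer(padded.shape, optics.pixel_size_m, zdm)
    filtered = np.fft.ifft2(np.fft.fft2(padded) / H).real
    if pad > 0:
        filtered = filtered[pad:-pad, pad:-pad]
    filtered = np.maximum(filtered, floor)
    muT = -np.log(filtered)
    return muT / mu, muT
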