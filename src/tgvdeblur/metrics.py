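"""Restoration quality metrics: SNR, PSNR, RelErr, MSE and SSIM.

All metrics take the reference (ideal) image first and the test
(restored) image second, on the native intensity scale (nominally
0-255; PSNR's peak constant and SSIM's stabilizers default to 255).

Conventions:

* ``psnr`` / ``snr`` return ``+inf`` when the images agree exactly.
* ``relerr`` is the scale-free ``||u - u_hat||_2 / ||u||_2``; the
  non-scale-free variant with a squared-norm denominator is available
  via ``literal_denominator=True``.
* ``ssim`` defaults to the standard local formulation: statistics over
  an 11x11 Gaussian window (sigma 1.5) at every pixel, stabilizers
  ``C1 = (0.01*peak)^2``, ``C2 = (0.03*peak)^2``, averaged over the
  valid (border-cropped) region.  ``mode="global"`` instead evaluates
  the SSIM formula once with whole-image moments.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import correlate

__all__ = ["MetricsReport", "mse", "psnr", "snr", "relerr", "ssim", "evaluate"]


def _check_pair(u: np.ndarray, u_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    u_hat = np.asarray(u_hat, dtype=float)
    if u.shape != u_hat.shape:
        raise ValueError(f"image shapes differ: {u.shape} vs {u_hat.shape}")
    if u.ndim != 2:
        raise ValueError("metrics are defined on 2-D images")
    return u, u_hat


def mse(u_true: np.ndarray, u_hat: np.ndarray) -> float:
    """Mean squared difference."""
    u, uh = _check_pair(u_true, u_hat)
    return float(np.mean((uh - u) ** 2))


def psnr(u_true: np.ndarray, u_hat: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(peak^2 / MSE)`` in dB."""
    m = mse(u_true, u_hat)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / m)


def snr(u_true: np.ndarray, u_hat: np.ndarray) -> float:
    """Signal-to-noise ratio ``20 log10(||u|| / ||u_hat - u||)`` in dB."""
    u, uh = _check_pair(u_true, u_hat)
    err = float(np.linalg.norm(uh - u))
    if err == 0.0:
        return math.inf
    return 20.0 * math.log10(float(np.linalg.norm(u)) / err)


def relerr(u_true: np.ndarray, u_hat: np.ndarray, literal_denominator: bool = False) -> float:
    """Relative error ``||u - u_hat||_2 / ||u||_2``.

    ``literal_denominator=True`` divides by ``||u||_2^2`` instead (the
    non-scale-free variant).
    """
    u, uh = _check_pair(u_true, u_hat)
    denom = float(np.linalg.norm(u))
    if denom == 0.0:
        raise ValueError("relerr is undefined for an identically zero reference")
    if literal_denominator:
        denom = denom**2
    return float(np.linalg.norm(u - uh)) / denom


def _gaussian_window(win_size: int, sigma: float) -> np.ndarray:
    r = win_size // 2
    ax = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def ssim(u_true: np.ndarray, u_hat: np.ndarray, peak: float = 255.0,
         mode: str = "windowed", win_size: int = 11, sigma: float = 1.5,
         K1: float = 0.01, K2: float = 0.03,
         C1: float | None = None, C2: float | None = None) -> float:
    """Structural similarity index.

    ``mode="windowed"`` (default): per-pixel local means/variances/
    covariance under a normalized ``win_size`` x ``win_size`` Gaussian
    window, SSIM map averaged over the border-cropped valid region.
    ``mode="global"``: the formula evaluated once with whole-image
    (population) moments.
    """
    u, uh = _check_pair(u_true, u_hat)
    if C1 is None:
        C1 = (K1 * peak) ** 2
    if C2 is None:
        C2 = (K2 * peak) ** 2
    if C1 <= 0 or C2 <= 0:
        raise ValueError("SSIM stabilizers C1, C2 must be positive")

    if mode == "global":
        mu_u, mu_h = u.mean(), uh.mean()
        var_u, var_h = u.var(), uh.var()
        cov = float(np.mean((u - mu_u) * (uh - mu_h)))
        return ((2 * mu_u * mu_h + C1) * (2 * cov + C2)) / (
            (mu_u**2 + mu_h**2 + C1) * (var_u + var_h + C2)
        )
    if mode != "windowed":
        raise ValueError(f"unknown SSIM mode {mode!r}")
    if win_size % 2 == 0 or win_size < 3:
        raise ValueError("win_size must be odd and >= 3")
    if min(u.shape) < win_size:
        raise ValueError(f"window {win_size} larger than image {u.shape}")

    win = _gaussian_window(win_size, sigma)

    def filt(img: np.ndarray) -> np.ndarray:
        return correlate(img, win, mode="reflect")

    mu_u = filt(u)
    mu_h = filt(uh)
    mu_uu = filt(u * u)
    mu_hh = filt(uh * uh)
    mu_uh = filt(u * uh)
    var_u = mu_uu - mu_u**2
    var_h = mu_hh - mu_h**2
    cov = mu_uh - mu_u * mu_h

    smap = ((2 * mu_u * mu_h + C1) * (2 * cov + C2)) / (
        (mu_u**2 + mu_h**2 + C1) * (var_u + var_h + C2)
    )
    pad = win_size // 2
    return float(np.mean(smap[pad:-pad, pad:-pad]))


@dataclass
class MetricsReport:
    """One row of quality numbers for a (reference, restored) pair."""

    snr: float
    psnr: float
    relerr: float
    mse: float
    ssim: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)

    def as_table(self) -> str:
        rows = [("SNR (dB)", self.snr), ("PSNR (dB)", self.psnr),
                ("RelErr", self.relerr), ("MSE", self.mse), ("SSIM", self.ssim)]
        width = max(len(name) for name, _ in rows)
        return "\n".join(f"{name:<{width}}  {value:.4f}" for name, value in rows)


def evaluate(u_true: np.ndarray, u_hat: np.ndarray, peak: float = 255.0,
             ssim_mode: str = "windowed") -> MetricsReport:
    """Compute the full metric set for a restoration."""
    return MetricsReport(
        snr=snr(u_true, u_hat),
        psnr=psnr(u_true, u_hat, peak=peak),
        relerr=relerr(u_true, u_hat),
        mse=mse(u_true, u_hat),
        ssim=ssim(u_true, u_hat, peak=peak, mode=ssim_mode),
    )
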