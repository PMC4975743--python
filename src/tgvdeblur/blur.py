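"""Point-spread functions and the blurring operator K.

A :class:`PSF` is a small nonnegative convolution kernel, normally
normalized to unit sum so that blurring conserves flux (total photon
count) — the natural contract for Poisson imaging.  Three classic
recipes are provided: a truncated sampled Gaussian, a uniform box, and
an anti-aliased linear-motion segment.

:class:`BlurOperator` realizes the linear map ``K`` (convolution with
the PSF) and its exact adjoint ``K^T`` on a fixed image shape.  Under
periodic boundaries both are applied by pointwise multiplication in the
frequency domain with the precomputed transfer function (the DFT of the
zero-padded, center-shifted kernel), which is what lets the solver's
normal equations be inverted exactly by FFT.  A ``"symmetric"``
(Neumann) variant is available: it symmetrically pads, correlates, and
applies the adjoint by the exact fold-back of the padding, so the
adjoint pairing still holds to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "PSF",
    "BlurOperator",
    "gaussian_psf",
    "box_psf",
    "motion_psf",
    "psf_from_array",
    "psf_from_spec",
    "save_psf",
    "load_psf",
]


@dataclass(frozen=True)
class PSF:
    """A small 2-D blur kernel with its center anchor."""

    kernel: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 2 or k.size == 0:
            raise ValueError("PSF kernel must be a non-empty 2-D array")
        if not np.all(np.isfinite(k)):
            raise ValueError("PSF kernel must be finite")
        if np.any(k < 0):
            raise ValueError("PSF kernel must be nonnegative")
        object.__setattr__(self, "kernel", k)

    @property
    def anchor(self) -> tuple[int, int]:
        """(row, col) offset of the kernel center."""
        return (self.kernel.shape[0] // 2, self.kernel.shape[1] // 2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.kernel.shape


def gaussian_psf(size: int, sigma: float) -> PSF:
    """Truncated sampled 2-D Gaussian on an odd ``size x size`` grid.

    The Gaussian ``exp(-(x^2+y^2)/(2 sigma^2))`` is sampled at integer
    offsets from the center and renormalized to unit sum.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("Gaussian PSF size must be odd and >= 1 (center must be unambiguous)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = size // 2
    ax = np.arange(-r, r + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return PSF(k / k.sum(), name=f"gaussian:{size},{sigma:g}")


def box_psf(size: int) -> PSF:
    """Uniform averaging kernel, every entry ``1/size^2``."""
    if size < 1:
        raise ValueError("box PSF size must be >= 1")
    return PSF(np.full((size, size), 1.0 / size**2), name=f"box:{size}")


def motion_psf(length: float, angle_degrees: float) -> PSF:
    """Linear camera-motion kernel of the given length and CCW angle.

    The kernel approximates convolution with a line segment of
    ``length`` pixels at ``angle_degrees`` counter-clockwise from the
    horizontal axis.  The segment is rasterized with anti-aliased
    weights (linear falloff of the distance to the segment) and
    normalized to unit sum; ``length <= 1`` degenerates to the identity
    kernel.
    """
    if length < 1:
        raise ValueError("motion length must be >= 1 pixel")
    half = (length - 1.0) / 2.0
    if half == 0.0:
        return PSF(np.array([[1.0]]), name=f"motion:{length:g},{angle_degrees:g}")
    theta = np.deg2rad(angle_degrees)
    # image rows grow downward, so a CCW angle has dy = -sin(theta)
    dx, dy = np.cos(theta), -np.sin(theta)
    r = int(np.ceil(half))
    ax = np.arange(-r, r + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    # distance from each pixel center to the segment [-half*d, +half*d]
    t = np.clip(xx * dx + yy * dy, -half, half)
    dist = np.hypot(xx - t * dx, yy - t * dy)
    k = np.maximum(0.0, 1.0 - dist)
    s = k.sum()
    if s == 0.0:  # cannot happen (center pixel has dist 0), defensive
        k[r, r] = 1.0
        s = 1.0
    return PSF(k / s, name=f"motion:{length:g},{angle_degrees:g}")


def psf_from_array(kernel: np.ndarray, normalize: bool = True, name: str = "custom") -> PSF:
    k = np.asarray(kernel, dtype=float)
    if normalize:
        s = k.sum()
        if s <= 0:
            raise ValueError("cannot normalize a kernel with nonpositive sum")
        k = k / s
    return PSF(k, name=name)


def psf_from_spec(spec: "str | PSF") -> PSF:
    """Build a PSF from a compact text spec.

    Accepted forms: ``gaussian:SIZE,SIGMA``, ``box:SIZE``,
    ``motion:LENGTH,ANGLE``, ``file:PATH`` (plain-text 2-D array or
    TIFF).  A :class:`PSF` instance passes through unchanged.
    """
    if isinstance(spec, PSF):
        return spec
    kind, _, rest = spec.partition(":")
    kind = kind.strip().lower()
    try:
        if kind == "gaussian":
            size_s, sigma_s = rest.split(",")
            return gaussian_psf(int(size_s), float(sigma_s))
        if kind == "box":
            return box_psf(int(rest))
        if kind == "motion":
            length_s, angle_s = rest.split(",")
            return motion_psf(float(length_s), float(angle_s))
        if kind == "file":
            return load_psf(rest)
    except ValueError:
        raise
    except Exception as exc:  # malformed numeric fields
        raise ValueError(f"malformed PSF spec {spec!r}") from exc
    raise ValueError(f"unknown PSF spec {spec!r}; expected gaussian:, box:, motion: or file:")


def save_psf(psf: PSF, path: "str | Path") -> None:
    """Write a PSF kernel as plain text (or TIFF for .tif/.tiff paths)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, psf.kernel.astype(np.float32))
    else:
        np.savetxt(path, psf.kernel)


def load_psf(path: "str | Path") -> PSF:
    path = Path(path)
    if not path.exists():
        raise ValueError(f"PSF file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        k = np.asarray(tifffile.imread(path), dtype=float)
    else:
        k = np.atleast_2d(np.loadtxt(path))
    return psf_from_array(k, normalize=False, name=f"file:{path}")


class BlurOperator:
    """The linear blurring map ``K`` and its adjoint on a fixed shape.

    Parameters
    ----------
    psf:
        Kernel (its shape must fit inside the image).
    shape:
        Target image shape ``(H, W)``.
    bc:
        ``"periodic"`` (circular convolution, FFT transfer function) or
        ``"symmetric"`` (Neumann padding with an exact fold-back adjoint).
    """

    def __init__(self, psf: PSF, shape: tuple[int, int], bc: str = "periodic") -> None:
        if bc not in ("periodic", "symmetric"):
            raise ValueError(f"unknown boundary condition {bc!r}")
        h, w = shape
        kh, kw = psf.shape
        if kh > h or kw > w:
            raise ValueError(f"PSF {psf.shape} does not fit in image {shape}")
        self.psf = psf
        self.shape = (int(h), int(w))
        self.bc = bc
        self.transfer: np.ndarray | None = None
        if bc == "periodic":
            self.transfer = _psf_transfer(psf, self.shape)

    def _check(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if u.shape != self.shape:
            raise ValueError(f"image shape {u.shape} does not match operator shape {self.shape}")
        return u

    def apply(self, u: np.ndarray) -> np.ndarray:
        """``K u``: convolution of ``u`` with the PSF."""
        u = self._check(u)
        if self.bc == "periodic":
            return np.real(np.fft.ifft2(np.fft.fft2(u) * self.transfer))
        return self._apply_symmetric(u, adjoint=False)

    def apply_adjoint(self, v: np.ndarray) -> np.ndarray:
        """``K^T v``: the exact adjoint under the Euclidean pairing."""
        v = self._check(v)
        if self.bc == "periodic":
            return np.real(np.fft.ifft2(np.fft.fft2(v) * np.conj(self.transfer)))
        return self._apply_symmetric(v, adjoint=True)

    # -- symmetric (Neumann) path -----------------------------------------
    def _pad_widths(self) -> tuple[tuple[int, int], tuple[int, int]]:
        kh, kw = self.psf.shape
        ah, aw = self.psf.anchor
        return ((kh - 1 - ah, ah), (kw - 1 - aw, aw))

    def _apply_symmetric(self, u: np.ndarray, adjoint: bool) -> np.ndarray:
        kf = self.psf.kernel[::-1, ::-1]
        (pt, pb), (pl, pr) = self._pad_widths()
        if not adjoint:
            up = np.pad(u, ((pt, pb), (pl, pr)), mode="symmetric")
            # valid correlation with the flipped kernel == convolution
            return convolve2d(up, self.psf.kernel, mode="valid")
        big = convolve2d(u, kf, mode="full")
        big = _fold_axis(big, self.shape[1], pl, pr, axis=1)
        return _fold_axis(big, self.shape[0], pt, pb, axis=0)


def _fold_axis(arr: np.ndarray, n: int, before: int, after: int, axis: int) -> np.ndarray:
    """Adjoint of ``np.pad(..., mode='symmetric')`` along one axis."""
    arr = np.moveaxis(arr, axis, 0)
    core = arr[before : before + n].copy()
    if before:
        core[:before] += arr[:before][::-1]
    if after:
        core[n - after :] += arr[before + n :][::-1]
    return np.moveaxis(core, 0, axis)


def _psf_transfer(psf: PSF, shape: tuple[int, int]) -> np.ndarray:
    """DFT of the zero-padded kernel shifted so its anchor sits at (0, 0)."""
    h, w = shape
    kh, kw = psf.shape
    big = np.zeros(shape)
    big[:kh, :kw] = psf.kernel
    ah, aw = psf.anchor
    big = np.roll(big, (-ah, -aw), axis=(0, 1))
    return np.fft.fft2(big)
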