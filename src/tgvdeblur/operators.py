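"""Discrete first-order differential operators and their exact adjoints.

Grid conventions used throughout the package
--------------------------------------------
* An image is a 2-D float array of shape ``(H, W)``.  The row index runs
  along the vertical (y) direction, the column index along the horizontal
  (x) direction.
* A vector field (e.g. the TGV auxiliary variable ``p``) is an array of
  shape ``(2, H, W)``; plane 0 is the x-component, plane 1 the
  y-component.
* A symmetric 2x2 tensor field (e.g. the symmetrized gradient
  ``eps(p)``) is an array of shape ``(3, H, W)`` storing the planes
  ``(t11, t22, t12)``.  The off-diagonal plane ``t12`` represents *two*
  equal matrix entries, so it is counted twice in inner products and in
  the pointwise Frobenius magnitude.

``D1`` is the forward difference along columns (x), ``D2`` the forward
difference along rows (y).  The divergences are defined as the exact
negative adjoints of the gradients under the Euclidean pairing (with the
doubled off-diagonal weight for tensors), so the discrete integration-
by-parts identities

    <grad u, v> = -<u, div v>,      <sym_grad p, y> = -<p, sym_div y>

hold to round-off for every supported boundary condition.

Two boundary conditions are supported:

* ``"periodic"`` (default): wrap-around differences.  All composite
  operators (Laplacians, normal-equation systems) are then diagonalized
  by the 2-D DFT; :func:`d1_symbol` / :func:`d2_symbol` expose the
  frequency symbols used by the solver's FFT fast path.
* ``"symmetric"``: Neumann-type differences (forward difference, zero at
  the far edge), with adjoints derived by summation by parts.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "grad",
    "div",
    "sym_grad",
    "sym_div",
    "d1",
    "d2",
    "d1_adj",
    "d2_adj",
    "d1_symbol",
    "d2_symbol",
    "image_inner",
    "vec_inner",
    "tensor_inner",
    "vec_norm1",
    "tensor_norm1",
    "vec_magnitude",
    "tensor_magnitude",
]

_BCS = ("periodic", "symmetric")


def _check_image(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {u.shape}")
    return u


def _check_bc(bc: str) -> None:
    if bc not in _BCS:
        raise ValueError(f"unknown boundary condition {bc!r}; expected one of {_BCS}")


# ---------------------------------------------------------------------------
# scalar building blocks: forward differences and their adjoints
# ---------------------------------------------------------------------------

def d1(u: np.ndarray, bc: str = "periodic") -> np.ndarray:
    """Forward difference along columns (the x/horizontal direction)."""
    _check_bc(bc)
    u = _check_image(u)
    if bc == "periodic":
        return np.roll(u, -1, axis=1) - u
    out = np.zeros_like(u)
    out[:, :-1] = u[:, 1:] - u[:, :-1]
    return out


def d2(u: np.ndarray, bc: str = "periodic") -> np.ndarray:
    """Forward difference along rows (the y/vertical direction)."""
    _check_bc(bc)
    u = _check_image(u)
    if bc == "periodic":
        return np.roll(u, -1, axis=0) - u
    out = np.zeros_like(u)
    out[:-1, :] = u[1:, :] - u[:-1, :]
    return out


def d1_adj(a: np.ndarray, bc: str = "periodic") -> np.ndarray:
    """Adjoint of :func:`d1`, i.e. ``D1^T a`` with ``<D1 u, a> = <u, D1^T a>``."""
    _check_bc(bc)
    a = _check_image(a)
    if bc == "periodic":
        return np.roll(a, 1, axis=1) - a
    out = np.zeros_like(a)
    out[:, 1:] = a[:, :-1]
    out[:, :-1] -= a[:, :-1]
    return out


def d2_adj(a: np.ndarray, bc: str = "periodic") -> np.ndarray:
    """Adjoint of :func:`d2`."""
    _check_bc(bc)
    a = _check_image(a)
    if bc == "periodic":
        return np.roll(a, 1, axis=0) - a
    out = np.zeros_like(a)
    out[1:, :] = a[:-1, :]
    out[:-1, :] -= a[:-1, :]
    return out


# ---------------------------------------------------------------------------
# gradient / divergence on images and vector fields
# ---------------------------------------------------------------------------

def grad(u: np.ndarray, bc: str = "periodic") -> np.ndarray:
    """Discrete gradient of an image: ``(D1 u, D2 u)`` stacked as (2, H, W)."""
    u = _check_image(u)
    return np.stack([d1(u, bc), d2(u, bc)])


def div(v: np.ndarray, bc: str = "periodic") -> np.ndarray:
    """Discrete divergence of a vector field, defined as ``-grad^T``.

    ``div(grad(u))`` is the 5-point discrete Laplacian of ``u``.
    """
    v = _as_vec(v)
    return -(d1_adj(v[0], bc) + d2_adj(v[1], bc))


def sym_grad(p: np.ndarray, bc: str = "periodic") -> np.ndarray:
    """Symmetrized gradient of a vector field.

    Returns the tensor planes ``(D1 p1, D2 p2, (D2 p1 + D1 p2)/2)``,
    the symmetric part of the Jacobian of ``p``.
    """
    p = _as_vec(p)
    t11 = d1(p[0], bc)
    t22 = d2(p[1], bc)
    t12 = 0.5 * (d2(p[0], bc) + d1(p[1], bc))
    return np.stack([t11, t22, t12])


def sym_div(y: np.ndarray, bc: str = "periodic") -> np.ndarray:
    """Divergence of a symmetric tensor field, defined as ``-sym_grad^T``.

    The adjoint is taken under the pairing in which the off-diagonal
    plane counts twice, so ``<sym_grad p, y> = -<p, sym_div y>`` exactly.
    """
    y = _as_tensor(y)
    c1 = -(d1_adj(y[0], bc) + d2_adj(y[2], bc))
    c2 = -(d1_adj(y[2], bc) + d2_adj(y[1], bc))
    return np.stack([c1, c2])


def _as_vec(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 3 or v.shape[0] != 2:
        raise ValueError(f"expected a vector field of shape (2, H, W), got {v.shape}")
    return v


def _as_tensor(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 3 or y.shape[0] != 3:
        raise ValueError(f"expected a tensor field of shape (3, H, W), got {y.shape}")
    return y


# ---------------------------------------------------------------------------
# Fourier symbols (periodic bc only)
# ---------------------------------------------------------------------------

def d1_symbol(shape: tuple[int, int]) -> np.ndarray:
    """DFT symbol of ``d1`` under periodic bc: ``exp(2 pi i k/W) - 1``."""
    _, w = shape
    k = np.arange(w)
    sym = np.exp(2j * np.pi * k / w) - 1.0
    return np.broadcast_to(sym[None, :], shape).copy()


def d2_symbol(shape: tuple[int, int]) -> np.ndarray:
    """DFT symbol of ``d2`` under periodic bc."""
    h, _ = shape
    k = np.arange(h)
    sym = np.exp(2j * np.pi * k / h) - 1.0
    return np.broadcast_to(sym[:, None], shape).copy()


# ---------------------------------------------------------------------------
# inner products and L1-type norms
# ---------------------------------------------------------------------------

def image_inner(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(a * b))


def vec_inner(v: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(v * w))


def tensor_inner(y: np.ndarray, s: np.ndarray) -> float:
    """Tensor pairing with the off-diagonal plane counted twice."""
    y = _as_tensor(y)
    s = _as_tensor(s)
    return float(np.sum(y[0] * s[0] + y[1] * s[1] + 2.0 * y[2] * s[2]))


def vec_magnitude(v: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean magnitude of a vector field."""
    v = _as_vec(v)
    return np.sqrt(v[0] ** 2 + v[1] ** 2)


def tensor_magnitude(y: np.ndarray) -> np.ndarray:
    """Pointwise Frobenius magnitude ``sqrt(t11^2 + t22^2 + 2 t12^2)``."""
    y = _as_tensor(y)
    return np.sqrt(y[0] ** 2 + y[1] ** 2 + 2.0 * y[2] ** 2)


def vec_norm1(v: np.ndarray) -> float:
    """Isotropic L1 norm: sum over pixels of the Euclidean magnitude."""
    return float(np.sum(vec_magnitude(v)))


def tensor_norm1(y: np.ndarray) -> float:
    """Isotropic L1 norm of a tensor field (Frobenius magnitude summed)."""
    return float(np.sum(tensor_magnitude(y)))
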