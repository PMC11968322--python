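"""2D Zernike expansion of disk images and the complementarity distance.

The Zernike functions ``Z_nm(r, theta) = R_nm(r) * exp(i m theta)`` with
``0 <= m <= n`` and ``n - m`` even form a complete orthogonal basis on the
unit disk::

    integral_disk Z_nm conj(Z_n'm') dA = pi / (n + 1) * delta_nn' delta_mm'

A disk image ``f`` therefore expands as ``f = sum c_nm Z_nm`` with
``c_nm = (n + 1) / pi * integral f conj(Z_nm) dA``, estimated here by a
least-squares fit of the truncated expansion to the masked pixels (see
:func:`decompose`).  Because the image is real, coefficients with
negative m are redundant (``c_{n,-m} = conj(c_nm)``) and only m >= 0 is
stored; reconstruction and Parseval sums weight m > 0 terms by two.

The modulus ``|c_nm|`` is invariant under rotation of the image about the
disk centre: rotating by alpha multiplies ``c_nm`` by ``exp(-i m alpha)``,
a pure phase.  The vector of moduli is the rotation-invariant descriptor,
and the complementarity distance between two patches is the Euclidean
distance between their descriptor vectors::

    D_z = sqrt( sum_nm (|c_nm| - |c'_nm|)^2 )

Radial polynomials are evaluated through Jacobi polynomials,
``R_nm(r) = (-1)^((n-m)/2) r^m P_{(n-m)/2}^{(m,0)}(1 - 2 r^2)``, which is
numerically stable well beyond order 40 (scipy evaluates Jacobi
polynomials by recurrence).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.special import eval_jacobi

from .errors import DescriptorMismatchError
from .projection import DiskImage

DistanceMode = Literal["modulus", "modulus_squared"]

#: Relative singular-value cutoff of the least-squares fit in
#: :func:`decompose`.  On a full disk grid the design matrix is well
#: conditioned (smallest/largest singular value ~ 0.17 at G = 64,
#: order 20) and the cutoff is inactive; on sparse patch masks it damps
#: the near-degenerate basis directions that would otherwise amplify
#: pixel noise.
LSTSQ_RCOND = 3e-2


def zernike_indices(order: int) -> list[tuple[int, int]]:
    """Valid (n, m) pairs up to ``order`` in lexicographic order.

    m runs over 0 <= m <= n with n - m even; the count is
    ``floor(order/2 + 1) * ceil(order/2 + 1)``.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    return [(n, m) for n in range(order + 1) for m in range(n % 2, n + 1, 2)]


def radial_polynomial(n: int, m: int, r) -> np.ndarray | float:
    """Zernike radial polynomial R_nm evaluated at r (scalar or array).

    Requires 0 <= m <= n with n - m even.  Equals the classical
    factorial-sum definition; implemented via the Jacobi-polynomial
    identity for numerical stability at high order.
    """
    if m < 0 or m > n or (n - m) % 2 != 0:
        raise ValueError(f"invalid Zernike indices (n={n}, m={m})")
    r = np.asarray(r, dtype=float)
    k = (n - m) // 2
    out = (-1.0) ** k * r**m * eval_jacobi(k, m, 0, 1.0 - 2.0 * r**2)
    return out if out.shape else float(out)


def zernike_basis(n: int, m: int, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Complex basis function Z_nm(r, theta) = R_nm(r) exp(i m theta)."""
    return radial_polynomial(n, m, r) * np.exp(1j * m * theta)


@dataclass
class ZernikeDescriptor:
    """Complex Zernike coefficients of a disk image up to ``order``.

    ``coefficients[k]`` corresponds to ``indices[k]`` (lexicographic
    (n, m)); ``invariants_vector`` is the rotation-invariant modulus
    vector in the same order.
    """

    order: int
    coefficients: np.ndarray  # complex, aligned with zernike_indices(order)
    grid_size: int = 0
    pixel_area: float = 0.0

    def __post_init__(self) -> None:
        expected = len(zernike_indices(self.order))
        if len(self.coefficients) != expected:
            raise DescriptorMismatchError(
                f"order {self.order} requires {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )

    @property
    def indices(self) -> list[tuple[int, int]]:
        return zernike_indices(self.order)

    @property
    def invariants_vector(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def truncate(self, order: int) -> "ZernikeDescriptor":
        """Descriptor restricted to n <= order (coefficients are unchanged:
        each c_nm is an independent projection onto its basis function)."""
        if order > self.order:
            raise ValueError("cannot truncate to a higher order")
        keep = [k for k, (n, _) in enumerate(self.indices) if n <= order]
        return ZernikeDescriptor(
            order=order,
            coefficients=self.coefficients[keep],
            grid_size=self.grid_size,
            pixel_area=self.pixel_area,
        )

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["n", "m", "re", "im", "modulus"])
            for (n, m), c in zip(self.indices, self.coefficients):
                w.writerow([n, m, f"{c.real:.12g}", f"{c.imag:.12g}", f"{abs(c):.12g}"])

    @classmethod
    def read_csv(cls, path: str | Path) -> "ZernikeDescriptor":
        rows = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                rows.append(((int(row["n"]), int(row["m"])),
                             complex(float(row["re"]), float(row["im"]))))
        order = max(n for (n, _), _ in rows)
        expected = zernike_indices(order)
        got = [idx for idx, _ in rows]
        if got != expected:
            raise DescriptorMismatchError(f"coefficient file {path} has an "
                                          "incomplete or misordered index set")
        return cls(order=order, coefficients=np.array([c for _, c in rows]))


def decompose(image: DiskImage, order: int = 20) -> ZernikeDescriptor:
    """Fit the Zernike expansion to a disk image up to ``order``.

    The coefficients solve the least-squares problem

        min_c  sum_pixels ( f - sum_nm w_m Re(c_nm Z_nm) )^2

    over masked pixels whose centres lie inside the unit disk (w_0 = 1,
    w_m = 2 for m > 0, the conjugate-pair weight of a real image).  This
    is the continuous projection ``c_nm = (n+1)/pi * integral f conj(Z_nm)
    dA`` premultiplied by the inverse of the discrete Gram matrix of the
    sampled basis; on a fine full-disk grid the Gram matrix approaches
    orthogonality and the fit reduces to the textbook projection, while on
    a pixelated or partially covered disk the fit removes the grid-induced
    cross-talk between basis functions.  Exact for band-limited images
    sampled at pixel centres; unhit pixels are treated as missing data.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    G = image.grid_size
    cx, cy = image.pixel_centers()
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    sel = image.mask & (np.hypot(X, Y) <= 1.0)
    r = np.hypot(X[sel], Y[sel])
    theta = np.arctan2(Y[sel], X[sel])
    f = image.values[sel]
    pairs = zernike_indices(order)

    if f.size == 0:  # all-zero/empty image: zero descriptor
        return ZernikeDescriptor(
            order=order,
            coefficients=np.zeros(len(pairs), dtype=complex),
            grid_size=G,
            pixel_area=image.pixel_area,
        )

    # real design matrix: a_nm multiplies w R cos(m theta),
    # b_nm multiplies -w R sin(m theta), with c_nm = a_nm + i b_nm
    cols = []
    for n, m in pairs:
        w = 1.0 if m == 0 else 2.0
        rad = w * radial_polynomial(n, m, r)
        cols.append(rad * np.cos(m * theta))
        if m > 0:
            cols.append(-rad * np.sin(m * theta))
    A = np.column_stack(cols)
    sol, *_ = np.linalg.lstsq(A, f, rcond=LSTSQ_RCOND)

    coeffs = np.empty(len(pairs), dtype=complex)
    k = 0
    for j, (n, m) in enumerate(pairs):
        if m == 0:
            coeffs[j] = sol[k]
            k += 1
        else:
            coeffs[j] = sol[k] + 1j * sol[k + 1]
            k += 2
    return ZernikeDescriptor(
        order=order,
        coefficients=coeffs,
        grid_size=G,
        pixel_area=image.pixel_area,
    )


def reconstruct(descriptor: ZernikeDescriptor, grid_size: int) -> DiskImage:
    """Evaluate the truncated expansion on a fresh disk grid.

    Real images are recovered as ``sum_m>=0 w_m Re(c_nm Z_nm)`` with w_0 = 1
    and w_m = 2 for m > 0 (the conjugate-pair weight).
    """
    c = -1.0 + (np.arange(grid_size) + 0.5) * (2.0 / grid_size)
    X, Y = np.meshgrid(c, c, indexing="ij")
    R = np.hypot(X, Y)
    mask = R <= 1.0
    r = R[mask]
    theta = np.arctan2(Y[mask], X[mask])
    vals = np.zeros(r.shape)
    for (n, m), cf in zip(descriptor.indices, descriptor.coefficients):
        w = 1.0 if m == 0 else 2.0
        vals += w * np.real(cf * zernike_basis(n, m, r, theta))
    out = np.zeros((grid_size, grid_size))
    out[mask] = vals
    return DiskImage(grid_size=grid_size, values=out, mask=mask)


def zernike_distance(
    a: ZernikeDescriptor,
    b: ZernikeDescriptor,
    mode: DistanceMode = "modulus",
) -> float:
    """Euclidean distance between the rotation-invariant descriptors.

    ``mode='modulus'`` differences the coefficient moduli (a true metric on
    descriptor vectors); ``mode='modulus_squared'`` differences squared
    moduli instead.  The two are monotonically related rankings against a
    fixed reference only through the moduli themselves; both are exposed
    for fidelity experiments.
    """
    if a.order != b.order:
        raise DescriptorMismatchError(
            f"descriptor orders differ: {a.order} vs {b.order}"
        )
    va, vb = a.invariants_vector, b.invariants_vector
    if mode == "modulus_squared":
        va, vb = va**2, vb**2
    elif mode != "modulus":
        raise ValueError(f"unknown distance mode {mode!r}")
    return float(np.sqrt(np.sum((va - vb) ** 2)))
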