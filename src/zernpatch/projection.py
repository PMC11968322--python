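"""Project an oriented patch onto a discretized unit disk.

A cone with vertex on the z-axis below the patch and a fixed half-angle
(default 45 degrees) is fitted so it exactly contains the patch.  Each
patch point is then mapped to the plane by its (x, y) coordinates, scaled
by the patch's maximal in-plane radius so the patch fills the unit disk,
and every pixel stores the mean Euclidean distance from its contributing
points to the cone vertex.  The resulting depth map encodes the local
curvature of the surface as seen from the vertex.

The vertex is placed on the negative-z side for both orientation signs.
Template (up) and target (down) patches of a complementary pair occupy
nearly the same geometry in the common oriented frame, so viewing both
from below produces nearly identical maps; this is what turns geometric
complementarity into descriptor similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConeFitError
from .patches import OrientedPatch

_ANGLE_TOL_DEG = 1e-6


@dataclass(frozen=True)
class ConeFrame:
    """Cone containing the patch: vertex on the z-axis, fixed half-angle."""

    vertex: np.ndarray  # (3,), on the z-axis
    half_angle_deg: float


@dataclass
class DiskImage:
    """Scalar map on a G x G Cartesian grid covering [-1, 1]^2.

    ``values[i, j]`` corresponds to the pixel centred at
    ``(x_i, y_j) = (-1 + (i + 0.5) * 2/G, -1 + (j + 0.5) * 2/G)``.
    ``mask`` marks pixels whose centre lies inside the unit circle and that
    received at least one patch point; values outside the mask are zero.
    ``n_contributors`` counts the points binned into each pixel (every
    patch point is assigned to exactly one pixel).
    """

    grid_size: int
    values: np.ndarray
    mask: np.ndarray
    n_contributors: np.ndarray | None = None

    @property
    def pixel_area(self) -> float:
        return (2.0 / self.grid_size) ** 2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x and y pixel-centre coordinates."""
        c = -1.0 + (np.arange(self.grid_size) + 0.5) * (2.0 / self.grid_size)
        return c, c

    def write_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.10g")

    @classmethod
    def from_function(cls, f, grid_size: int) -> "DiskImage":
        """Sample ``f(r, theta)`` at pixel centres inside the unit disk."""
        c = -1.0 + (np.arange(grid_size) + 0.5) * (2.0 / grid_size)
        X, Y = np.meshgrid(c, c, indexing="ij")
        R = np.hypot(X, Y)
        mask = R <= 1.0
        vals = np.zeros((grid_size, grid_size))
        vals[mask] = f(R[mask], np.arctan2(Y[mask], X[mask]))
        return cls(grid_size=grid_size, values=vals, mask=mask)


def _max_angle_deg(points: np.ndarray, z_v: float) -> float:
    """Largest angle (deg) between the +z axis and vertex-to-point vectors."""
    rho = np.hypot(points[:, 0], points[:, 1])
    dz = points[:, 2] - z_v
    return float(np.degrees(np.arctan2(rho, dz)).max())


def fit_cone(patch: OrientedPatch, half_angle_deg: float = 45.0) -> ConeFrame:
    """Place the cone vertex below the patch so that it exactly contains it.

    The vertex (0, 0, z_v) is found by bisection on z_v such that the
    maximum angle between the cone axis (+z) and any vertex-to-point vector
    equals ``half_angle_deg`` to within 1e-6 degrees.  For a flat patch of
    radius rho_max at z = 0 this gives z_v = -rho_max / tan(half_angle).
    """
    if not (0.0 < half_angle_deg < 90.0):
        raise ValueError("cone half-angle must be in (0, 90) degrees")
    pts = patch.points
    rho = np.hypot(pts[:, 0], pts[:, 1])
    rho_max = float(rho.max())
    if rho_max <= 0.0:
        raise ConeFitError("patch has no lateral extent; cone fit undefined")
    z_min = float(pts[:, 2].min())
    tan_half = np.tan(np.radians(half_angle_deg))

    # Bracket the root of f(z_v) = max_angle(z_v) - half_angle, which is
    # monotone increasing in z_v for a vertex below the patch.
    hi = z_min
    step = rho_max / tan_half + 1.0
    lo = z_min - step
    for _ in range(200):
        if _max_angle_deg(pts, lo) < half_angle_deg:
            break
        lo -= step
        step *= 2.0
    else:
        raise ConeFitError("cannot bracket the cone vertex below the patch")
    if _max_angle_deg(pts, hi) <= half_angle_deg:
        raise ConeFitError("patch geometry admits no containing cone at this angle")

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _max_angle_deg(pts, mid) < half_angle_deg:
            lo = mid
        else:
            hi = mid
        if abs(_max_angle_deg(pts, lo) - half_angle_deg) < _ANGLE_TOL_DEG:
            break
    z_v = lo  # largest tested z with max angle still <= half_angle
    return ConeFrame(vertex=np.array([0.0, 0.0, z_v]), half_angle_deg=half_angle_deg)


def project_to_disk(
    patch: OrientedPatch, cone: ConeFrame, grid_size: int = 64
) -> DiskImage:
    """Bin patch points into the unit-disk grid with cone-distance weights.

    Each point (x, y, z) maps to (x, y) / rho_max; the containing pixel
    (half-open bins, lower edge inclusive) accumulates the Euclidean
    distance from the point to the cone vertex, and the final pixel value
    is the mean over its contributors.
    """
    pts = patch.points
    rho = np.hypot(pts[:, 0], pts[:, 1])
    rho_max = float(rho.max())
    if rho_max <= 0.0:
        raise ConeFitError("patch has no lateral extent; projection undefined")
    uv = pts[:, :2] / rho_max
    dist = np.linalg.norm(pts - cone.vertex, axis=1)

    G = grid_size
    ij = np.floor((uv + 1.0) * 0.5 * G).astype(int)
    np.clip(ij, 0, G - 1, out=ij)  # points at u = 1 land in the last pixel

    sums = np.zeros((G, G))
    counts = np.zeros((G, G), dtype=int)
    np.add.at(sums, (ij[:, 0], ij[:, 1]), dist)
    np.add.at(counts, (ij[:, 0], ij[:, 1]), 1)

    c = -1.0 + (np.arange(G) + 0.5) * (2.0 / G)
    X, Y = np.meshgrid(c, c, indexing="ij")
    inside = np.hypot(X, Y) <= 1.0
    mask = (counts > 0) & inside
    values = np.zeros((G, G))
    values[mask] = sums[mask] / counts[mask]
    return DiskImage(grid_size=G, values=values, mask=mask, n_contributors=counts)
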