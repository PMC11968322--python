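"""Interface detection, circular patch extraction, and patch orientation.

The binding region is the set of surface points of one partner lying within
a distance cutoff (default 3 A) of the other partner's surface, together
with the residues owning those points.  A single circular patch per side is
cut around the surface point nearest the interface centroid, then rigidly
moved so its centre sits at the origin and its mean normal points along +z
(template convention) or -z (target convention).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegeneratePatchError, NoInterfaceError, OrientationError
from .surface import SurfacePointCloud

#: Patches with fewer points than this cannot support the disk expansion.
MIN_PATCH_POINTS = 16

Side = Literal["template", "target"]
Sign = Literal["up", "down"]


@dataclass
class InterfaceRegion:
    """Index sets of the mutually-close surface points of the two partners."""

    template_cloud: SurfacePointCloud
    target_cloud: SurfacePointCloud
    template_points: np.ndarray  # sorted indices into template_cloud
    target_points: np.ndarray
    cutoff: float

    @property
    def template_residues(self) -> set[tuple[str, int, str]]:
        ids = self.template_cloud.residue_ids()
        return {ids[i] for i in self.template_points}

    @property
    def target_residues(self) -> set[tuple[str, int, str]]:
        ids = self.target_cloud.residue_ids()
        return {ids[i] for i in self.target_points}

    @property
    def is_empty(self) -> bool:
        return len(self.template_points) == 0 and len(self.target_points) == 0

    def write_residues_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["chain", "resnum", "icode", "side"])
            for side, residues in (
                ("template", self.template_residues),
                ("target", self.target_residues),
            ):
                for chain, num, icode in sorted(residues):
                    w.writerow([chain, num, icode, side])


@dataclass
class Patch:
    """A circular piece of surface: all cloud points within ``radius`` of ``center``."""

    cloud: SurfacePointCloud
    point_indices: np.ndarray
    center: np.ndarray
    radius: float

    def __len__(self) -> int:
        return len(self.point_indices)

    @property
    def positions(self) -> np.ndarray:
        return self.cloud.positions[self.point_indices]

    @property
    def normals(self) -> np.ndarray:
        return self.cloud.normals[self.point_indices]


@dataclass
class OrientedPatch:
    """A patch in its canonical frame: centre at origin, mean normal on +/-z.

    ``rotation`` and ``origin_shift`` record the rigid motion applied, so
    ``points = (original - origin_shift) @ rotation.T``.
    """

    points: np.ndarray
    normals: np.ndarray
    mean_normal_sign: Sign
    rotation: np.ndarray
    origin_shift: np.ndarray

    def __len__(self) -> int:
        return len(self.points)

    @property
    def mean_normal(self) -> np.ndarray:
        m = self.normals.mean(axis=0)
        return m / np.linalg.norm(m)


def find_interface(
    template: SurfacePointCloud,
    target: SurfacePointCloud,
    cutoff: float = 3.0,
) -> InterfaceRegion:
    """Exact nearest-neighbour interface detection at ``cutoff`` Angstrom.

    A point belongs to the interface iff its nearest point on the other
    partner's surface is strictly closer than ``cutoff``.
    """
    if len(template) == 0 or len(target) == 0:
        raise NoInterfaceError("both surface clouds must be non-empty")
    t_tree = cKDTree(target.positions)
    d_t, _ = t_tree.query(template.positions, k=1)
    template_idx = np.flatnonzero(d_t < cutoff)
    s_tree = cKDTree(template.positions)
    d_s, _ = s_tree.query(target.positions, k=1)
    target_idx = np.flatnonzero(d_s < cutoff)
    return InterfaceRegion(
        template_cloud=template,
        target_cloud=target,
        template_points=template_idx,
        target_points=target_idx,
        cutoff=cutoff,
    )


def interface_patch_center(region: InterfaceRegion, side: Side) -> np.ndarray:
    """The surface point of ``side`` closest to that side's interface centroid.

    Ties are broken toward the lowest point index, so the centre is a
    deterministic, actual surface point.
    """
    if side == "template":
        cloud, idx = region.template_cloud, region.template_points
    else:
        cloud, idx = region.target_cloud, region.target_points
    if len(idx) == 0:
        raise NoInterfaceError(f"no {side} interface points at cutoff {region.cutoff} A")
    pts = cloud.positions[idx]
    centroid = pts.mean(axis=0)
    best = int(np.argmin(np.linalg.norm(pts - centroid, axis=1)))
    return cloud.positions[idx[best]].copy()


def extract_patch(
    cloud: SurfacePointCloud,
    center: np.ndarray,
    radius: float = 8.0,
    min_points: int = MIN_PATCH_POINTS,
) -> Patch:
    """All cloud points within a Euclidean ball of ``radius`` around ``center``."""
    if radius <= 0:
        raise ValueError("patch radius must be positive")
    d = np.linalg.norm(cloud.positions - np.asarray(center, dtype=float), axis=1)
    idx = np.flatnonzero(d <= radius)
    if len(idx) < min_points:
        raise DegeneratePatchError(
            f"patch has {len(idx)} points; at least {min_points} required"
        )
    return Patch(cloud=cloud, point_indices=idx, center=np.asarray(center, float), radius=radius)


def rotation_to_axis(mean_normal: np.ndarray, sign: Sign) -> np.ndarray:
    """Minimal proper rotation taking ``mean_normal`` to +z (up) or -z (down).

    The antiparallel case is resolved by a 180-degree rotation about x.
    """
    n = np.asarray(mean_normal, dtype=float)
    n = n / np.linalg.norm(n)
    t = np.array([0.0, 0.0, 1.0 if sign == "up" else -1.0])
    c = float(np.dot(n, t))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    axis = np.cross(n, t)
    axis /= np.linalg.norm(axis)
    s = np.sqrt(max(0.0, 1.0 - c * c))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def orient_point_set(
    positions: np.ndarray,
    normals: np.ndarray,
    sign: Sign,
    center: np.ndarray | None = None,
) -> OrientedPatch:
    """Rigidly move a point set so ``center`` is the origin and the mean
    normal lies along the requested z direction."""
    m = normals.mean(axis=0)
    norm = np.linalg.norm(m)
    if norm < 1e-6:
        raise OrientationError("mean normal vanishes; patch cannot be oriented")
    if center is None:
        center = positions.mean(axis=0)
    R = rotation_to_axis(m / norm, sign)
    return OrientedPatch(
        points=(positions - center) @ R.T,
        normals=normals @ R.T,
        mean_normal_sign=sign,
        rotation=R,
        origin_shift=np.asarray(center, dtype=float),
    )


def orient_patch(patch: Patch, sign: Sign = "up") -> OrientedPatch:
    """Orient a surface patch with its centre at the origin.

    The template side uses ``sign='up'`` (mean normal to +z), the target
    side ``sign='down'``; complementary patches then land in a common frame
    in which one surface is approximately the continuation of the other.
    """
    return orient_point_set(patch.positions, patch.normals, sign, center=patch.center)
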