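"""Solvent-accessible surface sampling as an oriented point cloud.

Each atom contributes a deterministic Fibonacci lattice of candidate points
on its solvent-inflated sphere (radius + probe).  Candidates that fall
strictly inside any other atom's inflated sphere are occluded and removed;
the survivors approximate the solvent-accessible surface, each carrying the
radial direction from its generating atom as an outward normal.

The lattice is generated once in a fixed global orientation and translated
to every atom centre, so the sampling is exactly equivariant under
translations of the structure and equivariant under rotations up to the
lattice resolution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError
from .structure_io import Structure

#: Tolerance of the strict-interior occlusion test: points exactly on a
#: neighbour's inflated sphere are kept.
OCCLUSION_EPS = 1e-9


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` near-uniform unit vectors on the sphere (golden spiral).

    Deterministic; the same lattice is reused for every atom.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


@dataclass
class SurfacePointCloud:
    """Oriented point samples of one partner's solvent-accessible surface.

    Attributes
    ----------
    positions, normals:
        (N, 3) arrays; normals are unit outward vectors.
    atom_indices:
        (N,) index of the generating atom in ``structure``.
    """

    positions: np.ndarray
    normals: np.ndarray
    atom_indices: np.ndarray
    structure: Structure
    probe_radius: float
    n_sphere_points: int

    def __len__(self) -> int:
        return len(self.positions)

    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Residue id (chain, number, icode) owning each surface point."""
        atoms = self.structure.atoms
        return [atoms[i].residue_id for i in self.atom_indices]

    def write_csv(self, path: str | Path) -> None:
        """Dump points as x,y,z,nx,ny,nz,chain,resnum for inspection."""
        atoms = self.structure.atoms
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", "z", "nx", "ny", "nz", "chain", "resnum"])
            for p, nrm, ai in zip(self.positions, self.normals, self.atom_indices):
                a = atoms[ai]
                w.writerow(
                    [f"{p[0]:.4f}", f"{p[1]:.4f}", f"{p[2]:.4f}",
                     f"{nrm[0]:.6f}", f"{nrm[1]:.6f}", f"{nrm[2]:.6f}",
                     a.chain_id, a.res_num]
                )


def compute_surface(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 256,
) -> SurfacePointCloud:
    """Sample the solvent-accessible surface of ``structure``.

    Parameters
    ----------
    probe_radius:
        Solvent probe radius in Angstrom (water: 1.4).
    n_sphere_points:
        Lattice points per atom before occlusion.

    Returns a deterministic cloud: same structure and parameters give the
    same points in the same order.
    """
    if len(structure) == 0:
        raise EmptyStructureError("cannot compute a surface for an empty structure")
    centers = structure.coords
    radii = structure.radii
    inflated = radii + probe_radius
    lattice = fibonacci_sphere(n_sphere_points)

    tree = cKDTree(centers)
    max_reach = inflated.max()

    positions = []
    normals = []
    atom_indices = []
    for i in range(len(structure)):
        pts = centers[i] + inflated[i] * lattice
        # candidate occluders: any atom whose inflated sphere can reach these points
        neigh = tree.query_ball_point(centers[i], inflated[i] + max_reach)
        neigh = [j for j in neigh if j != i]
        keep = np.ones(len(pts), dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - centers[j], axis=1)
            keep &= d >= inflated[j] - OCCLUSION_EPS
        if keep.any():
            positions.append(pts[keep])
            normals.append(lattice[keep])
            atom_indices.append(np.full(int(keep.sum()), i, dtype=int))

    if positions:
        pos = np.concatenate(positions)
        nrm = np.concatenate(normals)
        ai = np.concatenate(atom_indices)
    else:  # fully buried structure: no exposed points
        pos = np.empty((0, 3))
        nrm = np.empty((0, 3))
        ai = np.empty(0, dtype=int)
    return SurfacePointCloud(
        positions=pos,
        normals=nrm,
        atom_indices=ai,
        structure=structure,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )
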