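"""Synthetic inputs with known ground truth.

Three families of fixtures cover the pipeline at different depths:

* ``make_toy_complex`` writes a small two-chain PDB in which chain B is the
  exact mirror image of chain A across the contact plane, so the two
  molecular surfaces are perfect molds of one another separated by a known
  gap.  It exercises parsing, surface building, interface detection and
  the full pipeline without any real protein.
* ``make_bump_pair`` builds a Gaussian bump and its complementary mold as
  oriented patches directly (bypassing the surface stage), with optional
  positional noise.  By construction the two disk projections nearly
  coincide, so their Zernike distance is small.
* ``make_random_patch`` builds a smooth random height field (a sum of five
  Gaussians) as an uncorrelated negative control.

All fixtures are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .patches import OrientedPatch, orient_point_set

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def sunflower_disk(n: int, radius: float = 1.0) -> np.ndarray:
    """n deterministic, near-uniform sample points on a disk (sunflower layout)."""
    k = np.arange(n, dtype=float)
    rho = radius * np.sqrt((k + 0.5) / n)
    theta = k * GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])


def _gaussian_field_patch(
    xy: np.ndarray,
    amps: np.ndarray,
    centers: np.ndarray,
    sigmas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Heights and upward unit normals of z = sum_j a_j exp(-|p-mu_j|^2 / 2 s_j^2)."""
    z = np.zeros(len(xy))
    gx = np.zeros(len(xy))
    gy = np.zeros(len(xy))
    for a, mu, s in zip(amps, centers, sigmas):
        d = xy - mu
        g = a * np.exp(-np.sum(d**2, axis=1) / (2.0 * s**2))
        z += g
        gx += -d[:, 0] / s**2 * g
        gy += -d[:, 1] / s**2 * g
    normals = np.column_stack([-gx, -gy, np.ones(len(xy))])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return z, normals


def make_bump_pair(
    amplitude: float = 1.5,
    sigma: float = 2.5,
    patch_radius: float = 8.0,
    n_points: int = 400,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[OrientedPatch, OrientedPatch]:
    """A Gaussian bump and its exact mold as a pre-oriented (up, down) pair.

    Both sides sample the surface ``z = A exp(-(x^2+y^2) / 2 sigma^2)`` over
    a disk of ``patch_radius``; the mold carries inverted normals.  Each
    side receives an independent draw of isotropic Gaussian positional
    noise with standard deviation ``noise_sd`` (Angstrom).
    """
    if amplitude < 0 or sigma <= 0 or patch_radius <= 0:
        raise ValueError("amplitude must be >= 0; sigma and patch_radius positive")
    rng = np.random.default_rng(seed)
    xy = sunflower_disk(n_points, patch_radius)
    amps = np.array([amplitude])
    cts = np.zeros((1, 2))
    sgs = np.array([sigma])

    sides = []
    for sign, flip in (("up", 1.0), ("down", -1.0)):
        z, normals = _gaussian_field_patch(xy, amps, cts, sgs)
        pts = np.column_stack([xy, z])
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape) if noise_sd > 0 else pts
        sides.append(
            orient_point_set(pts, flip * normals, sign, center=np.zeros(3))
        )
    return sides[0], sides[1]


def make_random_patch(
    roughness: float = 1.5,
    patch_radius: float = 8.0,
    n_points: int = 400,
    seed: int = 0,
) -> OrientedPatch:
    """A smooth random surface patch oriented up (negative control).

    The height field is a sum of five Gaussians with random centres inside
    the disk, amplitudes ~ N(0, roughness^2) and widths drawn between 0.2
    and 0.45 of the patch radius.
    """
    if patch_radius <= 0:
        raise ValueError("patch_radius must be positive")
    rng = np.random.default_rng(seed)
    xy = sunflower_disk(n_points, patch_radius)
    n_bumps = 5
    amps = rng.normal(0.0, max(roughness, 1e-12), size=n_bumps)
    if roughness == 0:
        amps = np.zeros(n_bumps)
    ang = rng.uniform(0, 2 * np.pi, n_bumps)
    rad = patch_radius * np.sqrt(rng.uniform(0, 1, n_bumps))
    cts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    sgs = rng.uniform(0.2, 0.45, n_bumps) * patch_radius
    z, normals = _gaussian_field_patch(xy, amps, cts, sgs)
    return orient_point_set(
        np.column_stack([xy, z]), normals, "up", center=np.zeros(3)
    )


def _strand_atoms(
    n_res: int, gap: float, rng: np.random.Generator, jitter: float
) -> list[tuple[int, str, str, np.ndarray]]:
    """Chain A of the toy complexes: a jittered strand of pseudo-residues.

    Each residue carries three heavy atoms (OG at the contact face, CB and
    CA behind it).  The contact atoms are placed so the chain's
    solvent-inflated surface reaches up to y = -gap/2.
    """
    probe = 1.4
    r_o = 1.52  # oxygen vdW radius; OG is the contact atom
    contact_y = -(gap / 2.0 + r_o + probe)
    atoms = []
    spacing = 3.8
    for i in range(n_res):
        x = spacing * i
        jx, jz = rng.normal(0.0, jitter, 2)
        jy = abs(rng.normal(0.0, jitter))
        og = np.array([x + jx, contact_y - jy, jz])
        cb = og + np.array([0.4, -1.8, 0.9])
        ca = og + np.array([-0.5, -2.9, -0.4])
        atoms.append((i + 1, "OG", "O", og))
        atoms.append((i + 1, "CB", "C", cb))
        atoms.append((i + 1, "CA", "C", ca))
    return atoms


def _pdb_text(chains: list[tuple[str, str, list[tuple[int, str, str, np.ndarray]]]]) -> str:
    """Render (chain id, residue name, atom list) groups as PDB ATOM records."""
    lines = []
    serial = 1
    for chain_id, resname, atoms in chains:
        for resnum, name, element, coord in atoms:
            x, y, z = coord
            lines.append(
                f"ATOM  {serial:>5} {name:<4} {resname:<3} {chain_id}{resnum:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2}"
            )
            serial += 1
        lines.append(f"TER   {serial:>5}      {resname:<3} {chain_id}{atoms[-1][0]:>4}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_complex(
    n_res_per_chain: int = 3,
    gap: float = 2.0,
    seed: int = 0,
    jitter: float = 0.35,
) -> str:
    """PDB text of a two-chain pseudo-protein with facing strands.

    Chain A is a strand of ``n_res_per_chain`` pseudo-residues (OG, CB, CA;
    three heavy atoms each) with seeded positional jitter; chain B is chain
    A reflected across the contact plane y = 0.  The contact atoms are
    placed so the closest approach between the two solvent-inflated
    surfaces is approximately ``gap`` Angstrom: the interface at the 3 A
    cutoff is populated for ``gap`` < 3 and empty for large gaps.

    The reflection guarantees a geometrically matched, touching pair for
    parsing, interface and determinism tests.  It does *not* make the two
    surfaces complementary molds (a reflected bump faces a bump, not a
    dimple); use :func:`make_mold_complex` for a complementarity-positive
    complex.
    """
    if n_res_per_chain < 1:
        raise ValueError("need at least one residue per chain")
    if gap <= 0:
        raise ValueError("gap must be positive")
    rng = np.random.default_rng(seed)
    atoms_a = _strand_atoms(n_res_per_chain, gap, rng, jitter)
    atoms_b = [
        (resnum, name, element, coord * np.array([1.0, -1.0, 1.0]))
        for resnum, name, element, coord in atoms_a
    ]
    return _pdb_text([("A", "SER", atoms_a), ("B", "SER", atoms_b)])


def _block_atoms(
    n_cols: int, gap: float, rng: np.random.Generator, jitter: float
) -> list[tuple[int, str, str, np.ndarray]]:
    """A bulky pseudo-protein block: n_cols x 3 x 3 jittered atoms.

    Three depth layers keep the block ~13 A thick, so a radius-8 patch cut
    at the contact face stays on one side of the solid, as it would on a
    globular protein.
    """
    probe, r_o = 1.4, 1.52
    contact_y = -(gap / 2.0 + r_o + probe)
    atoms = []
    rid = 1
    for ix in range(n_cols):
        for iy in range(3):
            for iz in range(3):
                base = np.array([3.5 * ix, contact_y - 3.3 * iy, 3.5 * (iz - 1)])
                pos = base + rng.normal(0.0, jitter, 3)
                if iy == 0:
                    pos[1] = min(pos[1], contact_y)  # contact face stays below the plane
                element = "O" if iy == 0 else "C"
                name = "OG" if element == "O" else "CA"
                atoms.append((rid, name, element, pos))
                rid += 1
    return atoms


def make_mold_complex(
    n_cols: int = 6,
    gap: float = 2.0,
    seed: int = 0,
    jitter: float = 0.35,
    spacing: float = 2.2,
) -> str:
    """PDB text of a complex whose chain B surface is the mold of chain A's.

    Chain A is a bulky jittered block of pseudo-atoms.  Chain B is built to
    be A's complementary mold at the interface: carbon pseudo-atoms are
    laid out along the outward normals of A's solvent-accessible surface,
    each at the constant offset ``gap + r_C + probe`` from a surface point,
    so the envelope of B's solvent-inflated spheres tracks the parallel
    offset of A's surface at distance ``gap`` (a true lock-and-key mold,
    unlike a mirror reflection, which would face bump against bump).  Two
    sparser backing layers thicken chain B so its far side stays clear of
    the interface patch.

    Mold atoms are spaced at least ``spacing`` Angstrom apart (greedy
    thinning); smaller spacing gives a smoother mold.
    """
    from .structure_io import Atom, Structure, assign_radii
    from .surface import compute_surface

    if gap <= 0:
        raise ValueError("gap must be positive")
    rng = np.random.default_rng(seed)
    atoms_a = _block_atoms(n_cols, gap, rng, jitter)

    probe, r_c = 1.4, 1.70
    struct_a = assign_radii(
        Structure(
            atoms=[
                Atom(serial=i + 1, name=name, element=element, chain_id="A",
                     res_num=resnum, icode="", res_name="SER", coord=coord)
                for i, (resnum, name, element, coord) in enumerate(atoms_a)
            ]
        )
    )
    cloud = compute_surface(struct_a, probe_radius=probe)
    facing = cloud.normals[:, 1] > 0.5  # points looking across the contact plane
    pts = cloud.positions[facing]
    nrm = cloud.normals[facing]

    kept: list[tuple[np.ndarray, np.ndarray]] = []
    for p, n in zip(pts, nrm):
        if all(np.linalg.norm(p - q) >= spacing for q, _ in kept):
            kept.append((p, n))
    offset = gap + r_c + probe
    centers = [p + offset * n for p, n in kept]
    centers += [p + (offset + 4.0) * n for p, n in kept[::2]]  # backing layers
    centers += [p + (offset + 8.0) * n for p, n in kept[::2]]

    atoms_b = [(i + 1, "CA", "C", c) for i, c in enumerate(centers)]
    return _pdb_text([("A", "SER", atoms_a), ("B", "GLY", atoms_b)])


def write_toy_complex(path: str | Path, **kwargs) -> Path:
    """Write :func:`make_toy_complex` output to ``path`` and return it."""
    path = Path(path)
    path.write_text(make_toy_complex(**kwargs))
    return path
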