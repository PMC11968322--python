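import numpy as np
import pytest

from zernpatch.fixtures import write_toy_complex
from zernpatch.structure_io import Atom, Structure, assign_radii
from zernpatch.surface import SurfacePointCloud, compute_surface


def single_atom_structure(element="C", coord=(0.0, 0.0, 0.0)):
    return assign_radii(
        Structure(
            atoms=[
                Atom(serial=1, name="CA", element=element, chain_id="A",
                     res_num=1, icode="", res_name="ALA",
                     coord=np.asarray(coord, dtype=float))
            ]
        )
    )


def two_atom_structure(d, elements=("C", "C")):
    """Two atoms separated by d along x."""
    atoms = [
        Atom(serial=i + 1, name="CA", element=el, chain_id="A",
             res_num=i + 1, icode="", res_name="ALA",
             coord=np.array([d * i, 0.0, 0.0]))
        for i, el in enumerate(elements)
    ]
    return assign_radii(Structure(atoms=atoms))


def cloud_from_points(points, normals):
    """Wrap an arbitrary oriented point set as a SurfacePointCloud."""
    st = single_atom_structure()
    n = len(points)
    return SurfacePointCloud(
        positions=np.asarray(points, dtype=float),
        normals=np.asarray(normals, dtype=float),
        atom_indices=np.zeros(n, dtype=int),
        structure=st,
        probe_radius=1.4,
        n_sphere_points=n,
    )


@pytest.fixture(scope="session")
def toy_pdb_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "toy_complex.pdb"
    return write_toy_complex(path, n_res_per_chain=3, gap=2.0, seed=1)


@pytest.fixture(scope="session")
def toy_structure(toy_pdb_path):
    from zernpatch.structure_io import parse_structure

    return assign_radii(parse_structure(toy_pdb_path))


@pytest.fixture(scope="session")
def toy_clouds(toy_structure):
    from zernpatch.structure_io import PartnerSelection, split_partners

    a, b = split_partners(toy_structure, PartnerSelection.from_strings("A", "B"))
    return compute_surface(a), compute_surface(b)
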