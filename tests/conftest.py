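import numpy as np
import pytest

from pocketgraft.atlas import Atlas, AtlasDatapoint, build_atlas
from pocketgraft.pockets import PocketMember
from pocketgraft.synth import demo_collection


@pytest.fixture(scope="session")
def demo_atlas():
    """Atlas over the five-complex demo collection (Arg ligand pockets
    with Asp/Glu/Trp contacts plus flanking Ser/Asn)."""
    return build_atlas(demo_collection(seed=3))


def make_datapoint(ligand_type="ARG", binder_type="ASP",
                   ligand_origin=("s", "B", "1"), binder_origin=("s", "A", "1"),
                   ca=(3.0, 0.0, 0.0), prim=(1.0, 0.0, 0.0),
                   sec=(0.0, 1.0, 0.0), kinds=("other",)):
    """Synthetic datapoint with a binder pose defined by CA position and
    orientation unit vectors (ligand frame coordinates)."""
    ca = np.asarray(ca, dtype=float)
    prim = np.asarray(prim, dtype=float)
    prim = prim / np.linalg.norm(prim)
    sec = np.asarray(sec, dtype=float)
    sec = sec / np.linalg.norm(sec)
    binder_atoms = {
        "CA": ca,
        "CB": ca + 1.53 * prim,
        "C": ca + 1.52 * sec,
        "N": ca + 1.46 * np.array([0.0, 0.0, -1.0]),
    }
    ligand_atoms = {
        "CA": np.zeros(3), "CB": np.array([1.53, 0.0, 0.0]),
        "C": np.array([0.5, 1.4, 0.0]), "N": np.array([-0.5, 0.9, -1.0]),
    }
    return AtlasDatapoint(
        ligand_type=ligand_type, binder_type=binder_type,
        ligand_origin=ligand_origin, binder_origin=binder_origin,
        ligand_atoms=ligand_atoms, binder_atoms=binder_atoms,
        interaction_kinds=frozenset(kinds))


def make_member(natural_id, poses):
    """PocketMember from {binder_type: (ca, prim, sec)} specs."""
    dps = {}
    for i, (btype, (ca, prim, sec)) in enumerate(sorted(poses.items())):
        dps[btype] = make_datapoint(
            binder_type=btype, ligand_origin=natural_id,
            binder_origin=(natural_id[0], "A", str(i + 1)),
            ca=ca, prim=prim, sec=sec)
    return PocketMember(natural_id=natural_id, datapoints=dps)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
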