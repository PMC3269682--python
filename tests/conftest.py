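import numpy as np
import pytest

from enmkit import NodeSet, SyntheticSpec, make_structure


def make_nodes(coords, resnums=None, chain="A"):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if resnums is None:
        resnums = np.arange(1, n + 1)
    return NodeSet(
        coords=coords,
        residue_numbers=np.asarray(resnums, dtype=int),
        chain_ids=[chain] * n,
        residue_names=["ALA"] * n,
    )


def random_blob(n, seed, scale=4.0):
    """Compact random 3D point cloud; connected at generous cutoffs."""
    rng = np.random.default_rng(seed)
    return make_nodes(rng.uniform(-scale, scale, (n, 3)))


@pytest.fixture(scope="session")
def dumbbell():
    return make_structure(SyntheticSpec(kind="dumbbell"))


@pytest.fixture(scope="session")
def helix20():
    return make_structure(SyntheticSpec(kind="helix", n=20))


@pytest.fixture(scope="session")
def ring30():
    return make_structure(SyntheticSpec(kind="ring", n=30))


@pytest.fixture(scope="session")
def bundle():
    return make_structure(SyntheticSpec(kind="bundle"))


# --- minimal PDB fixtures (fixed-column ATOM records) ----------------------

def _atom_line(serial, name, resname, chain, resseq, x, y, z,
               altloc=" ", icode=" ", occ=1.0, bfac=0.0, record="ATOM  "):
    return (
        f"{record}{serial:>5} {name:^4}{altloc}{resname:>3} {chain}"
        f"{resseq:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}"
        f"          {name.strip()[0]:>2}"
    )


TWO_RESIDUE_PDB = "\n".join([
    _atom_line(1, " CA ", "ALA", "A", 1, 0.0, 0.0, 0.0),
    _atom_line(2, " CA ", "GLY", "A", 2, 3.8, 0.0, 0.0),
    "END",
]) + "\n"

TWO_RESIDUE_PLUS_WATER_PDB = "\n".join([
    _atom_line(1, " CA ", "ALA", "A", 1, 0.0, 0.0, 0.0),
    _atom_line(2, " CA ", "GLY", "A", 2, 3.8, 0.0, 0.0),
    _atom_line(3, " O  ", "HOH", "A", 101, 9.0, 9.0, 9.0, record="HETATM"),
    "END",
]) + "\n"

# 5 residues; residue 3 has two CA altLocs, B with the higher occupancy
ALTLOC_PDB = "\n".join(
    [
        _atom_line(1, " CA ", "ALA", "A", 1, 0.0, 0.0, 0.0),
        _atom_line(2, " CA ", "ALA", "A", 2, 3.8, 0.0, 0.0),
        _atom_line(3, " CA ", "SER", "A", 3, 7.6, 0.0, 0.0, altloc="A", occ=0.40),
        _atom_line(4, " CA ", "SER", "A", 3, 7.6, 1.0, 0.0, altloc="B", occ=0.60),
        _atom_line(5, " CA ", "ALA", "A", 4, 11.4, 0.0, 0.0),
        _atom_line(6, " CA ", "ALA", "A", 5, 15.2, 0.0, 0.0),
        "END",
    ]
) + "\n"
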