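"""Shared fixtures: planted toys with their spectra and strain matrices.

Expensive objects are module/session scoped; all randomness is seeded so
every run sees identical inputs.
"""

import numpy as np
import pytest

import capsid_domains as cd

TOY_PDB = """\
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000       20.00000
REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000
REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000
REMARK 350   BIOMT1   3  0.000000 -1.000000  0.000000        0.00000
REMARK 350   BIOMT2   3  1.000000  0.000000  0.000000       20.00000
REMARK 350   BIOMT3   3  0.000000  0.000000  1.000000        0.00000
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800   1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.500   2.600   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.000   1.500   0.000  1.00  0.00           O
ATOM     10  CA  MSE A   3       6.500   4.000   0.500  1.00  0.00           C
ATOM     11  SE  MSE A   3       7.500   5.000   1.500  1.00  0.00          SE
END
"""


@pytest.fixture(scope="session")
def toy_pdb_path(tmp_path_factory):
    """Three-residue single-chain PDB with BIOMT transforms (ALA, GLY, MSE)."""
    p = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture(scope="session")
def hinge():
    return cd.make_hinge_toy()


@pytest.fixture(scope="session")
def hinge_spectrum(hinge):
    return cd.compute_modes(hinge.network, 1)


def _prepared(toy, n_modes):
    """(toy, retained spectrum, strain matrix) with the mode count chosen
    from the first planted block's spectrum."""
    capsid = cd.compute_modes(toy.network, n_modes)
    block = cd.subnetwork(toy.network, np.flatnonzero(toy.planted_labels == 0))
    protein = cd.compute_modes(block, 6)
    spectrum = capsid.truncate(cd.select_mode_count(capsid, protein))
    F = cd.strain_matrix(spectrum, toy.structure)
    return toy, spectrum, F


@pytest.fixture(scope="session")
def ring4():
    """K=4 ring of 8-point blocks at contrast 100, ready for decomposition."""
    return _prepared(cd.make_ring_assembly(4, 8, contrast=100.0, seed=1), 40)


@pytest.fixture(scope="session")
def ico60():
    """60-unit icosahedral toy (4 points/unit) at contrast 100."""
    return _prepared(cd.make_icosahedral_toy(4, contrast=100.0, seed=2), 130)


@pytest.fixture(scope="session")
def ico_trimer():
    """Icosahedral toy with stiff intra-trimer couplings (20 super-blocks)."""
    return _prepared(
        cd.make_icosahedral_toy(4, contrast=100.0, seed=2, fuse_trimers=True), 130
    )


@pytest.fixture(scope="session")
def random_bgm_structure():
    """60-residue random cloud with side-chain centroids (two-center model)."""
    rng = np.random.default_rng(4)
    n = 60
    main = rng.uniform(0, 18, (n, 3))
    side = main + rng.normal(0, 1.0, (n, 3))
    side[::7] = np.nan  # sprinkle glycines
    return cd.CapsidStructure(
        chain_ids=["A"] * n,
        protein_ids=["A"] * n,
        res_numbers=[str(i + 1) for i in range(n)],
        res_names=["GLY" if i % 7 == 0 else "ALA" for i in range(n)],
        main_coords=main,
        side_coords=side,
    )
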