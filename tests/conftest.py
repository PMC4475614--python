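import numpy as np
import pytest

from nbsynergy import synthdata
from nbsynergy.doseresponse import normalize_plate
from nbsynergy.poseconsensus import ContactSurface, Residue, StructureModel


@pytest.fixture
def clean_plate():
    """Noiseless plate with planted IC50 = 100, Hill = 1."""
    return synthdata.gen_viability_plate(seed=1, ic50=100.0, hill=1.0, noise_sd=0.0)


@pytest.fixture
def clean_points(clean_plate):
    return normalize_plate(clean_plate)


@pytest.fixture
def random_structure():
    """Factory: a random synthetic structure + ligand pair for contact tests."""

    def make(seed, n_atoms=500, n_lig=20, box=40.0):
        rng = np.random.default_rng(seed)
        n_res = n_atoms // 4
        residues = [Residue("A", i + 1, "ALA") for i in range(n_res)]
        coords = rng.uniform(0, box, size=(n_atoms, 3))
        atom_residue = rng.integers(0, n_res, size=n_atoms)
        # every residue must own >= 1 atom for identifier uniqueness to matter
        atom_residue[:n_res] = np.arange(n_res)
        structure = StructureModel(
            residues=residues, coords=coords, atom_residue=atom_residue
        )
        ligand = rng.uniform(0, box, size=(n_lig, 3))
        return structure, ligand

    return make


def brute_force_contacts(structure, ligand, cutoff):
    """All-pairs O(N*M) contact oracle, independent of the k-d tree path."""
    members = set()
    for i, xyz in enumerate(structure.coords):
        d = np.sqrt(((ligand - xyz) ** 2).sum(axis=1))
        if (d <= cutoff).any():
            members.add(structure.residues[structure.atom_residue[i]])
    return ContactSurface(frozenset(members), cutoff)
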