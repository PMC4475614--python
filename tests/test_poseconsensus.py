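"""Contact surfaces, conservation scores, interfaces and site overlap."""

import numpy as np
import pytest

from conftest import brute_force_contacts
from nbsynergy.poseconsensus import (
    Pose,
    PoseEnsemble,
    Residue,
    StructureModel,
    contact_residues,
    conservation_scores,
    geometric_center,
    interface_residues,
    site_overlap,
)
from nbsynergy.synthdata import gen_pose_ensemble


def single_residue_structure(xyz=(0.0, 0.0, 0.0), seq=1):
    return StructureModel(
        residues=[Residue("A", seq, "ALA")],
        coords=np.array([xyz]),
        atom_residue=np.array([0]),
    )


class TestContactResidues:
    def test_boundary_inside(self):
        st = single_residue_structure()
        surf = contact_residues(st, np.array([[3.5, 0, 0]]), cutoff=3.6)
        assert len(surf.residues) == 1

    def test_boundary_outside(self):
        st = single_residue_structure()
        surf = contact_residues(st, np.array([[3.7, 0, 0]]), cutoff=3.6)
        assert len(surf.residues) == 0

    def test_exact_cutoff_included(self):
        st = single_residue_structure()
        surf = contact_residues(st, np.array([[3.6, 0, 0]]), cutoff=3.6)
        assert len(surf.residues) == 1

    def test_empty_pose_rejected(self):
        with pytest.raises(ValueError):
            contact_residues(single_residue_structure(), np.empty((0, 3)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, random_structure, seed):
        structure, ligand = random_structure(seed)
        fast = contact_residues(structure, ligand, cutoff=3.6)
        slow = brute_force_contacts(structure, ligand, cutoff=3.6)
        assert fast.residues == slow.residues

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_monotone_in_cutoff(self, random_structure, seed):
        structure, ligand = random_structure(seed)
        small = contact_residues(structure, ligand, cutoff=2.0).residues
        large = contact_residues(structure, ligand, cutoff=5.0).residues
        assert small <= large


class TestConservationScores:
    def test_single_pose_scores_are_one(self):
        structure, ensemble, _ = gen_pose_ensemble(seed=1, jitter=0.0, n_poses=1)
        pocket = conservation_scores(structure, ensemble)
        assert pocket.n_poses_used == 1
        assert all(s == 1.0 for s in pocket.scores.values())

    def test_frequency_definition(self):
        st = single_residue_structure()
        near = Pose(np.array([[1.0, 0, 0]]), energy=-1.0)
        far = Pose(np.array([[50.0, 0, 0]]), energy=-0.5)
        ensemble = PoseEnsemble([near, far] * 25)
        pocket = conservation_scores(st, ensemble, top_k=50)
        assert pocket.scores[st.residues[0]] == pytest.approx(0.5)

    def test_top_k_selection_by_energy(self):
        st = single_residue_structure()
        # the 50 best-energy poses are all near; the far poses rank below
        near = [Pose(np.array([[1.0, 0, 0]]), energy=-10.0 + 0.01 * i) for i in range(50)]
        far = [Pose(np.array([[50.0, 0, 0]]), energy=0.0)] * 30
        pocket = conservation_scores(st, PoseEnsemble(far + near), top_k=50)
        assert pocket.scores[st.residues[0]] == 1.0

    def test_top_k_nonpositive_rejected(self):
        structure, ensemble, _ = gen_pose_ensemble(seed=1, n_poses=2)
        with pytest.raises(ValueError):
            conservation_scores(structure, ensemble, top_k=0)

    def test_planted_pocket_recovered_as_top_region(self):
        structure, ensemble, truth = gen_pose_ensemble(seed=5, jitter=0.5)
        pocket = conservation_scores(structure, ensemble)
        assert pocket.regions
        top = {r.seq for r in pocket.regions[0].residues}
        assert top == set(truth.pocket_seqs)

    def test_rigid_motion_invariance(self):
        """Scores are unchanged by a rotation+translation applied jointly."""
        structure, ensemble, _ = gen_pose_ensemble(seed=6, jitter=0.5)
        base = conservation_scores(structure, ensemble)

        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([11.0, -3.0, 7.0])
        moved_structure = StructureModel(
            residues=structure.residues,
            coords=structure.coords @ rot.T + shift,
            atom_residue=structure.atom_residue,
            atom_names=structure.atom_names,
        )
        moved_ensemble = PoseEnsemble(
            [Pose(p.coords @ rot.T + shift, p.energy) for p in ensemble.poses]
        )
        moved = conservation_scores(moved_structure, moved_ensemble)
        assert moved.scores == pytest.approx(base.scores)

    def test_bimodal_ensemble_scores_split(self):
        """Poses split between two sites score each near 0.5."""
        res = [Residue("A", 1, "ALA"), Residue("A", 50, "ALA")]
        st = StructureModel(
            residues=res,
            coords=np.array([[0.0, 0, 0], [100.0, 0, 0]]),
            atom_residue=np.array([0, 1]),
        )
        site_x = [Pose(np.array([[1.0, 0, 0]]), energy=-1.0)] * 25
        site_y = [Pose(np.array([[101.0, 0, 0]]), energy=-1.0)] * 25
        pocket = conservation_scores(st, PoseEnsemble(site_x + site_y), top_k=50)
        assert pocket.scores[res[0]] == pytest.approx(0.5)
        assert pocket.scores[res[1]] == pytest.approx(0.5)

    def test_region_bridging_and_ranking(self):
        # residues 1-2 and 5 hot (gap of 2 bridged); residue 20 separate
        residues = [Residue("A", s, "ALA") for s in (1, 2, 5, 20)]
        st = StructureModel(
            residues=residues,
            coords=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [50.0, 0, 0]]),
            atom_residue=np.arange(4),
        )
        both = Pose(np.array([[1.0, 0, 0], [50.0, 0, 0]]), energy=-2.0)
        first_only = Pose(np.array([[1.0, 0, 0]]), energy=-1.0)
        pocket = conservation_scores(st, PoseEnsemble([both, first_only]), top_k=2)
        spans = [reg.span for reg in pocket.regions]
        assert (1, 5) in spans and (20, 20) in spans
        assert pocket.regions[0].span == (1, 5)  # higher mean score ranks first


class TestInterfaceResidues:
    def two_chain_structure(self, offset):
        residues = [Residue("A", 1, "ALA"), Residue("B", 1, "GLY")]
        coords = np.array([[0.0, 0, 0], [offset, 0, 0]])
        return StructureModel(
            residues=residues, coords=coords, atom_residue=np.array([0, 1])
        )

    def test_distant_chains_empty(self):
        st = self.two_chain_structure(offset=10.0)
        assert interface_residues(st, "A", "B") == frozenset()

    def test_single_contact_pair(self):
        st = self.two_chain_structure(offset=3.0)
        pairs = interface_residues(st, "A", "B")
        assert pairs == frozenset({(st.residues[0], st.residues[1])})

    def test_symmetry(self):
        st = self.two_chain_structure(offset=3.0)
        ab = interface_residues(st, "A", "B")
        ba = interface_residues(st, "B", "A")
        assert {(b, a) for a, b in ab} == ba

    def test_missing_chain_rejected(self):
        st = self.two_chain_structure(offset=3.0)
        with pytest.raises(KeyError):
            interface_residues(st, "A", "C")


class TestSiteOverlap:
    def test_identical_sites(self):
        st, ens, _ = gen_pose_ensemble(seed=8, jitter=0.0, n_poses=1)
        lig = ens.poses[0].coords
        surf = contact_residues(st, lig)
        ov = site_overlap(surf, lig, surf, lig)
        assert ov.jaccard == 1.0
        assert ov.center_distance == 0.0

    def test_disjoint_sites(self):
        a = contact_residues(single_residue_structure(), np.array([[1.0, 0, 0]]))
        st2 = single_residue_structure((100.0, 0, 0), seq=2)
        b = contact_residues(st2, np.array([[101.0, 0, 0]]))
        ov = site_overlap(a, np.array([[1.0, 0, 0]]), b, np.array([[101.0, 0, 0]]))
        assert ov.jaccard == 0.0

    def test_three_four_five_center_distance(self):
        """Ligand translated by (0.3, 0.4, 0) moves the center 0.5 Å."""
        st, ens, _ = gen_pose_ensemble(seed=9, jitter=0.0, n_poses=1)
        lig_a = ens.poses[0].coords
        lig_b = lig_a + np.array([0.3, 0.4, 0.0])
        surf_a = contact_residues(st, lig_a)
        surf_b = contact_residues(st, lig_b)
        ov = site_overlap(surf_a, lig_a, surf_b, lig_b)
        assert ov.center_distance == pytest.approx(0.5)

    def test_empty_sites_have_no_jaccard(self):
        empty = contact_residues(single_residue_structure(), np.array([[99.0, 0, 0]]))
        ov = site_overlap(
            empty, np.array([[99.0, 0, 0]]), empty, np.array([[99.0, 0, 0]])
        )
        assert ov.jaccard is None

    def test_geometric_center_is_unweighted_mean(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 3.0, 0]])
        assert geometric_center(coords) == pytest.approx([1.0, 1.0, 0.0])
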