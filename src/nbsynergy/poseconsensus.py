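"""Consensus binding-site detection from docking-pose ensembles.

A pose's *contact surface* is the set of receptor residues with any heavy
atom within a distance cutoff (default 3.6 Å) of any ligand atom.  Over the
K lowest-energy poses (default K = 50), each residue's *conservation score*
is the fraction of kept poses whose contact surface contains it.  Runs of
sequence-consecutive high-scoring residues form the consensus pocket
regions.  The same cutoff defines dimer-interface residue pairs between two
protein chains, and two ligand sites can be compared by shared residues,
Jaccard index and geometric-center separation.

Distances are Euclidean over heavy atoms; contact detection uses a k-d tree
that agrees exactly with the all-pairs definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Residue",
    "StructureModel",
    "Pose",
    "PoseEnsemble",
    "ContactSurface",
    "PocketRegion",
    "ConsensusPocket",
    "SiteOverlap",
    "contact_residues",
    "conservation_scores",
    "interface_residues",
    "site_overlap",
    "geometric_center",
]

DEFAULT_CUTOFF = 3.6
DEFAULT_TOP_K = 50


class Residue(NamedTuple):
    """A residue identifier: chain, sequence number, residue name."""

    chain: str
    seq: int
    name: str


@dataclass
class StructureModel:
    """Receptor heavy-atom coordinates grouped by residue.

    ``coords`` is an (n_atoms, 3) array in Å; ``atom_residue`` maps each atom
    to an index into ``residues``.  Hydrogens, waters and alternate
    locations are expected to have been filtered by the reader.
    """

    residues: list[Residue]
    coords: np.ndarray
    atom_residue: np.ndarray
    atom_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if len(self.atom_residue) != len(self.coords):
            raise ValueError("atom_residue must map every atom")
        if len(self.coords) and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue identifiers")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def chain_atoms(self, chain: str) -> np.ndarray:
        """Indices of atoms belonging to one chain."""
        res_idx = [i for i, r in enumerate(self.residues) if r.chain == chain]
        if not res_idx:
            raise KeyError(f"chain {chain!r} not in structure")
        return np.flatnonzero(np.isin(self.atom_residue, res_idx))


@dataclass(frozen=True)
class Pose:
    coords: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or not len(self.coords):
            raise ValueError("pose needs >= 1 atom with xyz coordinates")


@dataclass
class PoseEnsemble:
    """Ligand pose coordinates with comparable energies (lower = better)."""

    poses: list[Pose]
    ligand_label: str = ""

    def sorted_indices(self) -> np.ndarray:
        # stable: energy ties broken by input order
        return np.argsort([p.energy for p in self.poses], kind="stable")


@dataclass(frozen=True)
class ContactSurface:
    residues: frozenset[Residue]
    cutoff: float = DEFAULT_CUTOFF


@dataclass(frozen=True)
class PocketRegion:
    """A maximal run of sequence-consecutive high-scoring residues."""

    residues: tuple[Residue, ...]
    mean_score: float

    @property
    def span(self) -> tuple[int, int]:
        return self.residues[0].seq, self.residues[-1].seq


@dataclass
class ConsensusPocket:
    scores: dict[Residue, float]
    regions: list[PocketRegion]
    n_poses_used: int


class SiteOverlap(NamedTuple):
    shared: frozenset[Residue]
    jaccard: float | None
    center_distance: float


def contact_residues(
    structure: StructureModel,
    pose: Pose | np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactSurface:
    """Residues with any heavy atom within ``cutoff`` Å of any ligand atom.

    A residue is included iff the minimum over all (protein atom, ligand
    atom) pairs of the Euclidean distance is <= cutoff (boundary inclusive).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not len(structure.coords):
        raise ValueError("empty structure")
    lig = pose.coords if isinstance(pose, Pose) else np.asarray(pose, dtype=float)
    if lig.ndim != 2 or not len(lig):
        raise ValueError("empty ligand pose")
    tree = cKDTree(lig)
    d, _ = tree.query(structure.coords, k=1, distance_upper_bound=cutoff * (1 + 1e-12))
    near = d <= cutoff
    members = {structure.residues[i] for i in set(structure.atom_residue[near])}
    return ContactSurface(frozenset(members), cutoff)


def conservation_scores(
    structure: StructureModel,
    ensemble: PoseEnsemble,
    top_k: int = DEFAULT_TOP_K,
    cutoff: float = DEFAULT_CUTOFF,
    region_threshold: float = 0.5,
    bridge_gaps: int = 2,
) -> ConsensusPocket:
    """Per-residue contact frequency over the top-k lowest-energy poses.

    Poses are ranked by ascending energy (ties by input order) and the first
    min(top_k, n) kept; a residue's score is the fraction of kept poses whose
    contact surface contains it.  Residues scoring >= ``region_threshold``
    are segmented into sequence-consecutive runs within a chain, bridging
    gaps of up to ``bridge_gaps`` residues; regions are ranked by descending
    mean score.
    """
    if top_k <= 0:
        raise ValueError("top_k must be >= 1")
    if not ensemble.poses:
        raise ValueError("empty pose ensemble")
    order = ensemble.sorted_indices()[: min(top_k, len(ensemble.poses))]
    counts: dict[Residue, int] = {}
    for i in order:
        for res in contact_residues(structure, ensemble.poses[i], cutoff).residues:
            counts[res] = counts.get(res, 0) + 1
    n_used = len(order)
    scores = {res: c / n_used for res, c in counts.items()}
    regions = _segment_regions(scores, region_threshold, bridge_gaps)
    return ConsensusPocket(scores=scores, regions=regions, n_poses_used=n_used)


def _segment_regions(
    scores: dict[Residue, float], threshold: float, bridge_gaps: int
) -> list[PocketRegion]:
    hot = sorted(
        (r for r, s in scores.items() if s >= threshold),
        key=lambda r: (r.chain, r.seq),
    )
    runs: list[list[Residue]] = []
    for res in hot:
        if (
            runs
            and runs[-1][-1].chain == res.chain
            and res.seq - runs[-1][-1].seq <= bridge_gaps + 1
        ):
            runs[-1].append(res)
        else:
            runs.append([res])
    regions = [
        PocketRegion(tuple(run), float(np.mean([scores[r] for r in run])))
        for run in runs
    ]
    # rank by mean score, stable on sequence order for ties
    regions.sort(key=lambda reg: -reg.mean_score)
    return regions


def interface_residues(
    structure: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> frozenset[tuple[Residue, Residue]]:
    """Residue pairs (one per chain) with any atom pair within ``cutoff`` Å.

    The result is symmetric: a pair (ra, rb) with ra from ``chain_a`` and rb
    from ``chain_b`` appears iff any atom of ra is within the cutoff of any
    atom of rb.
    """
    ia = structure.chain_atoms(chain_a)
    ib = structure.chain_atoms(chain_b)
    tree_b = cKDTree(structure.coords[ib])
    pairs: set[tuple[Residue, Residue]] = set()
    neighbours = tree_b.query_ball_point(
        structure.coords[ia], r=cutoff * (1 + 1e-12)
    )
    for a_pos, hits in zip(ia, neighbours):
        if not hits:
            continue
        ra = structure.residues[structure.atom_residue[a_pos]]
        for h in hits:
            b_pos = ib[h]
            d = np.linalg.norm(structure.coords[a_pos] - structure.coords[b_pos])
            if d <= cutoff:
                rb = structure.residues[structure.atom_residue[b_pos]]
                pairs.add((ra, rb))
    return frozenset(pairs)


def geometric_center(coords: np.ndarray) -> np.ndarray:
    """Unweighted mean of atom coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or not len(coords):
        raise ValueError("need at least one atom")
    return coords.mean(axis=0)


def site_overlap(
    site_a: ContactSurface,
    ligand_a: np.ndarray,
    site_b: ContactSurface,
    ligand_b: np.ndarray,
) -> SiteOverlap:
    """Compare two ligand binding sites on the same structure frame:
    shared residues, Jaccard index (None when both sites are empty) and the
    Euclidean distance between the ligands' geometric centers."""
    shared = site_a.residues & site_b.residues
    union = site_a.residues | site_b.residues
    jaccard = len(shared) / len(union) if union else None
    dist = float(
        np.linalg.norm(geometric_center(ligand_a) - geometric_center(ligand_b))
    )
    return SiteOverlap(frozenset(shared), jaccard, dist)
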