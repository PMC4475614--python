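"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments (seed included): the
same call always returns the same object.  Randomness uses NumPy's
``default_rng`` (PCG64, recorded in :data:`RNG_ALGORITHM`).

The generators emulate the statistical structure of the study inputs:

* viability plates — 4-parameter-logistic responses (top 100, bottom 0)
  with additive Gaussian optical-density noise and vehicle wells;
* combination grids — per fixed drug-B dose, a drug-A plate whose true
  combination IC50 realises a planted combination index;
* expression cohorts — 2log-scale Gaussian genes with a planted group shift
  for a target gene and a bivariate pair at a target Pearson correlation;
* pose ensembles — lattice pseudo-residues with a designated contact pocket
  and ligand poses jittered around it, energies increasing with jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohortstats import CohortMatrix
from .doseresponse import ViabilityPlate, Well
from .poseconsensus import (
    Pose,
    PoseEnsemble,
    Residue,
    StructureModel,
    contact_residues,
)

__all__ = [
    "RNG_ALGORITHM",
    "gen_viability_plate",
    "gen_combination_grid",
    "gen_cohort",
    "gen_pose_ensemble",
]

RNG_ALGORITHM = "PCG64"  # np.random.default_rng; pinned so fixtures are stable

DEFAULT_DOSES = tuple(float(x) for x in np.round(10 ** np.linspace(0.5, 3.5, 7), 4))


def _logistic(dose: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    return 100.0 / (1.0 + (dose / ic50) ** hill)


def gen_viability_plate(
    seed: int,
    ic50: float = 100.0,
    hill: float = 1.0,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    replicates: int = 3,
    noise_sd: float = 2.0,
    n_vehicle: int = 3,
    baseline_od: float = 1.0,
    unit: str = "uM",
    drug_label: str = "drugA",
) -> ViabilityPlate:
    """A viability plate with a planted log-logistic truth.

    ``noise_sd`` is Gaussian noise in percent-viability units added on the
    OD scale (sd = noise_sd/100 * baseline_od).  Vehicle wells are included;
    no blank wells (the normalisation handles their absence).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(doses) < 3:
        raise ValueError("need >= 3 doses")
    rng = np.random.default_rng(seed)
    sd = noise_sd / 100.0 * baseline_od
    wells = []
    for rep in range(n_vehicle):
        wells.append(Well(0.0, float(baseline_od + rng.normal(0, sd)), rep, "vehicle"))
    truth = _logistic(np.asarray(doses, dtype=float), ic50, hill)
    for d, resp in zip(doses, truth):
        for rep in range(replicates):
            od = float(baseline_od * resp / 100.0 + rng.normal(0, sd))
            wells.append(Well(float(d), od, rep, "treated"))
    return ViabilityPlate(wells=wells, drug_label=drug_label, unit=unit)


def gen_combination_grid(
    seed: int,
    ic50_a: float = 337.2,
    ic50_b: float = 5.79,
    b_doses: tuple[float, ...] | None = None,
    planted_ci: float | tuple[float, ...] = 0.5,
    hill: float = 1.0,
    n_a_doses: int = 7,
    replicates: int = 2,
    noise_sd: float = 2.0,
    unit_a: str = "uM",
    unit_b: str = "mM",
) -> tuple[dict[float, ViabilityPlate], pd.DataFrame]:
    """Fixed-B/varying-A combination design with a planted CI per B dose.

    For each fixed drug-B dose b, drug A's true combination IC50 is set so
    that CI = ic50_comb/ic50_a + b/ic50_b equals the planted value; each
    B dose therefore requires planted_ci > b/ic50_b.  The default B grid
    spans 5-25% of the drug-B IC50 so that any planted CI above 0.25 is
    realisable at every B dose.  A-dose grids are log-spaced around the
    planted combination IC50.  Returns the plates keyed by B dose plus a
    truth table (b_dose, true_a_ic50, planted_ci).
    """
    if b_doses is None:
        b_doses = tuple(
            float(np.round(f * ic50_b, 6)) for f in (0.05, 0.10, 0.15, 0.20, 0.25)
        )
    cis = (
        tuple(float(c) for c in planted_ci)
        if np.iterable(planted_ci)
        else (float(planted_ci),) * len(b_doses)
    )
    if len(cis) != len(b_doses):
        raise ValueError("one planted CI per B dose required")
    rows = []
    plates: dict[float, ViabilityPlate] = {}
    for k, (b, ci) in enumerate(zip(b_doses, cis)):
        e_a = ci - b / ic50_b
        if ci <= 0 or e_a <= 0:
            raise ValueError(
                f"planted CI {ci} not realisable at B dose {b} "
                f"(drug-B equivalent alone is {b / ic50_b:.3f})"
            )
        a_ic50 = e_a * ic50_a
        doses = tuple(
            float(x)
            for x in np.round(a_ic50 * 10 ** np.linspace(-1.5, 1.5, n_a_doses), 6)
        )
        plates[float(b)] = gen_viability_plate(
            seed=seed + k,
            ic50=a_ic50,
            hill=hill,
            doses=doses,
            replicates=replicates,
            noise_sd=noise_sd,
            unit=unit_a,
            drug_label="drugA",
        )
        rows.append({"b_dose": b, "true_a_ic50": a_ic50, "planted_ci": ci})
    truth = pd.DataFrame(rows)
    truth.attrs["unit_a"] = unit_a
    truth.attrs["unit_b"] = unit_b
    return plates, truth


def gen_cohort(
    seed: int,
    n_per_group: tuple[int, int] = (300, 349),
    shift_sd: float = 1.0,
    target_r: float = 0.225,
    target_gene: str = "SPR",
    partner_gene: str = "ODC1",
    n_noise_genes: int = 3,
    mean_log2: float = 7.0,
    sd_log2: float = 1.0,
    frac_mycn_amp: float = 0.2,
    frac_unknown: float = 0.05,
) -> CohortMatrix:
    """A neuroblastoma-style expression cohort on 2log scale.

    Two age groups (sizes ``n_per_group``); the target gene's mean is
    shifted by ``shift_sd`` standard deviations in the older group.  The
    target and partner genes are drawn bivariate-normal with correlation
    ``target_r`` (Cholesky construction) before the shift is applied, so the
    planted within-group correlation is exact in expectation.  MYCN and
    INSS annotations are assigned independently at realistic frequencies
    with a small unknown fraction.
    """
    if abs(target_r) >= 1:
        raise ValueError("|target_r| must be < 1")
    rng = np.random.default_rng(seed)
    n = int(sum(n_per_group))
    # correlated pair via Cholesky
    z = rng.standard_normal((n, 2))
    l11 = target_r
    l12 = np.sqrt(1.0 - target_r**2)
    g_target = z[:, 0]
    g_partner = l11 * z[:, 0] + l12 * z[:, 1]
    age = np.array(["<18mo"] * n_per_group[0] + [">=18mo"] * n_per_group[1])
    g_target = g_target + shift_sd * (age == ">=18mo")
    expr = {
        target_gene: mean_log2 + sd_log2 * g_target,
        partner_gene: mean_log2 + sd_log2 * g_partner,
    }
    for i in range(n_noise_genes):
        expr[f"GENE{i + 1}"] = mean_log2 + sd_log2 * rng.standard_normal(n)
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    expression = pd.DataFrame(expr, index=samples)

    mycn = rng.choice(
        ["amplified", "not amplified"], size=n, p=[frac_mycn_amp, 1 - frac_mycn_amp]
    ).astype(object)
    inss = rng.choice(
        ["1", "2", "3", "4", "4S"], size=n, p=[0.2, 0.15, 0.2, 0.35, 0.1]
    ).astype(object)
    for arr in (mycn, inss):
        unk = rng.random(n) < frac_unknown
        arr[unk] = "unknown"
    annotations = pd.DataFrame(
        {"age_group": age, "mycn": mycn, "inss_stage": inss}, index=samples
    )
    return CohortMatrix(expression=expression, annotations=annotations)


@dataclass(frozen=True)
class PoseTruth:
    """Ground truth for a generated ensemble: the planted contact pocket."""

    pocket: frozenset[Residue]
    pocket_seqs: tuple[int, ...]


def gen_pose_ensemble(
    seed: int,
    n_residues: int = 120,
    pocket_size: int = 8,
    pocket_start: int | None = None,
    jitter: float = 0.5,
    n_poses: int = 60,
    spacing: float = 5.0,
    contact_offset: float = 3.0,
    cutoff: float = 3.6,
    chain: str = "A",
) -> tuple[StructureModel, PoseEnsemble, PoseTruth]:
    """A lattice pseudo-protein, a planted pocket, and a jittered ensemble.

    Residues are single pseudo-atoms on a 3D snake lattice (``spacing`` Å
    apart).  The base ligand places one atom ``contact_offset`` Å from each
    of ``pocket_size`` consecutive residues starting at ``pocket_start``
    (middle of the chain by default).  Each pose is the base ligand plus
    isotropic Gaussian jitter of scale ``jitter`` Å; its energy grows with
    the jitter magnitude, so low-energy poses sit closest to the pocket.
    The truth pocket is the contact surface of the unjittered ligand.
    """
    if pocket_size <= 0 or pocket_size > n_residues:
        raise ValueError("pocket larger than structure")
    if n_poses < 1:
        raise ValueError("need >= 1 pose")
    rng = np.random.default_rng(seed)

    # snake over a cubic lattice so the chain folds through space
    side = int(np.ceil(n_residues ** (1 / 3)))
    coords = []
    for i in range(n_residues):
        x = i % side
        y = (i // side) % side
        z = i // (side * side)
        # alternate direction each row/layer to keep neighbours adjacent
        xx = x if y % 2 == 0 else side - 1 - x
        yy = y if z % 2 == 0 else side - 1 - y
        coords.append((xx * spacing, yy * spacing, z * spacing))
    coords = np.asarray(coords, dtype=float)
    residues = [Residue(chain, i + 1, "ALA") for i in range(n_residues)]
    structure = StructureModel(
        residues=residues,
        coords=coords,
        atom_residue=np.arange(n_residues),
        atom_names=["CA"] * n_residues,
    )

    if pocket_start is None:
        pocket_start = (n_residues - pocket_size) // 2
    pocket_idx = np.arange(pocket_start, pocket_start + pocket_size)
    # one ligand atom offset from each pocket residue, pushed off-lattice
    direction = np.array([0.57735, 0.57735, 0.57735])
    base = coords[pocket_idx] + contact_offset * direction

    poses = []
    for _ in range(n_poses):
        shift = rng.normal(0.0, jitter, size=3) if jitter > 0 else np.zeros(3)
        wobble = rng.normal(0.0, jitter / 2, size=base.shape) if jitter > 0 else 0.0
        pose_coords = base + shift + wobble
        energy = -100.0 + 10.0 * np.linalg.norm(shift) + rng.normal(0, 0.1)
        poses.append(Pose(coords=pose_coords, energy=float(energy)))
    ensemble = PoseEnsemble(poses=poses, ligand_label="LIG")

    truth_surface = contact_residues(structure, base, cutoff=cutoff)
    truth = PoseTruth(
        pocket=truth_surface.residues,
        pocket_seqs=tuple(sorted(r.seq for r in truth_surface.residues)),
    )
    return structure, ensemble, truth
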