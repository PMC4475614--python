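"""Readers and writers for the pipeline's file dialects.

Plates, combination designs and cohorts travel as comma-separated UTF-8
files with dot decimals and required headers; structures and pose ensembles
as PDB.  Every reader reports malformed rows with their line number, and
rejects anything its paired writer would not produce.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .cohortstats import CohortMatrix
from .doseresponse import ViabilityPlate, Well
from .poseconsensus import Pose, PoseEnsemble, Residue, StructureModel
from .synergy import CombinationIndexResult, round_display
from .units import UnitError, canonical_unit

__all__ = [
    "FormatError",
    "read_plate_csv",
    "write_plate_csv",
    "read_combination_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_structure_pdb",
    "write_structure_pdb",
    "read_pose_ensemble",
    "write_pose_ensemble",
    "write_synergy_report",
]

PLATE_COLUMNS = ["dose", "unit", "od", "replicate", "role", "drug"]
COMBO_COLUMNS = ["cell_line", "drug_a", "dose_a", "unit_a", "drug_b", "dose_b", "unit_b"]
REPORT_COLUMNS = ["cell_line", "equiv_a", "equiv_b", "ci", "class", "dose_a", "dose_b"]
ROLES = {"treated", "vehicle", "blank"}


class FormatError(ValueError):
    """A file violates its dialect; the message carries the location."""


def _require_columns(have: Iterable[str], want: Sequence[str], path) -> None:
    missing = [c for c in want if c not in set(have)]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# plates


def read_plate_csv(path) -> ViabilityPlate:
    """Read a one-row-per-well plate CSV (dose, unit, od, replicate, role,
    drug).  All wells must share one unit; unit spellings are normalised."""
    path = Path(path)
    wells = []
    units = set()
    drugs = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        _require_columns(reader.fieldnames, PLATE_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                dose = float(row["dose"])
                od = float(row["od"])
                replicate = int(row["replicate"])
            except (TypeError, ValueError) as e:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({e})") from e
            role = (row["role"] or "").strip()
            if role not in ROLES:
                raise FormatError(f"{path}:{lineno}: unknown role {role!r}")
            try:
                units.add(canonical_unit(row["unit"]))
            except UnitError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
            drugs.add(row["drug"])
            wells.append(Well(dose=dose, od=od, replicate=replicate, role=role))
    if len(units) > 1:
        raise FormatError(f"{path}: mixed concentration units {sorted(units)}")
    if not wells:
        raise FormatError(f"{path}: no data rows")
    return ViabilityPlate(
        wells=wells,
        drug_label=sorted(drugs)[0] if drugs else "",
        unit=units.pop(),
    )


def write_plate_csv(plate: ViabilityPlate, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PLATE_COLUMNS)
        for well in plate.wells:
            w.writerow(
                [
                    repr(float(well.dose)),
                    plate.unit,
                    repr(float(well.od)),
                    well.replicate,
                    well.role,
                    plate.drug_label,
                ]
            )


# ---------------------------------------------------------------------------
# combination designs


def read_combination_csv(path) -> pd.DataFrame:
    """Read a combination design table (one row per design point)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as e:
        raise FormatError(f"{path}: {e}") from e
    _require_columns(df.columns, COMBO_COLUMNS, path)
    for col in ("dose_a", "dose_b"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric {col} at data row {bad[0] + 2}")
        df[col] = vals
    for col in ("unit_a", "unit_b"):
        try:
            df[col] = [canonical_unit(u) for u in df[col]]
        except UnitError as e:
            raise FormatError(f"{path}: {e}") from e
    return df


# ---------------------------------------------------------------------------
# cohorts


def read_cohort_csv(path) -> CohortMatrix:
    """Read a cohort CSV: first column sample id, ``clin:``-prefixed
    annotation columns, remaining columns gene symbols with 2log values."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, encoding="utf-8")
    except Exception as e:
        raise FormatError(f"{path}: {e}") from e
    clin_cols = [c for c in df.columns if c.startswith("clin:")]
    gene_cols = [c for c in df.columns if not c.startswith("clin:")]
    if not gene_cols:
        raise FormatError(f"{path}: no gene columns")
    expr = df[gene_cols].apply(pd.to_numeric, errors="coerce")
    bad = expr.columns[expr.isna().any()]
    if len(bad):
        raise FormatError(f"{path}: non-numeric expression values in {list(bad)}")
    annotations = df[clin_cols].rename(columns=lambda c: c[len("clin:") :])
    annotations = annotations.astype(str)
    return CohortMatrix(expression=expr, annotations=annotations)


def write_cohort_csv(cohort: CohortMatrix, path) -> None:
    ann = cohort.annotations.rename(columns=lambda c: f"clin:{c}")
    out = pd.concat([ann, cohort.expression], axis=1)
    out.index.name = "sample"
    out.to_csv(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# structures and pose ensembles


def read_structure_pdb(path, chains: Sequence[str] | None = None) -> StructureModel:
    """Parse a PDB file into a heavy-atom :class:`StructureModel`.

    Model 1 only; waters and hydrogens removed; for alternate locations the
    highest-occupancy conformer is kept; optional chain selection.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    residues: list[Residue] = []
    coords = []
    atom_residue = []
    atom_names = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            rid = Residue(chain.name, res.seqid.num, res.name)
            residues.append(rid)
            ri = len(residues) - 1
            # alternate locations: keep the highest-occupancy conformer
            best: dict[str, tuple[float, gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                occ = atom.occ if atom.altloc else float("inf")
                if atom.name not in best or occ > best[atom.name][0]:
                    best[atom.name] = (occ, atom)
            for name, (_, atom) in best.items():
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                atom_residue.append(ri)
                atom_names.append(name)
    if not coords:
        raise FormatError(f"{path}: no atoms after filtering")
    # drop residues that lost every atom (e.g. hydrogen-only)
    used = sorted(set(atom_residue))
    remap = {old: new for new, old in enumerate(used)}
    return StructureModel(
        residues=[residues[i] for i in used],
        coords=np.asarray(coords),
        atom_residue=np.asarray([remap[i] for i in atom_residue]),
        atom_names=atom_names,
    )


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, seq: int, xyz, element: str
) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain:1s}{seq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_structure_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as minimal fixed-width PDB ATOM records
    (deterministic: identical models give identical bytes)."""
    lines = []
    serial = 0
    for ai in range(len(model.coords)):
        serial += 1
        res = model.residues[model.atom_residue[ai]]
        name = model.atom_names[ai] if model.atom_names else "CA"
        element = "".join(c for c in name if c.isalpha())[:1] or "C"
        lines.append(
            _pdb_atom_line(
                serial, name, res.name, res.chain, res.seq, model.coords[ai], element
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_pose_ensemble(ensemble: PoseEnsemble, out_dir, prefix: str = "pose") -> Path:
    """Write one PDB per pose plus an energies CSV (pose_file, energy).
    Returns the energies CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pose in enumerate(ensemble.poses):
        fname = f"{prefix}_{i:04d}.pdb"
        lines = []
        for j, xyz in enumerate(pose.coords):
            lines.append(
                _pdb_atom_line(j + 1, f"C{j + 1}", "LIG", "X", 1, xyz, "C")
            )
        lines.append("END")
        (out_dir / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")
        rows.append((fname, pose.energy))
    energies = out_dir / "energies.csv"
    with open(energies, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["pose_file", "energy"])
        for fname, e in rows:
            w.writerow([fname, repr(e)])
    return energies


def read_pose_ensemble(energies_csv, ligand_label: str = "") -> PoseEnsemble:
    """Read a pose ensemble from an energies CSV (pose_file, energy) whose
    pose files live next to it."""
    energies_csv = Path(energies_csv)
    base = energies_csv.parent
    poses = []
    with open(energies_csv, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{energies_csv}: empty file")
        _require_columns(reader.fieldnames, ["pose_file", "energy"], energies_csv)
        for lineno, row in enumerate(reader, start=2):
            try:
                energy = float(row["energy"])
            except (TypeError, ValueError) as e:
                raise FormatError(f"{energies_csv}:{lineno}: bad energy ({e})") from e
            pose_path = base / row["pose_file"]
            if not pose_path.exists():
                raise FormatError(
                    f"{energies_csv}:{lineno}: pose file {row['pose_file']!r} missing"
                )
            coords = _read_pdb_coords(pose_path)
            poses.append(Pose(coords=coords, energy=energy))
    if not poses:
        raise FormatError(f"{energies_csv}: no poses listed")
    return PoseEnsemble(poses=poses, ligand_label=ligand_label)


def _read_pdb_coords(path) -> np.ndarray:
    st = gemmi.read_structure(str(path))
    coords = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    if not atom.element.is_hydrogen:
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # model 1 only
    if not coords:
        raise FormatError(f"{path}: no atoms")
    return np.asarray(coords)


# ---------------------------------------------------------------------------
# reports


def write_synergy_report(results: Sequence[CombinationIndexResult], path) -> None:
    """Write a synergy table as TSV with 3-decimal half-up display values,
    rows in input order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(REPORT_COLUMNS)
        for r in results:
            rec = r.record
            w.writerow(
                [
                    rec.cell_line if rec else "",
                    _disp(r.e_a.value),
                    _disp(r.e_b.value),
                    _disp(r.ci),
                    r.synergy_class,
                    _disp(rec.drug_a_dose) if rec else "",
                    _disp(rec.drug_b_dose) if rec else "",
                ]
            )


def _disp(x: float) -> str:
    if x != x:  # NaN from an unfit row
        return "NA"
    return f"{round_display(x):.3f}"
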