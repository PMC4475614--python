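"""IC50-equivalent doses, combination index and isobologram coordinates.

The combination index (CI) at the 50% effect level is the Loewe-style sum of
the two drugs' IC50-equivalent doses:

    CI = d_A / IC50_A  +  d_B / IC50_B

where, for the fixed-B/varying-A design used here, d_A is the IC50 of drug A
re-measured in the presence of a fixed dose d_B of drug B.  CI < 1 indicates
synergy, CI = 1 additivity, CI > 1 antagonism, refined into seven bands.
All arithmetic is done on unrounded equivalents; 3-decimal half-up rounding
is applied only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .doseresponse import LogLogisticModel, NormalizedResponse

__all__ = [
    "CombinationRecord",
    "EquivalentDose",
    "CombinationIndexResult",
    "IsobologramData",
    "CI_BANDS",
    "ic50_equivalent",
    "combination_index",
    "classify_ci",
    "isobologram",
    "synergy_table",
    "round_display",
]


@dataclass(frozen=True)
class CombinationRecord:
    """One design point: drug A's combination IC50 at a fixed drug-B dose."""

    drug_a_dose: float
    drug_b_dose: float
    cell_line: str = ""


@dataclass(frozen=True)
class EquivalentDose:
    """A dose expressed as a (dimensionless) fraction of the single-agent IC50."""

    value: float


@dataclass(frozen=True)
class CombinationIndexResult:
    ci: float
    e_a: EquivalentDose
    e_b: EquivalentDose
    synergy_class: str
    effect_level: float = 50.0
    record: CombinationRecord | None = None
    fit_ok: bool = True


@dataclass(frozen=True)
class IsobologramData:
    """Plot-ready isobologram: additivity line endpoints plus one point per
    combination in IC50-equivalent axes.  A point lies below the line iff
    e_a + e_b < 1."""

    points: tuple[tuple[float, float], ...]
    below_line: tuple[bool, ...]
    additivity_line: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    axis_labels: tuple[str, str] = ("drug A (IC50 equivalents)", "drug B (IC50 equivalents)")


# (lower, upper, class); lower-closed/upper-open except moderate antagonism,
# which is upper-closed so that only CI > 1.3 is antagonism
CI_BANDS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.2, "below-scale"),
    (0.2, 0.4, "strong synergism"),
    (0.4, 0.6, "synergism"),
    (0.6, 0.8, "moderate synergism"),
    (0.8, 0.9, "slight synergism"),
    (0.9, 1.1, "additive"),
    (1.1, 1.3, "moderate antagonism"),
)


def ic50_equivalent(dose: float, single_agent_ic50: float) -> EquivalentDose:
    """dose / single-agent IC50, unrounded.  Both must be positive and in
    the same unit."""
    if dose < 0 or single_agent_ic50 <= 0:
        raise ValueError(
            f"doses and IC50 must be positive (got dose={dose}, "
            f"ic50={single_agent_ic50})"
        )
    return EquivalentDose(dose / single_agent_ic50)


def combination_index(
    e_a: EquivalentDose | float,
    e_b: EquivalentDose | float,
    effect_level: float = 50.0,
    record: CombinationRecord | None = None,
) -> CombinationIndexResult:
    """CI = e_a + e_b on unrounded equivalents, with the band class."""
    ea = e_a.value if isinstance(e_a, EquivalentDose) else float(e_a)
    eb = e_b.value if isinstance(e_b, EquivalentDose) else float(e_b)
    if ea < 0 or eb < 0:
        raise ValueError("equivalent doses must be non-negative")
    ci = ea + eb
    return CombinationIndexResult(
        ci=ci,
        e_a=EquivalentDose(ea),
        e_b=EquivalentDose(eb),
        synergy_class=classify_ci(ci),
        effect_level=effect_level,
        record=record,
    )


def classify_ci(
    ci: float, bands: Sequence[tuple[float, float, str]] = CI_BANDS
) -> str:
    """Map an (unrounded) CI to its synergy band.

    Bands partition [0, inf): values below the lowest band are
    "below-scale"; the top band's upper edge is closed (CI = 1.3 is still
    moderate antagonism) and only CI > 1.3 is antagonism.
    """
    if ci < 0:
        raise ValueError(f"combination index must be >= 0, got {ci}")
    for lo, hi, label in bands:
        if lo <= ci < hi:
            return label
    if ci == bands[-1][1]:  # closed upper edge of the top finite band
        return bands[-1][2]
    return "antagonism"


def isobologram(
    records: Sequence[CombinationRecord], ic50_a: float, ic50_b: float
) -> IsobologramData:
    """Map combination records into IC50-equivalent axes with the line of
    additivity from (1,0) to (0,1)."""
    points = []
    below = []
    for rec in records:
        ea = ic50_equivalent(rec.drug_a_dose, ic50_a).value
        eb = ic50_equivalent(rec.drug_b_dose, ic50_b).value
        points.append((ea, eb))
        below.append(ea + eb < 1.0)
    return IsobologramData(points=tuple(points), below_line=tuple(below))


def synergy_table(
    plates_by_b_dose: Mapping[float, Sequence[NormalizedResponse]],
    ic50_a: float,
    ic50_b: float,
    cell_line: str = "",
    variable_slope: bool = True,
    effect_level: float = 50.0,
) -> list[CombinationIndexResult]:
    """Fit drug A's combination IC50 at each fixed drug-B dose and score CI.

    ``plates_by_b_dose`` maps each fixed B dose to normalised A-dose-response
    points.  A failed fit yields a row flagged ``fit_ok=False`` instead of
    aborting the table.  Rows follow the input order of B doses.
    """
    rows: list[CombinationIndexResult] = []
    for b_dose, points in plates_by_b_dose.items():
        try:
            res = LogLogisticModel.from_points(points, variable_slope).fit()
            ok = res.converged
            a_ic50 = res.ic50 if ok else float("nan")
        except ValueError:
            ok, a_ic50 = False, float("nan")
        rec = CombinationRecord(a_ic50, b_dose, cell_line)
        if not ok:
            rows.append(
                CombinationIndexResult(
                    ci=float("nan"),
                    e_a=EquivalentDose(float("nan")),
                    e_b=EquivalentDose(float("nan")),
                    synergy_class="unfit",
                    effect_level=effect_level,
                    record=rec,
                    fit_ok=False,
                )
            )
            continue
        ea = ic50_equivalent(a_ic50, ic50_a)
        eb = ic50_equivalent(b_dose, ic50_b) if b_dose > 0 else EquivalentDose(0.0)
        rows.append(combination_index(ea, eb, effect_level, record=rec))
    return rows


def round_display(x: float, ndigits: int = 3) -> float:
    """Half-up rounding for report display (Python's round() is banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
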