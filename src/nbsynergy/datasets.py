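"""Published reference measurements for the SSZ + DFMO combination.

Single-agent IC50s and combination-treatment measurements for sulfasalazine
(SSZ) and alpha-difluoromethylornithine (DFMO) in two neuroblastoma cell
lines, from 48-h MTS viability assays.  Each combination row pairs the IC50
of SSZ re-measured in the presence of a fixed DFMO dose with that DFMO
dose — the fixed-B/varying-A design scored by :mod:`nbsynergy.synergy`.
"""

from __future__ import annotations

from .synergy import CombinationRecord

__all__ = [
    "SSZ_IC50_UM",
    "DFMO_IC50_MM",
    "COMBINATION_DOSES",
    "combination_records",
]

# single-agent IC50 of SSZ, μM
SSZ_IC50_UM = {"SK-N-Be(2)c": 133.1, "LAN-5": 337.2}

# single-agent IC50 of DFMO, mM
DFMO_IC50_MM = {"SK-N-Be(2)c": 4.07, "LAN-5": 5.79}

# (SSZ combination IC50 in μM, fixed DFMO dose in mM) per cell line
COMBINATION_DOSES: dict[str, list[tuple[float, float]]] = {
    "SK-N-Be(2)c": [
        (54.360, 1.800),
        (29.640, 2.600),
        (41.740, 3.400),
        (18.700, 4.200),
        (55.180, 5.000),
    ],
    "LAN-5": [
        (1.207, 1.200),
        (58.250, 1.800),
        (5.152, 2.700),
        (147.900, 4.000),
        (0.893, 6.000),
    ],
}


def combination_records(cell_line: str) -> list[CombinationRecord]:
    """The combination design points of one cell line as records."""
    return [
        CombinationRecord(a, b, cell_line) for a, b in COMBINATION_DOSES[cell_line]
    ]
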