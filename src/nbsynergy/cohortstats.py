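"""Clinical-cohort expression statistics.

Implements the association tests used for neuroblastoma expression cohorts:
Kruskal-Wallis tests of a gene's expression against clinical groupings
(age at diagnosis, MYCN amplification, INSS stage), Pearson correlation of
two genes on the 2log (log base-2) scale with significance from

    t = r / sqrt((1 - r^2) / (n - 2)),   df = n - 2,

a ranked dual-gene export for plotting, and the one-tailed paired t-test
used for treated-vs-control viability comparisons.  Unknown or missing
annotations are dropped listwise per test, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortMatrix",
    "AssociationResult",
    "CorrelationResult",
    "UNKNOWN_LABELS",
    "kruskal_wallis",
    "pearson_log2",
    "correlation_significance",
    "ranked_dual_gene_export",
    "paired_onetailed_t",
]

UNKNOWN_LABELS = {"unknown", "n.d.", "nd", "na", ""}

AGE_GROUPS = ("<18mo", ">=18mo")
MYCN_GROUPS = ("amplified", "not amplified")
INSS_STAGES = ("1", "2", "3", "4", "4S")


@dataclass
class CohortMatrix:
    """Sample x gene expression on 2log scale plus clinical annotations.

    ``expression`` is a samples-by-genes DataFrame (2log values);
    ``annotations`` is a samples-by-fields DataFrame of categorical clinical
    covariates sharing the same index.
    """

    expression: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.annotations.index):
            raise ValueError("expression and annotations must share sample index")

    @property
    def samples(self) -> pd.Index:
        return self.expression.index

    def gene(self, name: str) -> pd.Series:
        if name not in self.expression.columns:
            raise KeyError(f"gene {name!r} not in cohort")
        return self.expression[name]

    def groups(self, field: str) -> pd.Series:
        if field not in self.annotations.columns:
            raise KeyError(f"annotation {field!r} not in cohort")
        return self.annotations[field]


@dataclass(frozen=True)
class AssociationResult:
    """A group-association test result (Kruskal-Wallis H or paired t)."""

    statistic: float
    p_value: float
    groups: dict[str, int]
    direction: str | None = None
    p_exact: float | None = None
    statistic_name: str = "H"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p_value: float
    degenerate: bool = False

    @property
    def df(self) -> int:
        return self.n - 2


def _drop_unknown(values, groups):
    v = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    keep = np.isfinite(v) & ~np.isin(np.char.lower(g), list(UNKNOWN_LABELS))
    return v[keep], g[keep]


def _kw_statistic(values: np.ndarray, groups: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H (used by the permutation path)."""
    ranks = stats.rankdata(values)
    n = len(values)
    h = 0.0
    for lab in np.unique(groups):
        r = ranks[groups == lab]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def _exact_permutation_p(values: np.ndarray, groups: np.ndarray) -> float:
    """Exact permutation p for small n: enumerate all assignments of the
    observed group sizes to the observed values."""
    labels, sizes = np.unique(groups, return_counts=True)
    h_obs = _kw_statistic(values, groups)
    n = len(values)
    idx = np.arange(n)

    count = 0
    total = 0

    def rec(remaining: np.ndarray, li: int, assignment: np.ndarray):
        nonlocal count, total
        if li == len(labels) - 1:
            assignment = assignment.copy()
            assignment[remaining] = li
            h = _kw_statistic(values, assignment)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for chosen in combinations(range(len(remaining)), int(sizes[li])):
            sub = assignment.copy()
            chosen_idx = remaining[list(chosen)]
            sub[chosen_idx] = li
            rest = np.delete(remaining, list(chosen))
            rec(rest, li + 1, sub)

    rec(idx, 0, np.full(n, -1))
    return count / total


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence[str],
    exact_max_n: int = 8,
) -> AssociationResult:
    """Kruskal-Wallis association of expression values with group labels.

    Uses the tie-corrected H statistic with the chi-square approximation on
    k-1 degrees of freedom.  For total n <= ``exact_max_n`` an exact
    permutation p over all label assignments is also computed and reported
    as ``p_exact``.  Samples with unknown annotations are dropped first.
    """
    v, g = _drop_unknown(values, groups)
    labels, sizes = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    group_sizes = {str(l): int(s) for l, s in zip(labels, sizes)}
    medians = {str(l): float(np.median(v[g == l])) for l in labels}
    direction = max(medians, key=medians.get)
    if np.allclose(v, v[0]):
        return AssociationResult(0.0, 1.0, group_sizes, direction, None)
    h, p = stats.kruskal(*[v[g == l] for l in labels])
    p_exact = _exact_permutation_p(v, g) if len(v) <= exact_max_n else None
    return AssociationResult(float(h), float(p), group_sizes, direction, p_exact)


def correlation_significance(r: float, n: int) -> tuple[float, float]:
    """t statistic and two-sided p for a Pearson correlation.

    t = r / sqrt((1 - r^2)/(n - 2)), compared against Student's t with
    n - 2 degrees of freedom.  |r| = 1 returns (inf, 0) as the limit.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return float("inf") if r > 0 else float("-inf"), 0.0
    t = r / np.sqrt((1.0 - r * r) / (n - 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(t), float(p)


def pearson_log2(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of two 2log expression vectors (no re-transform)
    with significance from the t formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    r = float(np.corrcoef(x, y)[0, 1])
    degenerate = abs(r) >= 1.0
    t, p = correlation_significance(min(max(r, -1.0), 1.0), len(x))
    return CorrelationResult(r=r, n=len(x), t=t, p_value=p, degenerate=degenerate)


def ranked_dual_gene_export(
    cohort: CohortMatrix, gene_rank: str, gene_other: str
) -> pd.DataFrame:
    """Samples ordered by ascending expression of ``gene_rank`` (ties broken
    by sample id), carrying both genes' 2log values and every clinical
    annotation — the plotting table for ranked dual-gene figures."""
    a = cohort.gene(gene_rank)
    b = cohort.gene(gene_other)
    df = pd.DataFrame({gene_rank: a, gene_other: b}).join(cohort.annotations)
    df = df.reset_index(names="sample")
    return df.sort_values([gene_rank, "sample"], kind="mergesort").reset_index(
        drop=True
    )


def paired_onetailed_t(
    treated: Sequence[float], control: Sequence[float]
) -> AssociationResult:
    """Paired one-tailed t-test in the direction control > treated.

    The alternative is that treatment reduces viability.  Identical paired
    values give t = 0, p = 0.5; non-zero constant differences are degenerate
    (zero variance) and raise.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape or len(treated) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = control - treated
    sd = np.std(d, ddof=1)
    n = len(d)
    if sd == 0:
        if np.all(d == 0):
            return AssociationResult(
                0.0, 0.5, {"treated": n, "control": n}, None, None, "t"
            )
        raise ValueError("zero-variance differences: paired t undefined")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(stats.t.sf(t, df=n - 1))
    return AssociationResult(
        t, p, {"treated": n, "control": n}, "control" if t > 0 else "treated", None, "t"
    )
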