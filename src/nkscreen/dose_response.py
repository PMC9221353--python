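"""Dose-response validation: lysis tables, exact rank-sum, effective dose.

Candidate compounds from the screen are re-tested over a concentration
range (vehicle 0 plus increasing doses) at one or more effector:target
ratios, with replicate wells per (dose, ratio) cell.  With only a few
technical replicates per cell, asymptotic rank tests are meaningless, so
treated-vs-vehicle comparisons use the exact Mann-Whitney/Wilcoxon
rank-sum null obtained by full enumeration of rank assignments; ties are
handled with mid-ranks, enumerating over the observed tie pattern.

The minimum effective dose (MED) is the smallest tested dose whose lysis
significantly exceeds the vehicle control.  Because the claim being
tested is directional (enhancement), the MED call uses the one-sided
exact tail together with a positive mean difference; the two-tailed
p-value is also reported for descriptive use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .cytotoxicity import specific_lysis

MAX_EXACT_GROUP = 10


@dataclass(frozen=True)
class RankSumResult:
    """Exact rank-sum test result for group A versus group B.

    ``statistic`` is the (mid-)rank sum of group A.  ``p_two_tailed``
    doubles the smaller exact tail (capped at 1); ``p_greater`` is the
    exact one-sided tail for "A tends larger than B".
    """

    statistic: float
    p_two_tailed: float
    p_greater: float
    method: str  # "exact" (no ties) or "midrank_exact"


@dataclass(frozen=True)
class DoseResponseTable:
    """Percent-lysis replicates per (dose, E:T ratio) cell for one drug."""

    drug_id: str
    doses: tuple[float, ...]
    e_t_ratios: tuple[float, ...]
    cells: Mapping[tuple[float, float], tuple[float, ...]]

    def __post_init__(self) -> None:
        if 0.0 not in self.doses:
            raise ValueError("dose 0 (vehicle control) is required")

    def cell(self, dose: float, ratio: float) -> tuple[float, ...]:
        return self.cells[(dose, ratio)]


@dataclass(frozen=True)
class MedResult:
    drug_id: str
    e_t_ratio: float
    minimum_effective_dose: float | None
    alpha: float


def _midranks(values: Sequence[float]) -> list[int]:
    """Mid-ranks of pooled values, doubled so ties stay integral."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks2 = [0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        # average rank of positions i..j (1-based), doubled
        avg2 = (i + 1) + (j + 1)
        for k in range(i, j + 1):
            ranks2[order[k]] = avg2
        i = j + 1
    return ranks2


@lru_cache(maxsize=4096)
def _null_tail_counts(ranks2: tuple[int, ...], n_a: int) -> dict[int, int]:
    """Counts of the rank-sum statistic over all C(n, n_a) assignments."""
    counts: dict[int, int] = {}
    for combo in combinations(ranks2, n_a):
        s = sum(combo)
        counts[s] = counts.get(s, 0) + 1
    return counts


def rank_sum_exact(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankSumResult:
    """Exact two-group rank-sum test by full enumeration.

    Both groups must have between 2 and 10 observations; beyond that the
    enumeration is no longer sensible and an approximate test (out of
    scope here) should be used instead.
    """
    n_a, n_b = len(group_a), len(group_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    if n_a > MAX_EXACT_GROUP or n_b > MAX_EXACT_GROUP:
        raise ValueError(
            f"exact enumeration supports group sizes up to {MAX_EXACT_GROUP}; "
            "use an approximate rank-sum test for larger groups"
        )
    pooled = list(group_a) + list(group_b)
    ranks2 = _midranks(pooled)
    w2 = sum(ranks2[:n_a])
    ties = len(set(pooled)) != len(pooled)

    # Enumerate over the multiset of mid-ranks; sort for cache hits.
    counts = _null_tail_counts(tuple(sorted(ranks2)), n_a)
    total = math.comb(n_a + n_b, n_a)
    p_le = sum(c for s, c in counts.items() if s <= w2) / total
    p_ge = sum(c for s, c in counts.items() if s >= w2) / total
    return RankSumResult(
        statistic=w2 / 2.0,
        p_two_tailed=min(1.0, 2.0 * min(p_le, p_ge)),
        p_greater=p_ge,
        method="midrank_exact" if ties else "exact",
    )


REQUIRED_COLUMNS = ("drug_id", "dose_uM", "et_ratio", "replicate", "role", "rlu")


def dose_response_lysis(
    data: pd.DataFrame, drug_id: str | None = None
) -> DoseResponseTable:
    """Build a dose x E:T percent-lysis table from long-format well data.

    ``data`` has one row per well with columns ``drug_id, dose_uM,
    et_ratio, replicate, role, rlu``; ``role`` is ``experimental`` for
    treated/vehicle co-culture wells, ``spontaneous`` for target-alone
    anchors and ``maximal`` for digitonin anchors (anchor rows ignore
    dose and ratio).  Anchors are summarized by their means and every
    experimental well converted to percent specific lysis.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"dose-response table missing columns: {missing}")
    if drug_id is None:
        ids = sorted(data.loc[data["role"] == "experimental", "drug_id"].unique())
        if len(ids) != 1:
            raise ValueError(
                f"expected a single drug_id, got {ids}; pass drug_id explicitly"
            )
        drug_id = ids[0]
    else:
        data = data[
            (data["drug_id"] == drug_id) | (data["role"] != "experimental")
        ]

    spont = data.loc[data["role"] == "spontaneous", "rlu"]
    maxi = data.loc[data["role"] == "maximal", "rlu"]
    if spont.empty or maxi.empty:
        raise ValueError("spontaneous and maximal anchor wells are required")
    spont_mean = float(spont.mean())
    max_mean = float(maxi.mean())

    exp = data[data["role"] == "experimental"]
    doses = tuple(sorted(exp["dose_uM"].unique()))
    if 0.0 not in doses:
        raise ValueError("dose 0 (vehicle control) rows are required")
    ratios = tuple(sorted(exp["et_ratio"].unique()))
    cells: dict[tuple[float, float], tuple[float, ...]] = {}
    for (dose, ratio), grp in exp.groupby(["dose_uM", "et_ratio"]):
        lysis = tuple(
            specific_lysis(v, spont_mean, max_mean).percent_specific_lysis
            for v in grp.sort_values("replicate")["rlu"]
        )
        cells[(float(dose), float(ratio))] = lysis
    return DoseResponseTable(
        drug_id=drug_id, doses=doses, e_t_ratios=ratios, cells=cells
    )


def minimum_effective_dose(
    table: DoseResponseTable, alpha: float = 0.05
) -> list[MedResult]:
    """Minimum effective dose per E:T ratio.

    The MED is the smallest non-zero dose whose lysis exceeds the
    vehicle (dose 0) cell with one-sided exact rank-sum p <= alpha and a
    positive mean difference; ``None`` when no dose qualifies.  Each
    cell needs at least 2 replicates.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    results = []
    for ratio in table.e_t_ratios:
        baseline = table.cell(0.0, ratio)
        med: float | None = None
        for dose in sorted(d for d in table.doses if d > 0):
            treated = table.cell(dose, ratio)
            res = rank_sum_exact(treated, baseline)
            mean_diff = sum(treated) / len(treated) - sum(baseline) / len(
                baseline
            )
            if res.p_greater <= alpha and mean_diff > 0:
                med = dose
                break
        results.append(
            MedResult(
                drug_id=table.drug_id,
                e_t_ratio=ratio,
                minimum_effective_dose=med,
                alpha=alpha,
            )
        )
    return results
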