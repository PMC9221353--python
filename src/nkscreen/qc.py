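"""Plate-level Z'-factor quality control.

The Z'-factor summarizes a plate's assay window from its control wells::

    Z' = 1 - (3*SD+ + 3*SD-) / |m+ - m-|

where ``m`` and ``SD`` are the mean and sample standard deviation of the
positive (+) and negative (-) control wells.  Z' is at most 1 (noise-free
controls) and unbounded below; 0.5-1 is conventionally an excellent
("good") assay, 0-0.5 a marginal ("fair") one, and below 0 the control
distributions overlap ("poor").  With identical control means the window
is undefined and the plate is excluded from screen averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .plate_model import (
    Condition,
    PlateRead,
    Role,
    ScreenLayout,
    control_values,
)


class ZClass(str, Enum):
    GOOD = "good"
    FAIR = "fair"
    POOR = "poor"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class ControlStats:
    """Means and sample SDs of a plate's control groups."""

    m_pos: float
    m_neg: float
    sd_pos: float
    sd_neg: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ZPrimeResult:
    z_prime: float  # NaN when classification is undefined
    classification: ZClass
    plate_id: str | None = None
    condition: Condition | None = None
    replicate_id: int | None = None


@dataclass(frozen=True)
class ConditionQC:
    """Per-condition QC: pooled mean Z' across plates and replicate days."""

    condition: Condition
    mean_z: float
    results: tuple[ZPrimeResult, ...]
    undefined_plates: tuple[str, ...]


@dataclass(frozen=True)
class QCReport:
    conditions: Mapping[Condition, ConditionQC]


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    m = sum(values) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
    return m, sd


def control_stats(pos: Sequence[float], neg: Sequence[float]) -> ControlStats:
    """Control-group statistics; each group needs >= 2 wells for the SD."""
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            "need at least 2 wells per control group to estimate the SD "
            f"(got {len(pos)} positive, {len(neg)} negative)"
        )
    m_pos, sd_pos = _mean_sd(pos)
    m_neg, sd_neg = _mean_sd(neg)
    return ControlStats(
        m_pos=m_pos,
        m_neg=m_neg,
        sd_pos=sd_pos,
        sd_neg=sd_neg,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def classify_z(z: float) -> ZClass:
    """Band a Z' value: good [0.5, 1], fair [0, 0.5), poor (-inf, 0)."""
    if math.isnan(z):
        return ZClass.UNDEFINED
    if z > 1.0:
        raise ValueError(f"Z' cannot exceed 1, got {z}")
    if z >= 0.5:
        return ZClass.GOOD
    if z >= 0.0:
        return ZClass.FAIR
    return ZClass.POOR


def z_prime(
    stats: ControlStats,
    *,
    plate_id: str | None = None,
    condition: Condition | None = None,
    replicate_id: int | None = None,
) -> ZPrimeResult:
    """Z'-factor of one plate from its control statistics.

    Equal control means give an undefined window: the result carries
    ``z_prime = NaN`` and classification ``undefined`` rather than
    raising, so screen-level reporting can list the plate.
    """
    if stats.m_pos == stats.m_neg:
        z = math.nan
    else:
        z = 1.0 - (3.0 * stats.sd_pos + 3.0 * stats.sd_neg) / abs(
            stats.m_pos - stats.m_neg
        )
    return ZPrimeResult(
        z_prime=z,
        classification=classify_z(z),
        plate_id=plate_id,
        condition=condition,
        replicate_id=replicate_id,
    )


def screen_qc_report(
    reads: Iterable[PlateRead], layout: ScreenLayout
) -> QCReport:
    """Per-plate Z' for every read plus the per-condition pooled mean.

    The per-condition mean pools all plates across replicate days;
    plates with an undefined Z' are excluded from the mean and listed.
    """
    per_condition: dict[Condition, list[ZPrimeResult]] = {
        c: [] for c in Condition
    }
    for read in reads:
        plate_layout = layout.plate(read.plate_id, read.condition)
        pos = control_values(read, plate_layout, Role.POSITIVE_CONTROL)
        neg = control_values(read, plate_layout, Role.NEGATIVE_CONTROL)
        result = z_prime(
            control_stats(pos, neg),
            plate_id=read.plate_id,
            condition=read.condition,
            replicate_id=read.replicate_id,
        )
        per_condition[read.condition].append(result)

    conditions: dict[Condition, ConditionQC] = {}
    for condition, results in per_condition.items():
        if not results:
            continue
        defined = [r.z_prime for r in results if not math.isnan(r.z_prime)]
        undefined = tuple(
            r.plate_id or "?" for r in results if math.isnan(r.z_prime)
        )
        mean_z = sum(defined) / len(defined) if defined else math.nan
        conditions[condition] = ConditionQC(
            condition=condition,
            mean_z=mean_z,
            results=tuple(results),
            undefined_plates=undefined,
        )
    return QCReport(conditions=conditions)
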