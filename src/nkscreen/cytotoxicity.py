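"""Percent specific lysis and effector:target lysis curves.

A luciferase-release killing assay reads out target-cell death as
luminescence of released luciferase.  Percent specific lysis normalizes
the experimental signal between two anchors measured on the same plate:
spontaneous release (targets alone, no effectors) and maximal release
(targets fully lysed with digitonin)::

    % specific lysis = (experimental - spontaneous)
                       / (maximal - spontaneous) * 100

Values below 0% or above 100% are possible with noisy anchors; they are
reported as-is and flagged, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

BELOW_ZERO = "below_zero"
ABOVE_MAX = "above_max"


class DegenerateAssayError(ValueError):
    """Maximal release does not exceed spontaneous release."""


@dataclass(frozen=True)
class LysisResult:
    percent_specific_lysis: float
    flags: frozenset[str]


@dataclass(frozen=True)
class CurvePoint:
    """Lysis at one effector:target ratio, replicates retained."""

    e_t_ratio: float
    replicate_lysis: tuple[float, ...]
    mean: float
    sd: float  # sample SD (n-1); NaN for a single replicate


@dataclass(frozen=True)
class LysisCurve:
    points: tuple[CurvePoint, ...]


def specific_lysis(
    experimental: float, spontaneous: float, maximal: float
) -> LysisResult:
    """Percent specific lysis of one experimental release value.

    Parameters are raw luminescence values (RLU, all >= 0); ``maximal``
    must strictly exceed ``spontaneous`` or the assay has no dynamic
    range and a :class:`DegenerateAssayError` is raised.
    """
    for name, v in (
        ("experimental", experimental),
        ("spontaneous", spontaneous),
        ("maximal", maximal),
    ):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} release must be finite and >= 0, got {v}")
    if maximal <= spontaneous:
        raise DegenerateAssayError(
            f"maximal release ({maximal}) must exceed spontaneous release "
            f"({spontaneous})"
        )
    value = (experimental - spontaneous) / (maximal - spontaneous) * 100.0
    flags: set[str] = set()
    if value < 0.0:
        flags.add(BELOW_ZERO)
    if value > 100.0:
        flags.add(ABOVE_MAX)
    return LysisResult(percent_specific_lysis=value, flags=frozenset(flags))


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def _sample_sd(values: Sequence[float]) -> float:
    n = len(values)
    if n < 2:
        return math.nan
    m = _mean(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


def lysis_curve(
    experimental: Mapping[float, Sequence[float]],
    spontaneous: Sequence[float],
    maximal: Sequence[float],
) -> LysisCurve:
    """Lysis curve over effector:target ratios.

    ``experimental`` maps each E:T ratio to its replicate RLUs.  The
    spontaneous and maximal anchors are summarized by the arithmetic
    mean of their replicate wells; each experimental replicate is then
    converted to percent specific lysis against those means.
    """
    if not experimental:
        raise ValueError("no E:T ratios supplied")
    if not spontaneous or not maximal:
        raise ValueError("need at least one spontaneous and one maximal well")
    ratios = list(experimental)
    if any(r <= 0 for r in ratios):
        raise ValueError("E:T ratios must be strictly positive")
    if len(set(ratios)) != len(ratios):
        raise ValueError("E:T ratios must be unique")
    spont = _mean(spontaneous)
    maxi = _mean(maximal)
    points = []
    for ratio in sorted(ratios):
        reps = [
            specific_lysis(v, spont, maxi).percent_specific_lysis
            for v in experimental[ratio]
        ]
        if not reps:
            raise ValueError(f"no replicate wells at E:T {ratio}")
        points.append(
            CurvePoint(
                e_t_ratio=ratio,
                replicate_lysis=tuple(reps),
                mean=_mean(reps),
                sd=_sample_sd(reps),
            )
        )
    return LysisCurve(points=tuple(points))
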