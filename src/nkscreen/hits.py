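"""Fold-change normalization, hit calling, and the toxicity counter-screen.

Each compound well's luminescence is divided by the mean of the DMSO
control wells of its own plate, giving a unitless fold-change.  In the
co-culture condition, luciferase release tracks NK-mediated killing, so
a fold-change >= 1.3 marks a putative cytotoxicity enhancer.  The same
statistic computed on the target-alone counter-screen plates catches
compounds that lyse the target cells directly: any target-alone
fold-change >= 1.3 excludes the compound regardless of its co-culture
signal.  A compound is a hit when every co-culture replicate day meets
the threshold and the counter-screen is clean; compounds assayed on one
day only are flagged ``single_replicate_hit`` rather than silently
included or dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .plate_model import Condition, PlateLayout, PlateRead, ReadError

DEFAULT_THRESHOLD = 1.3


class HitStatus(str, Enum):
    HIT = "hit"
    NON_HIT = "non_hit"
    EXCLUDED_TOXIC = "excluded_toxic"
    SINGLE_REPLICATE_HIT = "single_replicate_hit"


@dataclass(frozen=True)
class FoldChangeRecord:
    """One well's fold-change over its plate's DMSO mean."""

    compound_id: str
    condition: Condition
    replicate_id: int
    fc: float


@dataclass(frozen=True)
class AggregatedFoldChange:
    mean_fc: float
    fcs: tuple[float, ...]
    n_replicates: int


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    coculture_fc: tuple[float, ...]
    target_alone_fc: tuple[float, ...]
    mean_fc: float
    status: HitStatus
    n_replicates: int
    notes: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class HitTable:
    """Hit calls sorted by descending mean co-culture fold-change.

    Ties are broken lexicographically by compound id so ranking is
    reproducible byte-for-byte.
    """

    calls: tuple[HitCall, ...]
    threshold: float
    provenance: Mapping[str, object] = field(default_factory=dict)

    def hits(self) -> list[HitCall]:
        return [c for c in self.calls if c.status is HitStatus.HIT]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "compound_id": c.compound_id,
                    "mean_fc": c.mean_fc,
                    "fc_replicates": ";".join(f"{v:.6g}" for v in c.coculture_fc),
                    "fc_target_alone_max": (
                        max(c.target_alone_fc) if c.target_alone_fc else float("nan")
                    ),
                    "n_replicates": c.n_replicates,
                    "status": c.status.value,
                }
            )
        return pd.DataFrame(rows)


def fold_change_plate(
    read: PlateRead, layout: PlateLayout, *, aggregation: str = "mean"
) -> list[FoldChangeRecord]:
    """Fold-change over the plate's own DMSO controls, one per compound well.

    ``aggregation`` picks the DMSO summary: ``"mean"`` (default) or
    ``"median"``.  Empty wells are skipped; a zero DMSO summary is a
    degenerate plate and raises.
    """
    from .plate_model import Role, control_values

    dmso = control_values(read, layout, Role.NEGATIVE_CONTROL)
    if aggregation == "mean":
        denom = sum(dmso) / len(dmso)
    elif aggregation == "median":
        denom = float(pd.Series(dmso).median())
    else:
        raise ValueError(f"unknown DMSO aggregation {aggregation!r}")
    if denom == 0:
        raise ReadError(f"plate {read.plate_id}: DMSO control {aggregation} is 0")
    records = []
    for well, compound_id in layout.compound_wells():
        if well not in read.values:
            raise ReadError(f"plate {read.plate_id}: missing compound well {well}")
        records.append(
            FoldChangeRecord(
                compound_id=compound_id,
                condition=read.condition,
                replicate_id=read.replicate_id,
                fc=read.values[well] / denom,
            )
        )
    return records


def aggregate_replicates(fcs: Sequence[float]) -> AggregatedFoldChange:
    """Arithmetic mean over the available replicate-day fold-changes."""
    if len(fcs) == 0:
        raise ValueError("no replicate fold-changes to aggregate")
    return AggregatedFoldChange(
        mean_fc=sum(fcs) / len(fcs),
        fcs=tuple(fcs),
        n_replicates=len(fcs),
    )


def _by_compound(
    records: Iterable[FoldChangeRecord],
) -> dict[str, list[FoldChangeRecord]]:
    out: dict[str, list[FoldChangeRecord]] = {}
    for r in records:
        out.setdefault(r.compound_id, []).append(r)
    for rs in out.values():
        rs.sort(key=lambda r: r.replicate_id)
    return out


def call_hits(
    coculture: Iterable[FoldChangeRecord],
    target_alone: Iterable[FoldChangeRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> HitTable:
    """Call hits from co-culture and counter-screen fold-change records.

    Status logic, in order of precedence:

    * ``excluded_toxic`` -- any target-alone replicate fc >= threshold;
    * ``hit`` -- fc >= threshold (inclusive) in every co-culture
      replicate, with at least two replicate days;
    * ``single_replicate_hit`` -- only one co-culture day available and
      it meets the threshold;
    * ``non_hit`` -- otherwise.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cc = _by_compound(coculture)
    ta = _by_compound(target_alone)
    only_cc = sorted(set(cc) - set(ta))
    only_ta = sorted(set(ta) - set(cc))
    for cid in only_cc:
        warnings.warn(
            f"compound {cid!r} has no target-alone records; counter-screen "
            "not applied",
            stacklevel=2,
        )
    for cid in only_ta:
        warnings.warn(
            f"compound {cid!r} has no co-culture records; called from "
            "counter-screen only",
            stacklevel=2,
        )

    calls = []
    for cid in sorted(set(cc) | set(ta)):
        cc_fcs = tuple(r.fc for r in cc.get(cid, []))
        ta_fcs = tuple(r.fc for r in ta.get(cid, []))
        notes: list[str] = []
        if not ta_fcs:
            notes.append("no_target_alone_data")
        if not cc_fcs:
            notes.append("no_coculture_data")
        n_rep = len(cc_fcs)
        if any(fc >= threshold for fc in ta_fcs):
            status = HitStatus.EXCLUDED_TOXIC
        elif cc_fcs and all(fc >= threshold for fc in cc_fcs):
            status = (
                HitStatus.HIT if n_rep >= 2 else HitStatus.SINGLE_REPLICATE_HIT
            )
        else:
            status = HitStatus.NON_HIT
        agg = aggregate_replicates(cc_fcs) if cc_fcs else None
        calls.append(
            HitCall(
                compound_id=cid,
                coculture_fc=cc_fcs,
                target_alone_fc=ta_fcs,
                mean_fc=agg.mean_fc if agg else float("nan"),
                status=status,
                n_replicates=max(n_rep, 1) if (cc_fcs or ta_fcs) else 0,
                notes=tuple(notes),
            )
        )
    table = HitTable(
        calls=tuple(calls),
        threshold=threshold,
        provenance={"n_compounds": len(calls)},
    )
    return rank_hits(table)


def rank_hits(table: HitTable) -> HitTable:
    """Sort by descending mean fold-change, ties by compound id."""
    import math

    def key(c: HitCall) -> tuple[float, str]:
        mean = c.mean_fc if not math.isnan(c.mean_fc) else float("-inf")
        return (-mean, c.compound_id)

    return HitTable(
        calls=tuple(sorted(table.calls, key=key)),
        threshold=table.threshold,
        provenance=table.provenance,
    )


def select_candidates(
    table: HitTable, annotations: Mapping[str, bool]
) -> list[HitCall]:
    """Apply curation annotations to the hits.

    ``annotations`` maps compound id to a deprioritize flag (drug no
    longer in use, unavailable, or already a known enhancer).  Hits
    (including single-replicate hits) without an annotation are kept
    with a warning.  Order is preserved.
    """
    out = []
    for call in table.calls:
        if call.status not in (HitStatus.HIT, HitStatus.SINGLE_REPLICATE_HIT):
            continue
        if call.compound_id not in annotations:
            warnings.warn(
                f"no curation annotation for hit {call.compound_id!r}; "
                "treating as not deprioritized",
                stacklevel=2,
            )
            out.append(call)
        elif not annotations[call.compound_id]:
            out.append(call)
    return out


# --- packaged dual-day hit-list fixture -----------------------------------

def load_table1_fixture() -> pd.DataFrame:
    """The packaged 14-compound dual-day hit list with printed fold-changes."""
    with resources.files("nkscreen.data").joinpath(
        "table1_fixture.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    for col in ("candidate", "single_replicate"):
        df[col] = df[col].astype(str).str.lower().eq("true")
    return df


def fixture_records(
    df: pd.DataFrame | None = None,
) -> tuple[list[FoldChangeRecord], list[FoldChangeRecord]]:
    """Fold-change records reconstructed from the packaged hit-list fixture.

    The fixture stores one reported aggregate fold-change per compound;
    it is expanded to both replicate days so the dual-day rule can be
    exercised (all 14 fixture compounds met the threshold on both days).
    Target-alone records are 1.0 -- none of the listed compounds was
    flagged by the toxicity counter-screen.
    """
    if df is None:
        df = load_table1_fixture()
    coculture = []
    target_alone = []
    for row in df.itertuples(index=False):
        for rep in (1, 2):
            coculture.append(
                FoldChangeRecord(
                    compound_id=row.compound_id,
                    condition=Condition.COCULTURE,
                    replicate_id=rep,
                    fc=float(row.fold_change),
                )
            )
            target_alone.append(
                FoldChangeRecord(
                    compound_id=row.compound_id,
                    condition=Condition.TARGET_ALONE,
                    replicate_id=rep,
                    fc=1.0,
                )
            )
    return coculture, target_alone


def fixture_annotations(df: pd.DataFrame | None = None) -> dict[str, bool]:
    """Deprioritize flags from the fixture: True for non-candidates."""
    if df is None:
        df = load_table1_fixture()
    return {
        row.compound_id: not bool(row.candidate)
        for row in df.itertuples(index=False)
    }
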