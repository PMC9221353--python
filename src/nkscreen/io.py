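"""Readers and writers for the pipeline's file dialects.

Canonical interchange is the long CSV read table
(``plate_id,replicate_id,condition,well,rlu``); 8x12 grid CSV exports
with a ``key=value`` metadata header, as plate readers produce, are
accepted for import.  Plate maps travel as JSON (or a simple
well/role/compound TSV); hit tables, QC reports and fold-change tables
are written as TSV/JSON with the analysis parameters embedded so every
output is reproducible from its own header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .hits import HitTable
from .plate_model import (
    Condition,
    PlateLayout,
    PlateRead,
    ReadError,
    Role,
    ScreenLayout,
    WellCoord,
    WellRole,
    iter_wells,
)
from .qc import QCReport

LONG_CSV_COLUMNS = ("plate_id", "replicate_id", "condition", "well", "rlu")


# --- layouts ---------------------------------------------------------------

def layout_to_json(layout: ScreenLayout) -> dict:
    plates = []
    for condition in Condition:
        for plate in layout.plates[condition]:
            plates.append(
                {
                    "plate_id": plate.plate_id,
                    "condition": condition.value,
                    "roles": {
                        str(w): {
                            "role": wr.role.value,
                            **(
                                {"compound_id": wr.compound_id}
                                if wr.compound_id
                                else {}
                            ),
                        }
                        for w, wr in sorted(plate.roles.items())
                    },
                }
            )
    return {"version": __version__, "plates": plates}


def layout_from_json(doc: dict) -> ScreenLayout:
    plates: dict[Condition, list[PlateLayout]] = {c: [] for c in Condition}
    index: dict[str, tuple[str, WellCoord]] = {}
    for entry in doc["plates"]:
        condition = Condition(entry["condition"])
        roles = {}
        for well_str, rr in entry["roles"].items():
            well = WellCoord.parse(well_str)
            roles[well] = WellRole(
                Role(rr["role"]), compound_id=rr.get("compound_id")
            )
        plate = PlateLayout(
            plate_id=entry["plate_id"], condition=condition, roles=roles
        )
        plates[condition].append(plate)
        if condition is Condition.TARGET_ALONE:
            for well, cid in plate.compound_wells():
                index[cid] = (plate.plate_id, well)
    return ScreenLayout(
        plates={c: tuple(ps) for c, ps in plates.items()},
        compound_index=index,
    )


def write_layout(layout: ScreenLayout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(layout_to_json(layout), indent=1))


def read_layout(path: str | Path) -> ScreenLayout:
    return layout_from_json(json.loads(Path(path).read_text()))


def plate_layout_from_tsv(
    path: str | Path, *, plate_id: str, condition: Condition
) -> PlateLayout:
    """Plate map from a TSV with columns ``well, role, compound_id``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    roles: dict[WellCoord, WellRole] = {
        w: WellRole(Role.EMPTY) for w in iter_wells()
    }
    for _, row in df.iterrows():
        cid = row.get("compound_id")
        if pd.isna(cid):
            cid = None
        roles[WellCoord.parse(row["well"])] = WellRole(Role(row["role"]), cid)
    return PlateLayout(plate_id=plate_id, condition=condition, roles=roles)


# --- plate reads -----------------------------------------------------------

def write_reads_long_csv(reads: Iterable[PlateRead], path: str | Path) -> None:
    rows = []
    for read in reads:
        for well in sorted(read.values):
            rows.append(
                {
                    "plate_id": read.plate_id,
                    "replicate_id": read.replicate_id,
                    "condition": read.condition.value,
                    "well": str(well),
                    "rlu": repr(read.values[well]),
                }
            )
    pd.DataFrame(rows, columns=list(LONG_CSV_COLUMNS)).to_csv(path, index=False)


def _reads_from_long_frame(df: pd.DataFrame, source: str) -> list[PlateRead]:
    missing = [c for c in LONG_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ReadError(f"{source}: missing columns {missing}")
    errors: list[str] = []
    reads: dict[tuple[str, str, int], dict[WellCoord, float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        line = f"{source}:{i}"
        try:
            well = WellCoord.parse(str(row.well))
        except ValueError:
            errors.append(f"{line}: unknown well {row.well!r}")
            continue
        try:
            rlu = float(row.rlu)
        except (TypeError, ValueError):
            errors.append(f"{line}: non-numeric RLU {row.rlu!r}")
            continue
        try:
            condition = Condition(str(row.condition))
        except ValueError:
            errors.append(f"{line}: unknown condition {row.condition!r}")
            continue
        key = (str(row.plate_id), condition.value, int(row.replicate_id))
        wells = reads.setdefault(key, {})
        if well in wells:
            errors.append(
                f"{line}: duplicate row for plate {key[0]} well {well} "
                f"replicate {key[2]}"
            )
            continue
        wells[well] = rlu
    if errors:
        raise ReadError("; ".join(errors))
    return [
        PlateRead(
            plate_id=pid,
            condition=Condition(cond),
            replicate_id=rep,
            values=wells,
        )
        for (pid, cond, rep), wells in reads.items()
    ]


def _read_grid_csv(path: Path) -> list[PlateRead]:
    """One plate per file: ``key=value`` header lines, then an 8x12 grid."""
    lines = path.read_text().splitlines()
    meta: dict[str, str] = {}
    grid_start = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" in stripped and "," not in stripped:
            k, _, v = stripped.partition("=")
            meta[k.strip()] = v.strip()
        else:
            grid_start = i
            break
    if grid_start is None:
        raise ReadError(f"{path}: no grid block found")
    for key in ("plate_id", "condition", "replicate_id"):
        if key not in meta:
            raise ReadError(f"{path}: metadata header missing {key!r}")
    grid_lines = [
        ln for ln in lines[grid_start:] if ln.strip() and not ln.startswith("#")
    ]
    if len(grid_lines) != 8:
        raise ReadError(
            f"{path}: expected 8 grid rows, found {len(grid_lines)}"
        )
    values: dict[WellCoord, float] = {}
    for r, line in enumerate(grid_lines):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) == 13:  # optional leading row label
            cells = cells[1:]
        if len(cells) != 12:
            raise ReadError(
                f"{path}: grid row {r + 1} has {len(cells)} columns, "
                "expected 12"
            )
        for c, cell in enumerate(cells):
            try:
                rlu = float(cell)
            except ValueError:
                raise ReadError(
                    f"{path}: non-numeric RLU {cell!r} at row {r + 1} "
                    f"column {c + 1}"
                ) from None
            values[WellCoord("ABCDEFGH"[r], c + 1)] = rlu
    return [
        PlateRead(
            plate_id=meta["plate_id"],
            condition=Condition(meta["condition"]),
            replicate_id=int(meta["replicate_id"]),
            values=values,
        )
    ]


def read_plate_reads(
    path: str | Path, dialect: str = "long_csv"
) -> list[PlateRead]:
    """Parse plate reads from ``long_csv`` or ``grid_csv`` files."""
    path = Path(path)
    if dialect == "long_csv":
        df = pd.read_csv(path, comment="#", dtype=str)
        return _reads_from_long_frame(df, path.name)
    if dialect == "grid_csv":
        return _read_grid_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# --- analysis outputs ------------------------------------------------------

def _header_lines(**params: object) -> str:
    fields = {"nkscreen_version": __version__, **params}
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def write_hits(
    table: HitTable, tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    df = table.to_frame()
    with open(tsv_path, "w") as fh:
        fh.write(_header_lines(threshold=table.threshold, **table.provenance))
        df.to_csv(fh, sep="\t", index=False)
    if json_path is not None:
        doc = {
            "version": __version__,
            "threshold": table.threshold,
            "provenance": dict(table.provenance),
            "calls": [
                {
                    "compound_id": c.compound_id,
                    "coculture_fc": list(c.coculture_fc),
                    "target_alone_fc": list(c.target_alone_fc),
                    "mean_fc": c.mean_fc,
                    "status": c.status.value,
                    "n_replicates": c.n_replicates,
                    "notes": list(c.notes),
                }
                for c in table.calls
            ],
        }
        Path(json_path).write_text(json.dumps(doc, indent=1))


def qc_report_to_json(report: QCReport) -> dict:
    out: dict = {"version": __version__}
    for condition, cqc in report.conditions.items():
        out[condition.value] = {
            "mean_z": cqc.mean_z,
            "undefined_plates": list(cqc.undefined_plates),
            "plates": [
                {
                    "plate_id": r.plate_id,
                    "replicate_id": r.replicate_id,
                    "z": r.z_prime,
                    "class": r.classification.value,
                }
                for r in cqc.results
            ],
        }
    return out


def write_qc_report(
    report: QCReport, json_path: str | Path, tsv_path: str | Path | None = None
) -> None:
    Path(json_path).write_text(json.dumps(qc_report_to_json(report), indent=1))
    if tsv_path is not None:
        rows = [
            {
                "condition": condition.value,
                "plate_id": r.plate_id,
                "replicate_id": r.replicate_id,
                "z_prime": r.z_prime,
                "classification": r.classification.value,
            }
            for condition, cqc in report.conditions.items()
            for r in cqc.results
        ]
        with open(tsv_path, "w") as fh:
            fh.write(_header_lines())
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_fold_changes(records, path: str | Path, **params: object) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "condition": r.condition.value,
            "replicate_id": r.replicate_id,
            "fc": repr(r.fc),
        }
        for r in records
    ]
    with open(path, "w") as fh:
        fh.write(_header_lines(**params))
        pd.DataFrame(
            rows, columns=["compound_id", "condition", "replicate_id", "fc"]
        ).to_csv(fh, sep="\t", index=False)


def read_fold_changes(path: str | Path):
    from .hits import FoldChangeRecord

    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        FoldChangeRecord(
            compound_id=str(r.compound_id),
            condition=Condition(str(r.condition)),
            replicate_id=int(r.replicate_id),
            fc=float(r.fc),
        )
        for r in df.itertuples(index=False)
    ]
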