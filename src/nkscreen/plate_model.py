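"""96-well plate geometry, well roles, and screen layout.

The screen uses standard 8x12 (rows A-H, columns 1-12) assay plates.
Compounds occupy columns 2-11 (80 wells per plate); column 1 holds the
vehicle (DMSO) negative controls and column 12 the positive controls
(digitonin full-lysis wells on target-alone plates, a high effector:target
ratio on co-culture plates).  Every stock plate is assayed under two
conditions -- targets alone (the toxicity counter-screen) and an
effector:target co-culture -- with the same compound occupying the same
position in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

ROWS: str = "ABCDEFGH"
COLUMNS: tuple[int, ...] = tuple(range(1, 13))
COMPOUND_COLUMNS: tuple[int, ...] = tuple(range(2, 12))
NEGATIVE_CONTROL_COLUMN: int = 1
POSITIVE_CONTROL_COLUMN: int = 12
WELLS_PER_PLATE: int = 96
COMPOUND_WELLS_PER_PLATE: int = 80
CONTROL_WELLS_PER_PLATE: int = 16


class Condition(str, Enum):
    """Assay condition of a plate."""

    TARGET_ALONE = "target_alone"
    COCULTURE = "coculture"


class Role(str, Enum):
    """What a well holds."""

    COMPOUND = "compound"
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"
    EMPTY = "empty"


class LayoutError(ValueError):
    """A plate or screen layout violates the screen's geometry rules."""


class ReadError(ValueError):
    """A plate read is inconsistent with its layout."""


@dataclass(frozen=True, order=True)
class WellCoord:
    """A well position: row letter A-H, 1-based column 1-12.

    Ordering is row-major (A1 < A2 < ... < B1 ...), matching the
    dispensing order of a liquid handler sweeping the plate by rows.
    """

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise LayoutError(f"invalid row {self.row!r}: must be one of {ROWS}")
        if self.column not in COLUMNS:
            raise LayoutError(f"invalid column {self.column}: must be 1-12")

    def __str__(self) -> str:
        return f"{self.row}{self.column}"

    @classmethod
    def parse(cls, text: str) -> "WellCoord":
        """Parse ``"A1"`` .. ``"H12"`` (case-insensitive)."""
        text = text.strip().upper()
        if len(text) < 2:
            raise LayoutError(f"cannot parse well coordinate {text!r}")
        try:
            column = int(text[1:])
        except ValueError as exc:
            raise LayoutError(f"cannot parse well coordinate {text!r}") from exc
        return cls(row=text[0], column=column)


def iter_wells() -> Iterator[WellCoord]:
    """All 96 wells in row-major order (A1..A12, B1..B12, ..., H12)."""
    for row in ROWS:
        for column in COLUMNS:
            yield WellCoord(row, column)


@dataclass(frozen=True)
class WellRole:
    """Role of a well; ``compound_id`` is set exactly for compound wells."""

    role: Role
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if self.role is Role.COMPOUND and not self.compound_id:
            raise LayoutError("compound well must carry a compound_id")
        if self.role is not Role.COMPOUND and self.compound_id is not None:
            raise LayoutError(
                f"{self.role.value} well must not carry a compound_id"
            )


@dataclass(frozen=True)
class PlateLayout:
    """Role map of one 96-well plate under one condition."""

    plate_id: str
    condition: Condition
    roles: Mapping[WellCoord, WellRole]

    def __post_init__(self) -> None:
        if len(self.roles) != WELLS_PER_PLATE:
            raise LayoutError(
                f"plate {self.plate_id}: expected {WELLS_PER_PLATE} wells, "
                f"got {len(self.roles)}"
            )
        seen: set[str] = set()
        for well, wr in self.roles.items():
            if well.column == NEGATIVE_CONTROL_COLUMN:
                if wr.role is not Role.NEGATIVE_CONTROL:
                    raise LayoutError(
                        f"plate {self.plate_id} well {well}: column 1 must be "
                        f"negative_control, got {wr.role.value}"
                    )
            elif well.column == POSITIVE_CONTROL_COLUMN:
                if wr.role is not Role.POSITIVE_CONTROL:
                    raise LayoutError(
                        f"plate {self.plate_id} well {well}: column 12 must be "
                        f"positive_control, got {wr.role.value}"
                    )
            elif wr.role not in (Role.COMPOUND, Role.EMPTY):
                raise LayoutError(
                    f"plate {self.plate_id} well {well}: columns 2-11 must be "
                    f"compound or empty, got {wr.role.value}"
                )
            if wr.role is Role.COMPOUND:
                assert wr.compound_id is not None
                if wr.compound_id in seen:
                    raise LayoutError(
                        f"plate {self.plate_id}: compound {wr.compound_id!r} "
                        "appears twice"
                    )
                seen.add(wr.compound_id)

    def compound_wells(self) -> list[tuple[WellCoord, str]]:
        """(well, compound_id) pairs in row-major well order."""
        out = [
            (w, wr.compound_id)
            for w, wr in self.roles.items()
            if wr.role is Role.COMPOUND
        ]
        out.sort(key=lambda pair: pair[0])
        return [(w, cid) for w, cid in out if cid is not None]

    def wells_with_role(self, role: Role) -> list[WellCoord]:
        return sorted(w for w, wr in self.roles.items() if wr.role is role)


@dataclass(frozen=True)
class ScreenLayout:
    """All plates of the screen, per condition, plus the compound index.

    Both conditions share a single compound -> (plate, well) map: each
    compound sits at the same position on the paired target-alone and
    co-culture plates.
    """

    plates: Mapping[Condition, tuple[PlateLayout, ...]]
    compound_index: Mapping[str, tuple[str, WellCoord]]

    @property
    def n_compounds(self) -> int:
        return len(self.compound_index)

    @property
    def plate_ids(self) -> tuple[str, ...]:
        return tuple(p.plate_id for p in self.plates[Condition.TARGET_ALONE])

    def plate(self, plate_id: str, condition: Condition) -> PlateLayout:
        for p in self.plates[condition]:
            if p.plate_id == plate_id:
                return p
        raise LayoutError(f"unknown plate {plate_id!r} for {condition.value}")


@dataclass(frozen=True)
class PlateRead:
    """Raw luminescence (RLU) values for one plate / condition / day."""

    plate_id: str
    condition: Condition
    replicate_id: int
    values: Mapping[WellCoord, float]


@dataclass(frozen=True)
class ValidationReport:
    """Findings from checking a plate read against its layout."""

    plate_id: str
    findings: tuple[str, ...] = field(default=())

    @property
    def passed(self) -> bool:
        return not self.findings


def build_screen_layout(compound_ids: Sequence[str]) -> ScreenLayout:
    """Lay out a screen for the given compounds.

    Compounds fill columns 2-11 row-major (A2..A11, B2..B11, ...) within
    each plate, plates in manifest order; a partially filled final plate
    leaves its remaining compound positions empty.  Column 1 is the DMSO
    negative control and column 12 the positive control on every plate.
    The layout is deterministic in the manifest order.
    """
    if len(compound_ids) == 0:
        raise LayoutError("compound manifest is empty")
    if len(set(compound_ids)) != len(compound_ids):
        dupes = sorted(
            {c for c in compound_ids if list(compound_ids).count(c) > 1}
        )
        raise LayoutError(f"duplicate compound ids in manifest: {dupes}")

    n_plates = math.ceil(len(compound_ids) / COMPOUND_WELLS_PER_PLATE)
    compound_positions = [
        WellCoord(row, col) for row in ROWS for col in COMPOUND_COLUMNS
    ]

    plates: dict[Condition, list[PlateLayout]] = {c: [] for c in Condition}
    index: dict[str, tuple[str, WellCoord]] = {}
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        batch = compound_ids[
            p * COMPOUND_WELLS_PER_PLATE : (p + 1) * COMPOUND_WELLS_PER_PLATE
        ]
        roles: dict[WellCoord, WellRole] = {}
        for well in iter_wells():
            if well.column == NEGATIVE_CONTROL_COLUMN:
                roles[well] = WellRole(Role.NEGATIVE_CONTROL)
            elif well.column == POSITIVE_CONTROL_COLUMN:
                roles[well] = WellRole(Role.POSITIVE_CONTROL)
            else:
                roles[well] = WellRole(Role.EMPTY)
        for well, cid in zip(compound_positions, batch):
            roles[well] = WellRole(Role.COMPOUND, compound_id=cid)
            index[cid] = (plate_id, well)
        for condition in Condition:
            plates[condition].append(
                PlateLayout(plate_id=plate_id, condition=condition, roles=roles)
            )

    return ScreenLayout(
        plates={c: tuple(ps) for c, ps in plates.items()},
        compound_index=index,
    )


def validate_read(read: PlateRead, layout: PlateLayout) -> ValidationReport:
    """Check a plate read against its layout; passes iff no findings."""
    if read.plate_id != layout.plate_id:
        raise ReadError(
            f"read plate {read.plate_id!r} does not match layout plate "
            f"{layout.plate_id!r}"
        )
    if read.condition is not layout.condition:
        raise ReadError(
            f"read condition {read.condition.value!r} does not match layout "
            f"condition {layout.condition.value!r}"
        )
    findings: list[str] = []
    for well in iter_wells():
        wr = layout.roles[well]
        if well not in read.values:
            if wr.role is not Role.EMPTY:
                findings.append(f"missing {wr.role.value} well {well}")
            continue
        rlu = read.values[well]
        if wr.role is Role.EMPTY:
            findings.append(f"value for empty well {well}")
        if rlu < 0:
            findings.append(f"negative luminescence at {well}")
    return ValidationReport(plate_id=read.plate_id, findings=tuple(findings))


def control_values(
    read: PlateRead, layout: PlateLayout, role: Role
) -> list[float]:
    """The 8 control-column RLUs of the requested role, in row order."""
    if role not in (Role.NEGATIVE_CONTROL, Role.POSITIVE_CONTROL):
        raise ValueError(
            "control_values accepts negative_control or positive_control; "
            "use PlateLayout.compound_wells for compound wells"
        )
    wells = layout.wells_with_role(role)
    missing = [str(w) for w in wells if w not in read.values]
    if missing:
        raise ReadError(
            f"plate {read.plate_id}: missing {role.value} wells {missing}"
        )
    return [read.values[w] for w in wells]
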