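import pytest

import nkscreen as nk
from nkscreen import Condition, PlateRead, WellCoord, iter_wells


@pytest.fixture(scope="session")
def small_layout() -> nk.ScreenLayout:
    """Single-plate screen: 80 compounds, columns 2-11 full."""
    return nk.build_screen_layout([f"C{i:04d}" for i in range(1, 81)])


def make_flat_read(
    layout: nk.ScreenLayout,
    condition: Condition = Condition.COCULTURE,
    *,
    plate_id: str = "P01",
    replicate_id: int = 1,
    compound_rlu: float = 200.0,
    negative_rlu: float = 200.0,
    positive_rlu: float = 1000.0,
) -> PlateRead:
    """A read with constant RLU per role (empty wells omitted)."""
    plate = layout.plate(plate_id, condition)
    values: dict[WellCoord, float] = {}
    for well in iter_wells():
        role = plate.roles[well].role
        if role is nk.Role.COMPOUND:
            values[well] = compound_rlu
        elif role is nk.Role.NEGATIVE_CONTROL:
            values[well] = negative_rlu
        elif role is nk.Role.POSITIVE_CONTROL:
            values[well] = positive_rlu
    return PlateRead(
        plate_id=plate_id,
        condition=condition,
        replicate_id=replicate_id,
        values=values,
    )
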