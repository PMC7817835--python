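import numpy as np
import pandas as pd
import pytest

from odacurate import AxisSet, FilamentAxis, LatticeSpec, ParticleTable


@pytest.fixture
def lattice() -> LatticeSpec:
    return LatticeSpec()  # 82 Å step, 3 registers, 246 Å repeat


def straight_axis(
    length_ang: float,
    micrograph_id: str = "mic_0",
    filament_id: int = 1,
    pixel_size_ang: float = 1.0,
) -> FilamentAxis:
    """Axis along +x from the origin; s equals the x coordinate in Å."""
    return FilamentAxis(
        micrograph_id=micrograph_id,
        filament_id=filament_id,
        support_ang=np.array([[0.0, 0.0], [length_ang, 0.0]]),
        pixel_size_ang=pixel_size_ang,
    )


def make_table(rows: list[dict]) -> ParticleTable:
    """ParticleTable from partial row dicts (schema defaults filled)."""
    if not rows:
        return ParticleTable.empty()
    return ParticleTable(pd.DataFrame(rows))


def table_on_axis(
    axis: FilamentAxis,
    s_values,
    register_class: int = 0,
    provenance: str = "picked",
) -> ParticleTable:
    """Particles on an axis at given arc coordinates (x/y consistent)."""
    s = np.asarray(s_values, dtype=float)
    xy = axis.point_at(s) / axis.pixel_size_ang
    return ParticleTable(
        pd.DataFrame(
            {
                "micrograph_id": axis.micrograph_id,
                "x_px": xy[:, 0],
                "y_px": xy[:, 1],
                "filament_id": axis.filament_id,
                "s_ang": s,
                "register_class": register_class,
                "provenance": provenance,
                "record_index": np.arange(len(s)),
            }
        )
    )


@pytest.fixture
def axis_1k() -> FilamentAxis:
    return straight_axis(1000.0)


@pytest.fixture
def axes_1k(axis_1k) -> AxisSet:
    return AxisSet([axis_1k])
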