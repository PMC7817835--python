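"""Filament axes: arc-length parameterization and 8-nm segmentation.

A picked filament is modelled as a planar polyline axis in Å (a straight
chord when only start/end coordinates were picked).  The axis carries an
exact arc-length parameterization s -> (x, y) used to place box centers
every ``step_ang`` (the tubulin-dimer length, 82 Å), to shift particles
between lattice registers, and to map externally supplied coordinates
onto the filament.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coords_io import (
    PROVENANCE_PICKED,
    REGISTER_UNKNOWN,
    FilamentPick,
    MicrographMeta,
    ParticleTable,
)
from .lattice import LatticeSpec

__all__ = ["FilamentAxis", "build_axis", "segment_axis", "arc_coordinate", "AxisSet"]


class LateralGateError(ValueError):
    """A point lies farther from the axis than the lateral gate allows."""

    def __init__(self, distance_ang: float, gate_ang: float):
        self.distance_ang = distance_ang
        self.gate_ang = gate_ang
        super().__init__(
            f"point is {distance_ang:.1f} Å from the axis "
            f"(lateral gate {gate_ang:.1f} Å)"
        )


@dataclass(frozen=True, eq=False)
class FilamentAxis:
    """A filament axis as a polyline in Å with arc-length parameterization.

    ``support_ang`` is an (n, 2) array of support points; consecutive
    duplicates are not allowed.  ``point_at`` and ``arc_of`` are exact
    (piecewise-linear) inverses of each other on [0, L].
    """

    micrograph_id: str
    filament_id: int
    support_ang: np.ndarray
    pixel_size_ang: float = 1.36

    def __post_init__(self) -> None:
        pts = np.asarray(self.support_ang, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("support_ang must be an (n>=2, 2) array")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("axis has zero-length segments")
        object.__setattr__(self, "support_ang", pts)
        object.__setattr__(self, "_seg_len", seg)
        object.__setattr__(
            self, "_cum_s", np.concatenate(([0.0], np.cumsum(seg)))
        )

    @property
    def total_length_ang(self) -> float:
        return float(self._cum_s[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Point(s) on the axis at arc length ``s`` (Å).  Continuous and
        monotone; values outside [0, L] are clamped."""
        s = np.clip(np.asarray(s, dtype=np.float64), 0.0, self.total_length_ang)
        x = np.interp(s, self._cum_s, self.support_ang[:, 0])
        y = np.interp(s, self._cum_s, self.support_ang[:, 1])
        return np.stack([x, y], axis=-1)

    def arc_of(self, point: np.ndarray) -> tuple[float, float]:
        """Arc length of the nearest axis point and the lateral distance.

        Ties (equidistant segments) break toward smaller s.
        """
        p = np.asarray(point, dtype=np.float64)
        a = self.support_ang[:-1]
        b = self.support_ang[1:]
        ab = b - a
        t = np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab)
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1)
        # strict argmin ties toward the earliest (smaller-s) segment
        i = int(np.argmin(d))
        s = float(self._cum_s[i] + t[i] * self._seg_len[i])
        return s, float(d[i])


def build_axis(
    pick: FilamentPick,
    meta: MicrographMeta,
    mode: str = "chord",
    support: np.ndarray | None = None,
) -> FilamentAxis:
    """Construct an axis from a filament pick.

    ``chord`` mode (the default, matching two-point manual picks) uses the
    start/end coordinates only; ``polyline`` mode takes >= 2 support
    points in pixels for curved (splayed) filaments.
    """
    scale = meta.pixel_size_ang
    if mode == "chord":
        pts = np.array([pick.start_px, pick.end_px], dtype=np.float64) * scale
    elif mode == "polyline":
        if support is None or len(support) < 2:
            raise ValueError("polyline mode requires >= 2 support points")
        pts = np.asarray(support, dtype=np.float64) * scale
    else:
        raise ValueError(f"unknown axis mode: {mode!r}")
    return FilamentAxis(
        micrograph_id=pick.micrograph_id,
        filament_id=pick.filament_id,
        support_ang=pts,
        pixel_size_ang=scale,
    )


def segment_axis(axis: FilamentAxis, lattice: LatticeSpec) -> ParticleTable:
    """Divide an axis into 8-nm particles.

    Box centers are placed at s_i = i * step for i = 0 .. floor(L/step);
    segmentation starts at the picked start point and includes the far
    endpoint when L is an exact multiple of the step.  A short axis
    yields a single center at s = 0.
    """
    step = lattice.step_ang
    n = int(np.floor(axis.total_length_ang / step + 1e-9)) + 1
    s = np.arange(n, dtype=np.float64) * step
    xy = axis.point_at(s) / axis.pixel_size_ang
    return ParticleTable(
        pd.DataFrame(
            {
                "micrograph_id": axis.micrograph_id,
                "x_px": xy[:, 0],
                "y_px": xy[:, 1],
                "filament_id": axis.filament_id,
                "s_ang": s,
                "register_class": REGISTER_UNKNOWN,
                "provenance": PROVENANCE_PICKED,
                "record_index": np.arange(n, dtype=np.int64),
            }
        )
    )


def arc_coordinate(
    axis: FilamentAxis,
    point_ang: np.ndarray,
    max_lateral_ang: float | None = None,
) -> float:
    """Arc-length coordinate of a point (Å) on the axis.

    ``max_lateral_ang`` gates how far off-axis the point may lie; the
    default is one box half-width (256 px at the axis pixel size) — a
    particle farther than its own box from the axis cannot belong to the
    filament.  Beyond the gate a :class:`LateralGateError` reports the
    offending distance.
    """
    if max_lateral_ang is None:
        max_lateral_ang = 256.0 * axis.pixel_size_ang
    s, d = axis.arc_of(point_ang)
    if d > max_lateral_ang:
        raise LateralGateError(d, max_lateral_ang)
    return s


class AxisSet:
    """Lookup of filament axes by (micrograph_id, filament_id)."""

    def __init__(self, axes: list[FilamentAxis] | None = None):
        self._axes: dict[tuple[str, int], FilamentAxis] = {}
        for ax in axes or []:
            self.add(ax)

    def add(self, axis: FilamentAxis) -> None:
        key = (axis.micrograph_id, axis.filament_id)
        if key in self._axes:
            raise ValueError(f"duplicate axis for {key}")
        self._axes[key] = axis

    def get(self, micrograph_id: str, filament_id: int) -> FilamentAxis:
        try:
            return self._axes[(micrograph_id, int(filament_id))]
        except KeyError:
            raise KeyError(
                f"no axis for filament {filament_id} on "
                f"micrograph {micrograph_id!r}"
            ) from None

    def __iter__(self):
        return iter(self._axes.values())

    def __len__(self) -> int:
        return len(self._axes)
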