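"""Register unification, lattice snapping and duplicate elimination.

3-D classification of 8-nm particles on a 24-nm-decorated filament
yields one class per register: the dynein arm sits centered in one class
and off-center by ±1 binding site in the other two.  Curation shifts
every particle along its own filament axis by the minimum whole number
of 8-nm steps that brings it into the reference register, re-snaps
positions onto exact lattice sites, and removes records that end up
representing the same binding site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords_io import PROVENANCE_PICKED, ParticleTable
from .geometry import AxisSet
from .lattice import LatticeSpec

__all__ = [
    "NON_PARTICLE",
    "RegisterMap",
    "DedupPolicy",
    "UnifyStats",
    "SnapStats",
    "DedupStats",
    "unify_registers",
    "snap_to_lattice",
    "deduplicate",
]

#: Map target for a class that does not contain particles (junk class).
NON_PARTICLE = "non-particle"


@dataclass(frozen=True)
class RegisterMap:
    """Maps external class labels to lattice phases.

    ``class_to_phase`` sends each class label to a phase index in
    {0, ..., r-1} or to :data:`NON_PARTICLE`; ``reference_phase`` is the
    phase every particle is shifted onto.  Which class served as the
    reference register is a free choice; the default phase is 0.
    """

    class_to_phase: dict[int, int | str]
    reference_phase: int = 0

    def __post_init__(self) -> None:
        phases = [v for v in self.class_to_phase.values() if v != NON_PARTICLE]
        if len(set(phases)) != len(phases):
            raise ValueError("phases assigned to classes must be distinct")
        if phases and self.reference_phase not in phases:
            raise ValueError(
                f"reference_phase {self.reference_phase} is not among the "
                f"assigned phases {sorted(phases)}"
            )

    @classmethod
    def identity(cls, r: int = 3, reference_phase: int = 0) -> "RegisterMap":
        """Class label k -> phase k for k in 0..r-1."""
        return cls({k: k for k in range(r)}, reference_phase)


@dataclass(frozen=True)
class DedupPolicy:
    """How close two records may be before one is a duplicate.

    ``d_min_ang`` defaults to half a lattice step (41 Å): same-site
    duplicates merge, adjacent sites never do.  Scope ``same_filament``
    treats crossing filaments as independent (they hold distinct
    complexes even when their boxes overlap in the image);
    ``same_micrograph`` compares all records on a micrograph.  Priority:
    picked records survive over expanded ones, then lower record_index.
    """

    d_min_ang: float = 41.0
    scope: str = "same_filament"

    def __post_init__(self) -> None:
        if self.d_min_ang <= 0:
            raise ValueError(f"d_min_ang must be positive, got {self.d_min_ang}")
        if self.scope not in ("same_filament", "same_micrograph"):
            raise ValueError(f"unknown dedup scope: {self.scope!r}")


@dataclass
class UnifyStats:
    shifted_per_delta: dict[int, int] = field(default_factory=dict)
    dropped_non_particle: int = 0
    dropped_clipped: int = 0


@dataclass
class SnapStats:
    n_flagged: int = 0
    max_displacement_ang: float = 0.0


@dataclass
class DedupStats:
    n_removed: int = 0


def _min_phase_shift(k: int, reference: int, r: int) -> int:
    """Minimum-magnitude integer D with (k + D) congruent to reference mod r.

    Unique for odd r; for even r the tie breaks toward the negative shift.
    """
    d = (reference - k) % r
    return d if d < r - d else d - r


def unify_registers(
    table: ParticleTable,
    axes: AxisSet,
    regmap: RegisterMap,
    lattice: LatticeSpec,
) -> tuple[ParticleTable, UnifyStats]:
    """Shift each particle onto the reference register along its axis.

    A particle of phase k moves by D * step where D is the
    minimum-magnitude phase correction; for three registers D is one of
    {-1, 0, +1} (the "shifted 8 nm" move).  Records mapped to
    :data:`NON_PARTICLE` are dropped and counted, as are records whose
    shifted arc coordinate falls off the filament.
    """
    df = table.df
    stats = UnifyStats()
    if len(df) == 0:
        return table.copy(), stats
    if df["s_ang"].isna().any():
        raise ValueError("unify_registers requires s_ang on every record")
    unmapped = sorted(
        int(c)
        for c in set(df["register_class"].unique()) - set(regmap.class_to_phase)
    )
    if unmapped:
        raise ValueError(f"register classes not covered by the map: {unmapped}")

    r = lattice.repeat_multiplier
    step = lattice.step_ang
    ref = regmap.reference_phase
    ref_class = next(
        (c for c, p in regmap.class_to_phase.items() if p == ref), None
    )

    mask = np.zeros(len(df), dtype=bool)
    new_s = []
    for pos, row in enumerate(df.itertuples(index=False)):
        phase = regmap.class_to_phase[row.register_class]
        if phase == NON_PARTICLE:
            stats.dropped_non_particle += 1
            continue
        delta = _min_phase_shift(int(phase), ref, r)
        s = row.s_ang + delta * step
        axis = axes.get(row.micrograph_id, row.filament_id)
        if s < -1e-9 or s > axis.total_length_ang + 1e-9:
            stats.dropped_clipped += 1
            continue
        stats.shifted_per_delta[delta] = stats.shifted_per_delta.get(delta, 0) + 1
        mask[pos] = True
        new_s.append(s)

    out = df[mask].reset_index(drop=True).copy()
    out["s_ang"] = np.asarray(new_s, dtype=np.float64)
    _recompute_xy(out, axes)
    if ref_class is not None:
        out["register_class"] = int(ref_class)
    return ParticleTable(out), stats


def _recompute_xy(df, axes: AxisSet) -> None:
    """Refresh x/y pixel coordinates from each record's arc coordinate."""
    for (mic, fid), sub in df.groupby(["micrograph_id", "filament_id"], sort=False):
        axis = axes.get(mic, fid)
        xy = axis.point_at(sub["s_ang"].to_numpy()) / axis.pixel_size_ang
        df.loc[sub.index, "x_px"] = xy[:, 0]
        df.loc[sub.index, "y_px"] = xy[:, 1]


def snap_to_lattice(
    table: ParticleTable,
    axes: AxisSet,
    lattice: LatticeSpec,
    tol_ang: float | None = None,
) -> tuple[ParticleTable, SnapStats]:
    """Replace each arc coordinate by the nearest integer multiple of the
    step (enforcing the 8-nm register); ties break toward smaller s.

    Records displaced by more than ``tol_ang`` are flagged in a boolean
    ``snap_flagged`` column, not dropped.
    """
    df = table.df.copy()
    stats = SnapStats()
    if len(df) == 0:
        return ParticleTable(df), stats
    if df["s_ang"].isna().any():
        raise ValueError("snap_to_lattice requires s_ang on every record")
    step = lattice.step_ang
    s = df["s_ang"].to_numpy()
    # nearest multiple with half-integer ties rounding down
    idx = np.ceil(s / step - 0.5).astype(np.int64)
    idx = np.maximum(idx, 0)
    # clamp to the last site that exists on each record's axis
    for (mic, fid), sub in df.groupby(["micrograph_id", "filament_id"], sort=False):
        axis = axes.get(mic, fid)
        max_idx = int(np.floor(axis.total_length_ang / step + 1e-9))
        pos = df.index.get_indexer(sub.index)
        idx[pos] = np.minimum(idx[pos], max_idx)
    snapped = idx.astype(np.float64) * step
    disp = np.abs(snapped - s)
    stats.max_displacement_ang = float(disp.max(initial=0.0))
    if tol_ang is not None:
        flagged = disp > tol_ang
        df["snap_flagged"] = flagged
        stats.n_flagged = int(flagged.sum())
    df["s_ang"] = snapped
    _recompute_xy(df, axes)
    return ParticleTable(df), stats


def deduplicate(
    table: ParticleTable,
    axes: AxisSet,
    policy: DedupPolicy = DedupPolicy(),
) -> tuple[ParticleTable, DedupStats]:
    """Greedy duplicate elimination.

    Records are swept in priority order (picked before expanded, then
    lower record_index); a record is kept iff its micrograph-plane
    distance to every already-kept record within scope is at least
    ``d_min_ang``.  Output preserves the original row order of the kept
    records.  Idempotent by construction.
    """
    df = table.df
    stats = DedupStats()
    if len(df) == 0:
        return table.copy(), stats

    prio = np.lexsort(
        (
            df["record_index"].to_numpy(),
            (df["provenance"] != PROVENANCE_PICKED).to_numpy(),
        )
    )
    if policy.scope == "same_filament":
        scope_keys = list(
            zip(df["micrograph_id"].to_numpy(), df["filament_id"].to_numpy())
        )
    else:
        scope_keys = list(df["micrograph_id"].to_numpy())

    x = df["x_px"].to_numpy()
    y = df["y_px"].to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    kept_by_scope: dict[object, list[int]] = {}
    for pos in prio:
        key = scope_keys[pos]
        mic = df["micrograph_id"].iloc[pos]
        fid = int(df["filament_id"].iloc[pos])
        px = _pixel_size_for(axes, mic, fid)
        others = kept_by_scope.get(key, [])
        if others:
            d = (
                np.hypot(x[others] - x[pos], y[others] - y[pos]) * px
            )
            if (d < policy.d_min_ang).any():
                stats.n_removed += 1
                continue
        keep[pos] = True
        kept_by_scope.setdefault(key, []).append(pos)

    out = df[keep].reset_index(drop=True)
    return ParticleTable(out), stats


def _pixel_size_for(axes: AxisSet, micrograph_id: str, filament_id: int) -> float:
    try:
        return axes.get(micrograph_id, filament_id).pixel_size_ang
    except KeyError:
        for ax in axes:
            if ax.micrograph_id == micrograph_id:
                return ax.pixel_size_ang
        return 1.36
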