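"""Neighbor-particle recovery along the filament axis.

Classification finds only part of the dynein arms actually bound to a
filament, but bound arms sit in clusters with one arm per 24-nm repeat.
Starting from validated seed particles, candidates are therefore
proposed at +-1 and +-2 repeats along the seed's own axis, screened by
an injected verifier (standing in for mask-focused classification plus
manual inspection of micrograph positions), merged, snapped and
deduplicated — and the whole cycle repeats until no new particle is
accepted.  With a perfect verifier this recovers exactly the occupied
sites of every cluster that contains at least one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .coords_io import PROVENANCE_EXPANDED, ParticleTable
from .curation import DedupPolicy, deduplicate, snap_to_lattice
from .geometry import AxisSet
from .lattice import LatticeSpec

__all__ = ["Candidate", "ExpansionSpec", "RoundStats", "RecoveryLog", "expand", "iterate_recovery"]


@dataclass(frozen=True)
class Candidate:
    """A proposed particle position handed to the verifier."""

    micrograph_id: str
    filament_id: int
    s_ang: float
    x_px: float
    y_px: float


#: Verifier contract: accept or reject a candidate particle.
Verifier = Callable[[Candidate], bool]


@dataclass(frozen=True)
class ExpansionSpec:
    """How far to look for neighbors and how long to iterate.

    ``multiples`` are the repeat offsets tried from each seed (default
    {1, 2}: +-24 and +-48 nm at the default lattice).  Iteration stops
    when a round accepts nothing new or after ``max_rounds`` rounds.
    """

    multiples: frozenset[int] = frozenset({1, 2})
    max_rounds: int = 10

    def __post_init__(self) -> None:
        ms = frozenset(int(m) for m in self.multiples)
        if not ms or any(m < 1 for m in ms):
            raise ValueError("multiples must be a non-empty set of integers >= 1")
        object.__setattr__(self, "multiples", ms)
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class RoundStats:
    proposed: int = 0
    accepted: int = 0
    new_records: int = 0
    duplicates_removed: int = 0


@dataclass
class RecoveryLog:
    rounds: list[RoundStats] = field(default_factory=list)
    converged: bool = False


def expand(
    seeds: ParticleTable,
    axes: AxisSet,
    lattice: LatticeSpec,
    spec: ExpansionSpec = ExpansionSpec(),
) -> ParticleTable:
    """Propose candidates at s +- m * repeat from every seed.

    Candidates falling outside [0, L] of their axis are clipped away;
    duplicates among candidates are NOT yet removed.  Candidate count
    before clipping is exactly |seeds| * 2 * |multiples|.
    """
    df = seeds.df
    if len(df) and df["s_ang"].isna().any():
        raise ValueError("expand requires s_ang on every seed")
    repeat = lattice.repeat_ang
    next_index = int(df["record_index"].max()) + 1 if len(df) else 0

    rows: list[dict] = []
    for row in df.itertuples(index=False):
        axis = axes.get(row.micrograph_id, row.filament_id)
        length = axis.total_length_ang
        for m in sorted(spec.multiples):
            for sign in (-1, 1):
                s = row.s_ang + sign * m * repeat
                if s < -1e-9 or s > length + 1e-9:
                    continue
                xy = axis.point_at(s) / axis.pixel_size_ang
                rows.append(
                    {
                        "micrograph_id": row.micrograph_id,
                        "x_px": float(xy[0]),
                        "y_px": float(xy[1]),
                        "filament_id": row.filament_id,
                        "s_ang": float(np.clip(s, 0.0, length)),
                        "register_class": row.register_class,
                        "provenance": PROVENANCE_EXPANDED,
                        "record_index": next_index,
                    }
                )
                next_index += 1
    if not rows:
        return ParticleTable.empty()
    return ParticleTable(pd.DataFrame(rows))


def _apply_verifier(candidates: ParticleTable, verifier: Verifier) -> ParticleTable:
    df = candidates.df
    if len(df) == 0:
        return candidates
    keep = [
        bool(
            verifier(
                Candidate(
                    micrograph_id=row.micrograph_id,
                    filament_id=int(row.filament_id),
                    s_ang=float(row.s_ang),
                    x_px=float(row.x_px),
                    y_px=float(row.y_px),
                )
            )
        )
        for row in df.itertuples(index=False)
    ]
    return ParticleTable(df[np.asarray(keep, dtype=bool)].reset_index(drop=True))


def iterate_recovery(
    seeds: ParticleTable,
    axes: AxisSet,
    lattice: LatticeSpec,
    spec: ExpansionSpec,
    verifier: Verifier,
    policy: DedupPolicy = DedupPolicy(),
) -> tuple[ParticleTable, RecoveryLog]:
    """Expand, verify, merge, snap and deduplicate until fixed point.

    The curated set grows monotonically: seeds and previously accepted
    records always win the dedup priority over newer candidates at the
    same site.  Non-convergence within ``max_rounds`` is reported in the
    log, not an error.
    """
    log = RecoveryLog()
    current = seeds.copy()
    if len(current) == 0:
        log.converged = True
        return current, log

    for _ in range(spec.max_rounds):
        stats = RoundStats()
        candidates = expand(current, axes, lattice, spec)
        stats.proposed = len(candidates)
        accepted = _apply_verifier(candidates, verifier)
        stats.accepted = len(accepted)
        n_before = len(current)
        merged = ParticleTable(
            pd.concat([current.df, accepted.df], ignore_index=True)
        )
        merged, _snap = snap_to_lattice(merged, axes, lattice)
        merged, dd = deduplicate(merged, axes, policy)
        stats.duplicates_removed = dd.n_removed
        stats.new_records = len(merged) - n_before
        log.rounds.append(stats)
        current = merged
        if stats.new_records == 0:
            log.converged = True
            break
    return current, log
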