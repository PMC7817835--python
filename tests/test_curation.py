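"""Register unification, lattice snapping and duplicate elimination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from odacurate import (
    AxisSet,
    DedupPolicy,
    LatticeSpec,
    ParticleTable,
    RegisterMap,
    deduplicate,
    snap_to_lattice,
    unify_registers,
)
from odacurate.curation import NON_PARTICLE, _min_phase_shift

from conftest import straight_axis, table_on_axis


def brute_force_dedup(df: pd.DataFrame, d_min: float, pixel_size: float = 1.0):
    """Independent O(n^2) greedy sweep; returns kept record_index set."""
    order = sorted(
        range(len(df)),
        key=lambda i: (
            df["provenance"].iloc[i] != "picked",
            df["record_index"].iloc[i],
        ),
    )
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if (
                df["micrograph_id"].iloc[i] == df["micrograph_id"].iloc[j]
                and df["filament_id"].iloc[i] == df["filament_id"].iloc[j]
            ):
                d = pixel_size * np.hypot(
                    df["x_px"].iloc[i] - df["x_px"].iloc[j],
                    df["y_px"].iloc[i] - df["y_px"].iloc[j],
                )
                if d < d_min:
                    ok = False
                    break
        if ok:
            kept.append(i)
    return {int(df["record_index"].iloc[i]) for i in kept}


# ---- unify_registers ------------------------------------------------------

def test_reference_phase_record_unchanged(lattice, axis_1k, axes_1k):
    table = table_on_axis(axis_1k, [246.0], register_class=0)
    out, stats = unify_registers(table, axes_1k, RegisterMap.identity(3), lattice)
    assert out.df["s_ang"].tolist() == [246.0]
    assert stats.shifted_per_delta == {0: 1}


@pytest.mark.parametrize(
    "phase,s_in,s_out,delta",
    [(1, 246.0, 164.0, -1), (2, 164.0, 246.0, 1), (0, 82.0, 82.0, 0)],
)
def test_phase_shift_moves_to_reference(phase, s_in, s_out, delta, lattice, axis_1k, axes_1k):
    table = table_on_axis(axis_1k, [s_in], register_class=phase)
    out, stats = unify_registers(table, axes_1k, RegisterMap.identity(3), lattice)
    assert out.df["s_ang"].tolist() == [s_out]
    assert stats.shifted_per_delta == {delta: 1}
    # integer oracle: the applied shift moves the labeled phase onto the
    # reference phase with the minimum number of steps
    assert (phase + delta) % 3 == 0 and abs(delta) <= 1


def test_unify_drops_non_particle_and_clipped(lattice, axis_1k, axes_1k):
    regmap = RegisterMap({0: 0, 1: 1, 2: 2, 9: NON_PARTICLE})
    table = table_on_axis(axis_1k, [0.0, 246.0, 500.0], register_class=2)
    df = table.df.copy()
    df.loc[2, "register_class"] = 9
    # phase-2 record at s = 0 shifts to s = +82 (still on axis); put one
    # at the far end so the +82 shift clips it off
    df.loc[1, "s_ang"] = 990.0
    table = ParticleTable(df)
    out, stats = unify_registers(table, axes_1k, regmap, lattice)
    assert stats.dropped_non_particle == 1
    assert stats.dropped_clipped == 1
    assert len(out) == 1 and out.df["s_ang"].tolist() == [82.0]


def test_unify_unmapped_class_raises(lattice, axis_1k, axes_1k):
    table = table_on_axis(axis_1k, [0.0], register_class=7)
    with pytest.raises(ValueError, match=r"\[7\]"):
        unify_registers(table, axes_1k, RegisterMap.identity(3), lattice)


def test_unify_preserves_identity_columns(lattice, axis_1k, axes_1k):
    table = table_on_axis(axis_1k, [82.0, 164.0, 246.0], register_class=1)
    out, _ = unify_registers(table, axes_1k, RegisterMap.identity(3), lattice)
    assert out.df["micrograph_id"].eq("mic_0").all()
    assert out.df["filament_id"].eq(1).all()


@pytest.mark.parametrize(
    "k,ref,r,expected",
    [(0, 0, 3, 0), (1, 0, 3, -1), (2, 0, 3, 1), (1, 2, 3, 1), (2, 0, 4, -2), (3, 1, 4, -2)],
)
def test_min_phase_shift(k, ref, r, expected):
    """Minimum-|D| correction; even-r ties break toward the negative."""
    assert _min_phase_shift(k, ref, r) == expected
    assert (k + expected) % r == ref % r


# ---- snap_to_lattice ------------------------------------------------------

@pytest.mark.parametrize("s_in,s_out", [(85.0, 82.0), (41.0, 0.0), (123.0, 82.0), (0.0, 0.0)])
def test_snap_nearest_site_with_tie_down(s_in, s_out, lattice, axis_1k, axes_1k):
    table = table_on_axis(axis_1k, [s_in])
    out, _ = snap_to_lattice(table, axes_1k, lattice)
    assert out.df["s_ang"].tolist() == [s_out]


def test_snap_uniform_random_all_on_lattice(lattice):
    axis = straight_axis(8200.0)
    axes = AxisSet([axis])
    rng = np.random.default_rng(7)
    s = rng.uniform(0, 8200.0, 500)
    table = table_on_axis(axis, s)
    out, _ = snap_to_lattice(table, axes, lattice)
    snapped = out.df["s_ang"].to_numpy()
    assert np.all(np.mod(snapped, 82.0) == 0.0)
    assert np.all(np.abs(snapped - s) <= 41.0)


def test_snap_flags_large_displacement(lattice, axis_1k, axes_1k):
    table = table_on_axis(axis_1k, [82.0, 120.0])
    out, stats = snap_to_lattice(table, axes_1k, lattice, tol_ang=10.0)
    assert stats.n_flagged == 1
    assert out.df["snap_flagged"].tolist() == [False, True]


# ---- deduplicate ----------------------------------------------------------

def test_exact_duplicate_keeps_picked(lattice, axis_1k, axes_1k):
    df = table_on_axis(axis_1k, [246.0, 246.0]).df
    df.loc[0, "provenance"] = "expanded"
    out, stats = deduplicate(ParticleTable(df), axes_1k)
    assert stats.n_removed == 1
    assert out.df["provenance"].tolist() == ["picked"]


def test_chain_a_b_c_greedy(axes_1k, axis_1k):
    # spacing 0.6 * d_min: B removed (near A), C kept (>= d_min from A)
    d = 0.6 * 41.0
    table = table_on_axis(axis_1k, [100.0, 100.0 + d, 100.0 + 2 * d])
    out, stats = deduplicate(table, axes_1k, DedupPolicy(d_min_ang=41.0))
    assert out.df["s_ang"].tolist() == [100.0, 100.0 + 2 * d]
    assert stats.n_removed == 1


def test_dedup_empty_table(axes_1k):
    out, stats = deduplicate(ParticleTable.empty(), axes_1k)
    assert len(out) == 0 and stats.n_removed == 0


def test_dedup_scope_same_filament_ignores_crossing(lattice):
    a1 = straight_axis(1000.0, filament_id=1)
    a2 = straight_axis(1000.0, filament_id=2)
    axes = AxisSet([a1, a2])
    df = pd.concat(
        [table_on_axis(a1, [500.0]).df, table_on_axis(a2, [500.0]).df],
        ignore_index=True,
    )
    df["record_index"] = [0, 1]
    table = ParticleTable(df)
    out, _ = deduplicate(table, axes, DedupPolicy(scope="same_filament"))
    assert len(out) == 2
    out, _ = deduplicate(table, axes, DedupPolicy(scope="same_micrograph"))
    assert len(out) == 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(0, 60))
def test_dedup_matches_brute_force_and_is_idempotent(seed, n):
    rng = np.random.default_rng(seed)
    axis = straight_axis(2000.0)
    axes = AxisSet([axis])
    s = rng.uniform(0, 2000.0, n)
    table = table_on_axis(axis, s)
    df = table.df.copy()
    df["provenance"] = rng.choice(["picked", "expanded"], n)
    table = ParticleTable(df)
    out, _ = deduplicate(table, axes, DedupPolicy(d_min_ang=41.0))
    assert set(out.df["record_index"]) == brute_force_dedup(table.df, 41.0)
    # pairwise separation invariant
    kept_s = np.sort(out.df["s_ang"].to_numpy())
    if len(kept_s) > 1:
        assert np.diff(kept_s).min() >= 41.0 - 1e-9
    # idempotence
    out2, stats2 = deduplicate(out, axes, DedupPolicy(d_min_ang=41.0))
    assert stats2.n_removed == 0
    pd.testing.assert_frame_equal(out.df, out2.df)


def test_unify_then_snap_phase_congruence_property(lattice):
    """Surviving records sit on site indices congruent to the reference
    phase, exactly, for any correctly-labeled input."""
    axis = straight_axis(5000.0)
    axes = AxisSet([axis])
    rng = np.random.default_rng(3)
    sites = rng.integers(0, 60, 40)
    phases = sites % 3
    s = sites * 82.0 + rng.normal(0, 5.0, 40)
    df = table_on_axis(axis, np.clip(s, 0, 5000.0)).df
    df["register_class"] = phases
    out, _ = unify_registers(ParticleTable(df), axes, RegisterMap.identity(3), lattice)
    out, _ = snap_to_lattice(out, axes, lattice)
    idx = np.round(out.df["s_ang"].to_numpy() / 82.0).astype(int)
    assert np.all(idx % 3 == 0)
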