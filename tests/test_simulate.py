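"""Synthetic-data generator: determinism, lattice structure, occupancy
calibration and the corruptible truth verifier."""

import numpy as np
import pandas as pd
import pytest

from odacurate import LatticeSpec, SimConfig, corrupt_verifier, simulate
from odacurate.recovery import Candidate
from odacurate.simulate import _occupancy_chain


def run_lengths(occ: np.ndarray) -> list[int]:
    runs, current = [], 0
    for o in occ:
        if o:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def test_noiseless_saturation_exact_lattice():
    cfg = SimConfig(
        n_micrographs=2,
        loc_noise_ang=0.0,
        register_label_error=0.0,
        p_start=1.0,
        p_stay=1.0,
        false_site_rate=0.0,
        rng_seed=1,
    )
    truth, observed, picks, metas = simulate(cfg)
    assert truth.sites["occupied"].all()
    repeat = cfg.lattice.repeat_ang
    step = cfg.lattice.step_ang
    # each observed particle sits exactly one register offset from its site
    for row in observed.df.itertuples():
        site_s = row.true_site_index * repeat
        offset = row.s_ang - site_s
        assert min(abs(offset - d * step) for d in (-1, 0, 1)) < 1e-6
        # and the label matches the offset (no label noise)
        lab_offset = {0: 0.0, 1: step, 2: -step}[row.register_class]
        assert offset == pytest.approx(lab_offset, abs=1e-6)


def test_identical_config_identical_output(tmp_path):
    cfg = SimConfig(n_micrographs=3, rng_seed=9)
    t1, o1, p1, m1 = simulate(cfg)
    t2, o2, p2, m2 = simulate(cfg)
    pd.testing.assert_frame_equal(o1.df, o2.df)
    pd.testing.assert_frame_equal(t1.sites, t2.sites)
    assert p1 == p2
    from odacurate import write_particles

    write_particles(o1, tmp_path / "a.star")
    write_particles(o2, tmp_path / "b.star")
    assert (tmp_path / "a.star").read_bytes() == (tmp_path / "b.star").read_bytes()


def test_different_seed_different_output():
    o1 = simulate(SimConfig(rng_seed=1))[1]
    o2 = simulate(SimConfig(rng_seed=2))[1]
    assert not o1.df.equals(o2.df)


def test_occupancy_chain_mean_run_length_matches_closed_form():
    """Mean occupied-run length is geometric: 1 / (1 - p_stay)."""
    rng = np.random.default_rng(0)
    p_stay = 0.8
    occ = _occupancy_chain(rng, 10_000, p_start=0.3, p_stay=p_stay)
    runs = np.array(run_lengths(occ))
    expected = 1.0 / (1.0 - p_stay)
    se = runs.std(ddof=1) / np.sqrt(len(runs))
    assert abs(runs.mean() - expected) <= 3 * se


def test_register_mislabel_fraction_converges():
    eps = 0.1
    cfg = SimConfig(
        n_micrographs=25,
        filaments_per_micrograph=5,
        field_px=16384,
        filament_length_ang=(18_000.0, 20_000.0),
        p_start=1.0,
        p_stay=1.0,
        loc_noise_ang=0.0,
        register_label_error=eps,
        false_site_rate=0.0,
        rng_seed=4,
    )
    truth, observed, _, _ = simulate(cfg)
    df = observed.df
    assert len(df) >= 5000
    step = cfg.lattice.step_ang
    repeat = cfg.lattice.repeat_ang
    offset = df["s_ang"].to_numpy() - df["true_site_index"].to_numpy() * repeat
    true_class = np.select(
        [np.abs(offset) < step / 2, offset > 0], [0, 1], default=2
    )
    frac = float((df["register_class"].to_numpy() != true_class).mean())
    n = len(df)
    # 99% binomial CI (normal approximation)
    half = 2.576 * np.sqrt(eps * (1 - eps) / n)
    assert abs(frac - eps) <= half


def test_seed_flagging_rate():
    cfg = SimConfig(
        n_micrographs=10,
        p_start=1.0,
        p_stay=1.0,
        seed_detection_rate=0.3,
        false_site_rate=0.0,
        rng_seed=6,
    )
    _, observed, _, _ = simulate(cfg)
    frac = observed.df["is_seed"].astype(bool).mean()
    n = len(observed)
    assert abs(frac - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / n)


def test_truth_sites_on_axis_at_exact_repeats():
    cfg = SimConfig(n_micrographs=2, rng_seed=3)
    truth, _, _, _ = simulate(cfg)
    repeat = cfg.lattice.repeat_ang
    for (mic, fid), sub in truth.sites.groupby(["micrograph_id", "filament_id"]):
        axis = truth.axes.get(mic, fid)
        for row in sub.itertuples():
            assert row.s_ang == row.site_index * repeat
            np.testing.assert_allclose(
                axis.point_at(row.s_ang),
                [row.x_px * cfg.pixel_size_ang, row.y_px * cfg.pixel_size_ang],
            )


def test_degenerate_field_rejected():
    with pytest.raises(ValueError, match="repeat"):
        SimConfig(field_px=64, pixel_size_ang=1.0, step_ang=82.0)


def test_yaml_round_trip(tmp_path):
    cfg = SimConfig(n_micrographs=7, p_stay=0.65, rng_seed=12)
    cfg.to_yaml(tmp_path / "sim.yaml")
    assert SimConfig.from_yaml(tmp_path / "sim.yaml") == cfg


# ---- corrupt_verifier -----------------------------------------------------

def _candidates_at(truth, sites, repeat):
    (mic, fid) = (
        truth.sites["micrograph_id"].iloc[0],
        int(truth.sites["filament_id"].iloc[0]),
    )
    return [
        Candidate(mic, fid, j * repeat, 0.0, 0.0) for j in sites
    ]


def test_perfect_verifier_accepts_exactly_occupied():
    cfg = SimConfig(n_micrographs=1, filaments_per_micrograph=1, rng_seed=8)
    truth, _, _, _ = simulate(cfg)
    repeat = cfg.lattice.repeat_ang
    v = corrupt_verifier(truth, fp=0.0, fn=0.0)
    sub = truth.sites
    for row in sub.itertuples():
        c = Candidate(row.micrograph_id, int(row.filament_id), row.s_ang, 0.0, 0.0)
        assert v(c) == bool(row.occupied)


def test_total_false_negative_rejects_occupied():
    cfg = SimConfig(n_micrographs=1, filaments_per_micrograph=1, p_start=1.0, p_stay=1.0, rng_seed=8)
    truth, _, _, _ = simulate(cfg)
    v = corrupt_verifier(truth, fp=0.0, fn=1.0)
    for c in _candidates_at(truth, truth.sites["site_index"], cfg.lattice.repeat_ang):
        assert not v(c)


def test_false_positive_rate_binomial():
    cfg = SimConfig(
        n_micrographs=6,
        filaments_per_micrograph=5,
        field_px=16384,
        filament_length_ang=(18_000.0, 20_000.0),
        p_start=0.0,
        p_stay=0.0,
        rng_seed=5,
    )
    truth, _, _, _ = simulate(cfg)
    assert not truth.sites["occupied"].any()
    v = corrupt_verifier(truth, fp=0.1, fn=0.0, rng_seed=17)
    repeat = cfg.lattice.repeat_ang
    accepts = [
        v(Candidate(row.micrograph_id, int(row.filament_id), row.s_ang, 0.0, 0.0))
        for row in truth.sites.itertuples()
    ]
    n = len(accepts)
    assert n >= 1000
    frac = np.mean(accepts)
    assert abs(frac - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / n)


def test_verifier_is_deterministic_per_site():
    cfg = SimConfig(n_micrographs=1, rng_seed=2)
    truth, _, _, _ = simulate(cfg)
    v = corrupt_verifier(truth, fp=0.5, fn=0.5, rng_seed=3)
    row = truth.sites.iloc[0]
    c = Candidate(row["micrograph_id"], int(row["filament_id"]), row["s_ang"], 0.0, 0.0)
    assert len({v(c) for _ in range(10)}) == 1
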