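"""End-to-end curation pipeline.

Stage order follows the workflow the method defines: segment the picked
filaments, unify the register classes, run the expand/verify/iterate
recovery (which snaps and deduplicates each round), then QC.  In
synthetic mode the run starts by generating a dataset with ground truth
and ends by scoring precision/recall against it.

Identical config + seed produce byte-identical output tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .coords_io import (
    ParticleTable,
    read_particles,
    read_picks,
    write_particles,
    write_picks,
    MicrographMeta,
)
from .curation import (
    DedupPolicy,
    RegisterMap,
    deduplicate,
    snap_to_lattice,
    unify_registers,
)
from .geometry import AxisSet, arc_coordinate, build_axis, segment_axis
from .lattice import LatticeSpec
from .qc import QCReport, detect_clusters, evaluate_recovery, spacing_stats
from .recovery import ExpansionSpec, iterate_recovery
from .simulate import SimConfig, corrupt_verifier, simulate

logger = logging.getLogger("odacurate")

__all__ = ["PipelineConfig", "RunReport", "ConfigError", "DataError", "run"]


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


class DataError(ValueError):
    """Input data cannot be processed."""


class PipelineConfig(BaseModel):
    """Everything one run needs; exactly one input mode is active."""

    mode: Literal["synthetic", "real"] = "synthetic"
    sim: SimConfig | None = None
    particles_path: str | None = None
    picks_path: str | None = None
    labels_path: str | None = None
    pixel_size_ang: float = Field(default=1.36, gt=0)

    step_ang: float = Field(default=82.0, gt=0)
    repeat_multiplier: int = Field(default=3, ge=1)
    reference_phase: int = 0
    class_to_phase: dict[int, int | str] | None = None

    d_min_ang: float = Field(default=41.0, gt=0)
    dedup_scope: Literal["same_filament", "same_micrograph"] = "same_filament"

    multiples: list[int] = [1, 2]
    max_rounds: int = Field(default=10, ge=1)
    #: verifier for real mode (synthetic mode uses the ground truth)
    real_verifier: Literal["reject_all", "accept_all"] = "reject_all"
    verifier_fp: float = Field(default=0.0, ge=0.0, le=1.0)
    verifier_fn: float = Field(default=0.0, ge=0.0, le=1.0)
    verifier_tol_ang: float = Field(default=41.0, gt=0)

    qc_bin_ang: float = Field(default=10.0, gt=0)
    qc_cluster_tol_ang: float | None = None
    match_tol_ang: float = Field(default=41.0, gt=0)

    output_dir: str = "odacurate_out"
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_mode(self) -> "PipelineConfig":
        if self.mode == "real" and self.particles_path is None:
            raise ValueError("real mode requires particles_path")
        if self.mode == "synthetic" and self.particles_path is not None:
            raise ValueError("synthetic mode must not set particles_path")
        return self

    @property
    def lattice(self) -> LatticeSpec:
        return LatticeSpec(self.step_ang, self.repeat_multiplier)

    @property
    def register_map(self) -> RegisterMap:
        mapping = self.class_to_phase or {
            k: k for k in range(self.repeat_multiplier)
        }
        return RegisterMap(dict(mapping), self.reference_phase)

    def resolved_sim(self) -> SimConfig:
        if self.sim is not None:
            return self.sim
        return SimConfig(
            step_ang=self.step_ang,
            repeat_multiplier=self.repeat_multiplier,
            rng_seed=self.rng_seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
            sim = data.get("sim")
            if isinstance(sim, dict):
                for key in (
                    "filaments_per_micrograph",
                    "filament_length_ang",
                    "curvature_radius_ang",
                ):
                    if isinstance(sim.get(key), list):
                        sim[key] = tuple(sim[key])
                data["sim"] = SimConfig(**sim)
            return cls(**data)
        except (ValueError, TypeError, KeyError, AttributeError) as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


@dataclass
class RunReport:
    """Per-stage bookkeeping of one pipeline run."""

    config: dict = field(default_factory=dict)
    version: str = __version__
    stage_seconds: dict[str, float] = field(default_factory=dict)
    n_input: int = 0
    shifted_per_delta: dict[int, int] = field(default_factory=dict)
    dropped_non_particle: int = 0
    dropped_clipped: int = 0
    proposed_per_round: list[int] = field(default_factory=list)
    accepted_per_round: list[int] = field(default_factory=list)
    new_per_round: list[int] = field(default_factory=list)
    duplicates_removed: int = 0
    converged: bool = True
    n_final: int = 0
    qc: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def conserved(self) -> bool:
        """final = input - dropped - removed + accepted-and-kept."""
        return self.n_final == (
            self.n_input
            - self.dropped_non_particle
            - self.dropped_clipped
            - self.duplicates_removed
            + sum(self.new_per_round)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "stage_seconds": self.stage_seconds,
            "counts": {
                "input": self.n_input,
                "shifted_per_delta": {str(k): v for k, v in self.shifted_per_delta.items()},
                "dropped_non_particle": self.dropped_non_particle,
                "dropped_clipped": self.dropped_clipped,
                "proposed_per_round": self.proposed_per_round,
                "accepted_per_round": self.accepted_per_round,
                "new_per_round": self.new_per_round,
                "duplicates_removed": self.duplicates_removed,
                "final": self.n_final,
            },
            "converged": self.converged,
            "qc": self.qc,
            "failed_stage": self.failed_stage,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def run(config: PipelineConfig) -> RunReport:
    """Execute the pipeline; write tables and report under
    ``config.output_dir``; return the report.

    A stage error aborts the run with the stage name attached and a
    partial report written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=json.loads(config.model_dump_json()))
    lattice = config.lattice
    stage = "setup"
    t0 = time.perf_counter()

    def tick(name: str) -> None:
        nonlocal t0
        report.stage_seconds[name] = round(time.perf_counter() - t0, 4)
        t0 = time.perf_counter()

    try:
        truth = None
        if config.mode == "synthetic":
            stage = "simulate"
            sim = config.resolved_sim()
            truth, observed, picks, metas = simulate(sim)
            write_particles(observed, out / "observed.star")
            write_picks(picks, out / "picks.star")
            truth.to_csv(out / "truth_sites.csv")
            truth.to_json(out / "truth.json")
            axes = truth.axes
            seeds_df = observed.df[observed.df["is_seed"].astype(bool)]
            seeds = ParticleTable(seeds_df.reset_index(drop=True))
            verifier = corrupt_verifier(
                truth,
                fp=config.verifier_fp,
                fn=config.verifier_fn,
                tol_ang=config.verifier_tol_ang,
                rng_seed=config.rng_seed,
            )
            logger.info("simulate: %d observed, %d seeds", len(observed), len(seeds))
            tick("simulate")
        else:
            stage = "read"
            seeds = read_particles(config.particles_path)
            if config.labels_path:
                labels = pd.read_csv(config.labels_path)
                df = seeds.df.drop(columns=["register_class"]).merge(
                    labels[["record_index", "register_class"]],
                    on="record_index",
                    how="left",
                )
                df["register_class"] = (
                    df["register_class"].fillna(-1).astype(int)
                )
                seeds = ParticleTable(df)
            picks = read_picks(config.picks_path) if config.picks_path else []
            axes = AxisSet()
            for p in picks:
                meta = MicrographMeta(
                    micrograph_id=p.micrograph_id,
                    pixel_size_ang=config.pixel_size_ang,
                )
                axes.add(build_axis(p, meta))
            verifier = (
                (lambda c: True)
                if config.real_verifier == "accept_all"
                else (lambda c: False)
            )
            tick("read")

            stage = "segment"
            # full-lattice particle stream from the picks, written as an
            # artifact of the segmentation stage
            if picks:
                boxes = pd.concat(
                    [segment_axis(ax, lattice).df for ax in axes],
                    ignore_index=True,
                )
                boxes["record_index"] = range(len(boxes))
                write_particles(ParticleTable(boxes), out / "boxes.star")
            if len(seeds) and seeds.df["s_ang"].isna().any():
                df = seeds.df.copy()
                for i in df.index[df["s_ang"].isna()]:
                    ax = axes.get(df.at[i, "micrograph_id"], df.at[i, "filament_id"])
                    pt = (
                        df.loc[i, ["x_px", "y_px"]].to_numpy(float)
                        * config.pixel_size_ang
                    )
                    df.at[i, "s_ang"] = arc_coordinate(ax, pt)
                seeds = ParticleTable(df)
            tick("segment")

        report.n_input = len(seeds)

        stage = "unify"
        unified, ustats = unify_registers(seeds, axes, config.register_map, lattice)
        report.shifted_per_delta = ustats.shifted_per_delta
        report.dropped_non_particle = ustats.dropped_non_particle
        report.dropped_clipped = ustats.dropped_clipped
        snapped, _ = snap_to_lattice(unified, axes, lattice)
        deduped, dstats = deduplicate(
            snapped, axes, DedupPolicy(config.d_min_ang, config.dedup_scope)
        )
        report.duplicates_removed = dstats.n_removed
        write_particles(deduped, out / "unified.star")
        logger.info(
            "unify: %d -> %d (dropped %d, deduped %d)",
            len(seeds), len(deduped),
            ustats.dropped_non_particle + ustats.dropped_clipped,
            dstats.n_removed,
        )
        tick("unify")

        stage = "recover"
        spec = ExpansionSpec(frozenset(config.multiples), config.max_rounds)
        curated, rlog = iterate_recovery(
            deduped, axes, lattice, spec, verifier,
            DedupPolicy(config.d_min_ang, config.dedup_scope),
        )
        report.proposed_per_round = [r.proposed for r in rlog.rounds]
        report.accepted_per_round = [r.accepted for r in rlog.rounds]
        report.new_per_round = [r.new_records for r in rlog.rounds]
        report.converged = rlog.converged
        report.n_final = len(curated)
        write_particles(curated, out / "curated.star")
        write_particles(curated, out / "curated.csv")
        logger.info("recover: %d curated after %d rounds", len(curated), len(rlog.rounds))
        tick("recover")

        stage = "qc"
        qc = spacing_stats(curated, axes, bin_ang=config.qc_bin_ang)
        qc = detect_clusters(
            curated, lattice, tol_ang=config.qc_cluster_tol_ang,
            axes=axes, report=qc,
        )
        if truth is not None:
            qc.precision, qc.recall = evaluate_recovery(
                curated, truth, tol_ang=config.match_tol_ang
            )
        qc.counters = {
            "dropped_non_particle": report.dropped_non_particle,
            "dropped_clipped": report.dropped_clipped,
            "duplicates_removed": report.duplicates_removed,
        }
        qc.to_json(out / "qc.json")
        qc.histogram_to_csv(out / "spacing_histogram.csv")
        report.qc = qc.to_dict()
        tick("qc")
    except Exception:
        report.failed_stage = stage
        report.to_json(out / "report.json")
        raise
    report.to_json(out / "report.json")
    return report
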