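"""Synthetic splayed-axoneme coordinate data with known ground truth.

Emulates, at the coordinate level, micrograph fields of gently curved
doublet microtubules carrying a binding-site lattice every 8 nm with a
functional (dynein-arm) site every third position.  Site occupancy is
drawn from a two-state Markov chain over consecutive repeat sites — the
simplest process that produces occupancy in clusters with a tunable run
length (mean run length 1/(1 - p_stay)).  Observations add isotropic
localization noise, noisy 3-class register labels, a partial initial
seed detection, and spurious seeds at unoccupied sites.

Filaments are laid as circular arcs: a single curvature parameter with
an exact arc-length closed form.  No images, densities or optics are
rendered — only coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .coords_io import (
    PROVENANCE_PICKED,
    FilamentPick,
    MicrographMeta,
    ParticleTable,
)
from .curation import _min_phase_shift
from .geometry import AxisSet, FilamentAxis
from .lattice import LatticeSpec
from .recovery import Candidate, Verifier

__all__ = ["SimConfig", "TruthTable", "simulate", "corrupt_verifier"]

_SUPPORT_STEP_ANG = 20.0  # arc sampling interval for axis polylines


class SimConfig(BaseModel):
    """Generative parameters for one synthetic dataset.

    Identical configs (including ``rng_seed``) produce identical outputs.
    """

    model_config = {"frozen": True}

    n_micrographs: int = Field(default=5, ge=1)
    field_px: int = Field(default=4096, ge=64)
    pixel_size_ang: float = Field(default=1.36, gt=0)
    filaments_per_micrograph: int | tuple[int, int] = (2, 4)
    #: filament arc length range in Å (before clipping at the field edge)
    filament_length_ang: tuple[float, float] = (3000.0, 5000.0)
    #: curvature radius range in Å; splayed doublets bend gently, so the
    #: default spans ~3-30 um. None means perfectly straight filaments.
    curvature_radius_ang: tuple[float, float] | None = (3.0e4, 3.0e5)
    step_ang: float = Field(default=82.0, gt=0)
    repeat_multiplier: int = Field(default=3, ge=1)
    #: occupancy chain: P(site occupied | previous unoccupied or first site)
    p_start: float = Field(default=0.3, ge=0.0, le=1.0)
    #: occupancy chain: P(site occupied | previous occupied)
    p_stay: float = Field(default=0.8, ge=0.0, le=1.0)
    loc_noise_ang: float = Field(default=2.0, ge=0.0)
    #: probability a particle's register label is wrong (uniform other class)
    register_label_error: float = Field(default=0.05, ge=0.0, le=1.0)
    #: probability an occupied site is in the initial seed set
    seed_detection_rate: float = Field(default=0.5, ge=0.0, le=1.0)
    #: probability an unoccupied repeat site appears as a spurious seed
    false_site_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        field_ang = self.field_px * self.pixel_size_ang
        if field_ang < self.repeat_multiplier * self.step_ang:
            raise ValueError(
                f"field of {field_ang:.0f} Å cannot hold one "
                f"{self.repeat_multiplier * self.step_ang:.0f} Å repeat"
            )
        lo, hi = self.filament_length_ang
        if not (0 < lo <= hi):
            raise ValueError("filament_length_ang must satisfy 0 < lo <= hi")
        return self

    @property
    def lattice(self) -> LatticeSpec:
        return LatticeSpec(self.step_ang, self.repeat_multiplier)

    # ---- YAML round trip ----------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump()
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("filaments_per_micrograph", "filament_length_ang", "curvature_radius_ang"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset: the filament axes, every
    repeat site with its occupancy flag, and its exact position."""

    axes: AxisSet
    sites: pd.DataFrame  # micrograph_id, filament_id, site_index, s_ang, x_px, y_px, occupied
    lattice: LatticeSpec

    def occupied_sites(self) -> pd.DataFrame:
        return self.sites[self.sites["occupied"]].reset_index(drop=True)

    def n_occupied(self) -> int:
        return int(self.sites["occupied"].sum())

    def is_occupied_near(
        self, micrograph_id: str, filament_id: int, s_ang: float, tol_ang: float
    ) -> bool:
        cache = getattr(self, "_occ_cache", None)
        if cache is None:
            cache = {}
            occ = self.sites[self.sites["occupied"]]
            for key, sub in occ.groupby(["micrograph_id", "filament_id"], sort=False):
                cache[key] = np.sort(sub["s_ang"].to_numpy())
            object.__setattr__(self, "_occ_cache", cache)
        arr = cache.get((micrograph_id, int(filament_id)))
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr, s_ang))
        lo = max(0, i - 1)
        return bool((np.abs(arr[lo : i + 1] - s_ang) <= tol_ang).any())

    def to_csv(self, path: str | Path) -> None:
        self.sites.to_csv(path, index=False, float_format="%.17g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lattice": {
                "step_ang": self.lattice.step_ang,
                "repeat_multiplier": self.lattice.repeat_multiplier,
            },
            "axes": [
                {
                    "micrograph_id": ax.micrograph_id,
                    "filament_id": ax.filament_id,
                    "support_ang": ax.support_ang.tolist(),
                }
                for ax in self.axes
            ],
            "sites": self.sites.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def _arc_support(
    rng: np.random.Generator,
    field_ang: float,
    length_ang: float,
    radius_range: tuple[float, float] | None,
) -> np.ndarray:
    """Support points of one filament axis: a circular arc (or chord)
    started at a random interior point with a random heading, clipped to
    the field."""
    margin = 0.05 * field_ang
    start = rng.uniform(margin, field_ang - margin, size=2)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    n = max(2, int(np.ceil(length_ang / _SUPPORT_STEP_ANG)) + 1)
    s = np.linspace(0.0, length_ang, n)
    if radius_range is None:
        pts = start + np.outer(s, [np.cos(theta0), np.sin(theta0)])
    else:
        radius = rng.uniform(*radius_range) * rng.choice([-1.0, 1.0])
        # circle through `start` with tangent heading theta0
        center = start + radius * np.array([-np.sin(theta0), np.cos(theta0)])
        phi = theta0 - np.pi / 2.0 * np.sign(radius) + s / radius
        pts = center + np.abs(radius) * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= field_ang)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= field_ang)
    )
    cut = np.flatnonzero(~inside)
    if cut.size:
        pts = pts[: cut[0]]
    return pts


def _occupancy_chain(
    rng: np.random.Generator, n_sites: int, p_start: float, p_stay: float
) -> np.ndarray:
    occ = np.zeros(n_sites, dtype=bool)
    prev = False
    for j in range(n_sites):
        p = p_stay if prev else p_start
        occ[j] = rng.random() < p
        prev = occ[j]
    return occ


def simulate(
    config: SimConfig,
) -> tuple[TruthTable, ParticleTable, list[FilamentPick], list[MicrographMeta]]:
    """Generate one synthetic dataset.

    Returns the ground truth, the observed particle table (one noisy
    record per occupied site plus spurious seed records; boolean
    ``is_seed`` column flags the initial detection), the filament picks,
    and per-micrograph metadata.  Deterministic in ``config``.
    """
    lattice = config.lattice
    repeat = lattice.repeat_ang
    step = lattice.step_ang
    r = lattice.repeat_multiplier
    field_ang = config.field_px * config.pixel_size_ang
    px = config.pixel_size_ang

    root = np.random.SeedSequence(config.rng_seed)
    mic_seeds = root.spawn(config.n_micrographs)

    axes = AxisSet()
    picks: list[FilamentPick] = []
    metas: list[MicrographMeta] = []
    site_rows: list[dict] = []
    obs_rows: list[dict] = []

    for mi in range(config.n_micrographs):
        mic = f"sim_{mi:04d}.mrc"
        metas.append(
            MicrographMeta(
                micrograph_id=mic,
                width_px=config.field_px,
                height_px=config.field_px,
                pixel_size_ang=px,
            )
        )
        fil_spec = config.filaments_per_micrograph
        mic_rng = np.random.default_rng(mic_seeds[mi])
        if isinstance(fil_spec, int):
            n_fil = fil_spec
        else:
            n_fil = int(mic_rng.integers(fil_spec[0], fil_spec[1] + 1))
        fil_seeds = mic_seeds[mi].spawn(n_fil)
        for fi in range(n_fil):
            rng = np.random.default_rng(fil_seeds[fi])
            fid = fi + 1
            length = rng.uniform(*config.filament_length_ang)
            pts = _arc_support(rng, field_ang, length, config.curvature_radius_ang)
            while pts.shape[0] < 2 or _polyline_length(pts) < repeat:
                # re-draw filaments clipped down to less than one repeat
                pts = _arc_support(
                    rng, field_ang, rng.uniform(*config.filament_length_ang),
                    config.curvature_radius_ang,
                )
            axis = FilamentAxis(mic, fid, pts, pixel_size_ang=px)
            axes.add(axis)
            picks.append(
                FilamentPick(
                    micrograph_id=mic,
                    filament_id=fid,
                    start_px=tuple(pts[0] / px),
                    end_px=tuple(pts[-1] / px),
                )
            )
            length = axis.total_length_ang
            n_sites = int(np.floor(length / repeat + 1e-9)) + 1
            occ = _occupancy_chain(rng, n_sites, config.p_start, config.p_stay)
            for j in range(n_sites):
                s_site = j * repeat
                xy = axis.point_at(s_site)
                site_rows.append(
                    {
                        "micrograph_id": mic,
                        "filament_id": fid,
                        "site_index": j,
                        "s_ang": s_site,
                        "x_px": xy[0] / px,
                        "y_px": xy[1] / px,
                        "occupied": bool(occ[j]),
                    }
                )
                if occ[j]:
                    obs_rows.append(
                        _observe_site(rng, config, axis, mic, fid, j, s_site)
                    )
                elif rng.random() < config.false_site_rate:
                    # spurious seed at an unoccupied site
                    rec = _observe_site(
                        rng, config, axis, mic, fid, j, s_site, spurious=True
                    )
                    obs_rows.append(rec)

    observed = _build_observed(obs_rows)
    truth = TruthTable(axes=axes, sites=pd.DataFrame(site_rows), lattice=lattice)
    return truth, observed, picks, metas


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _observe_site(
    rng: np.random.Generator,
    config: SimConfig,
    axis: FilamentAxis,
    mic: str,
    fid: int,
    j: int,
    s_site: float,
    spurious: bool = False,
) -> dict:
    lattice = config.lattice
    r = lattice.repeat_multiplier
    step = lattice.step_ang
    # the box that detected this arm sits in one of r registers: centered
    # (phase 0) or off by a whole binding site
    true_class = int(rng.integers(0, r))
    offset = -_min_phase_shift(true_class, 0, r) * step
    s_obs = s_site + offset
    if s_obs < 0 or s_obs > axis.total_length_ang:
        true_class = 0
        s_obs = s_site
    label = true_class
    if r > 1 and rng.random() < config.register_label_error:
        others = [c for c in range(r) if c != true_class]
        label = int(others[rng.integers(0, len(others))])
    xy = axis.point_at(s_obs) + rng.normal(0.0, config.loc_noise_ang, size=2)
    s_proj, _ = axis.arc_of(xy)
    if spurious:
        is_seed = True
    else:
        is_seed = bool(rng.random() < config.seed_detection_rate)
    return {
        "micrograph_id": mic,
        "x_px": xy[0] / config.pixel_size_ang,
        "y_px": xy[1] / config.pixel_size_ang,
        "filament_id": fid,
        "s_ang": s_proj,
        "register_class": label,
        "provenance": PROVENANCE_PICKED,
        "is_seed": is_seed,
        "true_site_index": j,
        "spurious": spurious,
    }


def _build_observed(rows: list[dict]) -> ParticleTable:
    if not rows:
        df = pd.DataFrame({c: [] for c in (
            "micrograph_id", "x_px", "y_px", "filament_id", "s_ang",
            "register_class", "provenance",
        )})
        df["is_seed"] = pd.Series([], dtype=bool)
        df["true_site_index"] = pd.Series([], dtype=np.int64)
        df["spurious"] = pd.Series([], dtype=bool)
        return ParticleTable(df)
    df = pd.DataFrame(rows)
    df["record_index"] = np.arange(len(df), dtype=np.int64)
    return ParticleTable(df)


def _stable_uniform(seed: int, *parts: object) -> float:
    """Deterministic uniform in [0, 1) keyed by a seed and a tuple of
    identifiers; stable across processes (unlike built-in hash)."""
    key = ":".join([str(seed), *map(str, parts)]).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2**64


def corrupt_verifier(
    truth: TruthTable,
    fp: float = 0.0,
    fn: float = 0.0,
    tol_ang: float = 41.0,
    rng_seed: int = 0,
) -> Verifier:
    """Verifier contract backed by the ground truth, optionally corrupted.

    Accepts a candidate iff an occupied site lies within ``tol_ang`` of
    its arc coordinate and it is not falsely rejected (probability
    ``fn``), or no such site exists but it is falsely accepted
    (probability ``fp``).  Decisions are deterministic given ``rng_seed``
    and repeatable for the same candidate site, so iterating the
    recovery never flip-flops on a site.
    """
    if not 0.0 <= fp <= 1.0 or not 0.0 <= fn <= 1.0:
        raise ValueError("fp and fn must be probabilities")
    repeat = truth.lattice.repeat_ang

    def verifier(c: Candidate) -> bool:
        occupied = truth.is_occupied_near(
            c.micrograph_id, c.filament_id, c.s_ang, tol_ang
        )
        j = int(round(c.s_ang / repeat))
        u = _stable_uniform(rng_seed, c.micrograph_id, c.filament_id, j)
        if occupied:
            return u >= fn
        return u < fp

    return verifier
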