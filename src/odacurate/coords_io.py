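"""Reading and writing particle and filament-pick coordinate tables.

Two on-disk dialects are supported losslessly:

* ``star`` — a single particles loop in the STAR dialect used by
  single-particle processing software (micrograph name, x/y coordinates
  in pixels, helical tube id, class number), parsed with :mod:`gemmi`.
  Unknown columns are preserved verbatim on round-trip.
* ``csv`` / ``tsv`` — a plain tabular mirror with identical columns.

Coordinate convention: x/y are pixel coordinates of box centers, origin
at the top-left pixel center, 0-based, x rightward, y downward.  The
internal canonical length unit is Å; pixel-to-Å conversion happens only
at the geometry boundary via :class:`MicrographMeta.pixel_size_ang`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "REGISTER_UNKNOWN",
    "PROVENANCE_PICKED",
    "PROVENANCE_EXPANDED",
    "CANONICAL_COLUMNS",
    "FormatError",
    "PickValidationError",
    "MicrographMeta",
    "FilamentPick",
    "ParticleTable",
    "read_particles",
    "write_particles",
    "read_picks",
    "write_picks",
]

#: Sentinel for a particle whose register class is not (yet) known.
REGISTER_UNKNOWN = -1

PROVENANCE_PICKED = "picked"
PROVENANCE_EXPANDED = "expanded"

CANONICAL_COLUMNS = [
    "micrograph_id",
    "x_px",
    "y_px",
    "filament_id",
    "s_ang",
    "register_class",
    "provenance",
    "record_index",
]

# STAR tags for the canonical columns. The rln-prefixed tags follow the
# dominant particle-table convention; the oda-prefixed tags carry fields
# this pipeline adds (arc-length coordinate, provenance).
_STAR_TAGS = {
    "micrograph_id": "_rlnMicrographName",
    "x_px": "_rlnCoordinateX",
    "y_px": "_rlnCoordinateY",
    "filament_id": "_rlnHelicalTubeID",
    "register_class": "_rlnClassNumber",
    "s_ang": "_odaArcLengthAng",
    "provenance": "_odaProvenance",
    "record_index": "_odaRecordIndex",
}
_TAG_TO_COLUMN = {v: k for k, v in _STAR_TAGS.items()}

# extra DataFrame columns that are not STAR tags themselves are written
# under this prefix and recovered verbatim on read
_EXTRA_PREFIX = "_odaExtra_"


def _column_to_tag(col: str) -> str:
    if col in _STAR_TAGS:
        return _STAR_TAGS[col]
    if col.startswith("_"):
        return col
    return _EXTRA_PREFIX + col


def _tag_to_column(tag: str) -> str:
    if tag in _TAG_TO_COLUMN:
        return _TAG_TO_COLUMN[tag]
    if tag.startswith(_EXTRA_PREFIX):
        return tag[len(_EXTRA_PREFIX):]
    return tag


class FormatError(ValueError):
    """A table file violates the expected dialect (missing column,
    unparsable cell, malformed loop)."""


class PickValidationError(ValueError):
    """A filament pick violates its invariants (zero chord, duplicate id)."""


@dataclass(frozen=True)
class MicrographMeta:
    """Size and scale of one micrograph."""

    micrograph_id: str
    width_px: int = 4096
    height_px: int = 4096
    #: Å per pixel; 1.36 Å is the calibrated pixel size of the K3 data
    #: this pipeline was designed around.
    pixel_size_ang: float = 1.36

    def __post_init__(self) -> None:
        if self.pixel_size_ang <= 0:
            raise ValueError(
                f"pixel_size_ang must be positive, got {self.pixel_size_ang}"
            )


@dataclass(frozen=True)
class FilamentPick:
    """One manually picked filament: a start and an end coordinate on a
    micrograph, in pixels."""

    micrograph_id: str
    filament_id: int
    start_px: tuple[float, float]
    end_px: tuple[float, float]

    def __post_init__(self) -> None:
        if self.start_px == self.end_px:
            raise PickValidationError(
                f"filament {self.filament_id} on {self.micrograph_id!r}: "
                "start and end coordinates coincide (zero-length chord)"
            )

    @property
    def chord_px(self) -> float:
        return math.dist(self.start_px, self.end_px)


class ParticleTable:
    """An ordered table of boxed particles.

    Thin wrapper around a :class:`pandas.DataFrame` that enforces the
    canonical schema.  Extra (unknown) columns from an input file are
    carried along untouched and re-emitted on write.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = _coerce_schema(df)
        self.validate()

    # ---- construction -------------------------------------------------
    @classmethod
    def empty(cls) -> "ParticleTable":
        return cls(pd.DataFrame({c: [] for c in CANONICAL_COLUMNS}))

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "ParticleTable":
        df = pd.DataFrame(list(records))
        return cls(df)

    # ---- container protocol -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParticleTable):
            return NotImplemented
        return self.df.equals(other.df)

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy())

    @property
    def extra_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in CANONICAL_COLUMNS]

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if not np.isfinite(df["x_px"].to_numpy(float)).all() or not np.isfinite(
            df["y_px"].to_numpy(float)
        ).all():
            raise ValueError("x_px and y_px must be finite")
        if (df["filament_id"].to_numpy() < 1).any():
            raise ValueError("filament_id must be >= 1")
        idx = df["record_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError("record_index values must be unique")
        bad = set(df["provenance"].unique()) - {
            PROVENANCE_PICKED,
            PROVENANCE_EXPANDED,
        }
        if bad:
            raise ValueError(f"unknown provenance values: {sorted(bad)}")


def _coerce_schema(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    n = len(df)
    if "micrograph_id" not in df.columns:
        raise FormatError("required column missing: micrograph_id")
    for col in ("x_px", "y_px"):
        if col not in df.columns:
            raise FormatError(f"required column missing: {col}")
    if "filament_id" not in df.columns:
        # single-filament-per-micrograph default, flagged for the caller
        df["filament_id"] = 1
        df["filament_id_defaulted"] = True
    if "s_ang" not in df.columns:
        df["s_ang"] = np.nan
    if "register_class" not in df.columns:
        df["register_class"] = REGISTER_UNKNOWN
    if "provenance" not in df.columns:
        df["provenance"] = PROVENANCE_PICKED
    if "record_index" not in df.columns:
        df["record_index"] = np.arange(n, dtype=np.int64)
    df["micrograph_id"] = df["micrograph_id"].astype(str)
    df["provenance"] = df["provenance"].astype(str)
    for col, dtype in (
        ("x_px", np.float64),
        ("y_px", np.float64),
        ("s_ang", np.float64),
        ("filament_id", np.int64),
        ("register_class", np.int64),
        ("record_index", np.int64),
    ):
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"column {col} is not numeric: {exc}") from exc
    ordered = CANONICAL_COLUMNS + [
        c for c in df.columns if c not in CANONICAL_COLUMNS
    ]
    return df[ordered].reset_index(drop=True)


# ---------------------------------------------------------------------------
# particle tables
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".star":
        return "star"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def read_particles(path: str | Path, dialect: str | None = None) -> ParticleTable:
    """Read a particle table.

    ``dialect`` is ``"star"``, ``"csv"`` or ``"tsv"``; when ``None`` it is
    inferred from the file extension.  Missing optional columns
    (filament id, class, arc length, provenance) are filled with
    defaults; missing required columns raise :class:`FormatError`.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "star":
        df = _read_star_loop(path)
    elif dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        if df.empty and not set(df.columns) >= {"micrograph_id", "x_px", "y_px"}:
            # header-only file written by write_particles
            pass
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return ParticleTable(df)


def _read_star_loop(path: Path) -> pd.DataFrame:
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse STAR file {path}: {exc}") from exc
    block = None
    for blk in doc:
        if any(item.loop is not None for item in blk):
            block = blk
            break
    if block is None:
        # header-only or empty file: empty table
        return pd.DataFrame({c: [] for c in ("micrograph_id", "x_px", "y_px")})
    loop = next(item.loop for item in block if item.loop is not None)
    tags = list(loop.tags)
    ncol, nrow = loop.width(), loop.length()
    columns: dict[str, list[str]] = {t: [] for t in tags}
    for i in range(nrow):
        for j, t in enumerate(tags):
            columns[t].append(gemmi.cif.as_string(loop[i, j]))
    data: dict[str, object] = {}
    for tag, values in columns.items():
        data[_tag_to_column(tag)] = values
    df = pd.DataFrame(data)
    for col in ("x_px", "y_px", "s_ang"):
        if col in df.columns:
            df[col] = _parse_numeric(df[col], col)
    for col in ("filament_id", "register_class", "record_index"):
        if col in df.columns:
            df[col] = _parse_numeric(df[col], col).astype(np.int64)
    return df


def _parse_numeric(series: pd.Series, name: str) -> pd.Series:
    # float() rather than pd.to_numeric: the latter's fast parser is not
    # correctly rounded, which breaks bit-exact round-trips
    vals = np.empty(len(series), dtype=np.float64)
    for i, v in enumerate(series):
        if v in ("", "nan", "NaN", "None"):
            vals[i] = np.nan
            continue
        try:
            vals[i] = float(v)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"unparsable numeric cell in column {name!r} at row {i}: {v!r}"
            ) from exc
    return pd.Series(vals, index=series.index)


def write_particles(
    table: ParticleTable, path: str | Path, dialect: str | None = None
) -> None:
    """Write a particle table; round-trips with :func:`read_particles`
    losslessly on all supported fields (full numeric precision)."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    table.validate()
    if dialect == "star":
        _write_star_loop(table, path)
    elif dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        # repr-precision floats so coordinates survive bit-identically
        table.df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def _write_star_loop(table: ParticleTable, path: Path) -> None:
    df = table.df
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    tags = [_STAR_TAGS[c] for c in CANONICAL_COLUMNS] + [
        _column_to_tag(c) for c in table.extra_columns
    ]
    loop = block.init_loop("", tags)
    for _, row in df.iterrows():
        cells = []
        for col in CANONICAL_COLUMNS + table.extra_columns:
            v = row[col]
            if isinstance(v, float):
                cells.append(repr(v))
            else:
                cells.append(gemmi.cif.quote(str(v)))
        loop.add_row(cells)
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# filament picks
# ---------------------------------------------------------------------------

def read_picks(path: str | Path, dialect: str | None = None) -> list[FilamentPick]:
    """Read filament picks (start/end coordinate pairs).

    STAR dialect: a loop with micrograph name, filament id, x, y and two
    consecutive rows (start, end) per filament.  Text dialect: the same
    four whitespace-separated fields, two lines per filament.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "star":
        df = _read_star_loop(path)
        if "filament_id" not in df.columns:
            raise FormatError("pick file lacks a filament id column")
        rows = list(
            df[["micrograph_id", "filament_id", "x_px", "y_px"]].itertuples(
                index=False
            )
        )
    else:
        rows = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"pick line {lineno}: expected 4 fields, got {len(parts)}"
                )
            try:
                rows.append(
                    (parts[0], int(parts[1]), float(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise FormatError(f"pick line {lineno}: {exc}") from exc
    if len(rows) % 2 != 0:
        raise FormatError(
            "pick file must contain two coordinate rows (start, end) per filament"
        )
    picks: list[FilamentPick] = []
    seen: set[tuple[str, int]] = set()
    for a, b in zip(rows[0::2], rows[1::2]):
        mic_a, fid_a = str(a[0]), int(a[1])
        mic_b, fid_b = str(b[0]), int(b[1])
        if (mic_a, fid_a) != (mic_b, fid_b):
            raise FormatError(
                f"start/end rows disagree on identity: "
                f"({mic_a}, {fid_a}) vs ({mic_b}, {fid_b})"
            )
        key = (mic_a, fid_a)
        if key in seen:
            raise PickValidationError(
                f"duplicate filament_id {fid_a} on micrograph {mic_a!r}"
            )
        seen.add(key)
        picks.append(
            FilamentPick(
                micrograph_id=mic_a,
                filament_id=fid_a,
                start_px=(float(a[2]), float(a[3])),
                end_px=(float(b[2]), float(b[3])),
            )
        )
    return picks


def write_picks(
    picks: Sequence[FilamentPick], path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "star":
        doc = gemmi.cif.Document()
        block = doc.add_new_block("filament_picks")
        loop = block.init_loop(
            "",
            [
                _STAR_TAGS["micrograph_id"],
                _STAR_TAGS["filament_id"],
                _STAR_TAGS["x_px"],
                _STAR_TAGS["y_px"],
            ],
        )
        for p in picks:
            for xy in (p.start_px, p.end_px):
                loop.add_row(
                    [
                        gemmi.cif.quote(p.micrograph_id),
                        str(p.filament_id),
                        repr(xy[0]),
                        repr(xy[1]),
                    ]
                )
        doc.write_file(str(path))
    else:
        lines = []
        for p in picks:
            for xy in (p.start_px, p.end_px):
                lines.append(
                    f"{p.micrograph_id} {p.filament_id} {xy[0]!r} {xy[1]!r}"
                )
        Path(path).write_text("\n".join(lines) + "\n")


def group_picks(picks: Sequence[FilamentPick]) -> dict[str, list[FilamentPick]]:
    """Group picks per micrograph, preserving order."""
    groups: dict[str, list[FilamentPick]] = {}
    for p in picks:
        groups.setdefault(p.micrograph_id, []).append(p)
    return groups
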