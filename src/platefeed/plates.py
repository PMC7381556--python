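"""Reading, validating and joining 96-well plate data.

The interchange dialect is comma-delimited UTF-8 with a header row.
Two read layouts are supported:

* **grid** — one plate per file, 8 rows labelled ``A``–``H`` in the first
  column and 12 numeric columns headed ``1``–``12``; every cell is a raw
  fluorescence value (RFU).
* **long** — one row per well with columns ``plate_id, well, fluorescence``
  and optional ``role, sample_id, gain``; several plates may share a file.

Everything downstream operates on a tidy *well table*: one row per well
with the canonical columns in :data:`WELL_COLUMNS`.  ``join_layout``
annotates that table with roles and per-animal metadata; it never touches
the fluorescence values.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import LayoutError, PlateFormatError

ROWS = tuple("ABCDEFGH")
COLUMNS = tuple(range(1, 13))

#: Valid values of the ``role`` column.
ROLES = ("sample", "control", "stressor_control", "blank", "empty")

#: Canonical columns of a tidy well table.
WELL_COLUMNS = [
    "plate_id",
    "well",
    "row",
    "column",
    "fluorescence",
    "role",
    "sample_id",
    "gain",
]

#: Extra columns present after ``join_layout``.
ANNOTATED_COLUMNS = WELL_COLUMNS + [
    "genotype",
    "block",
    "status",
    "volume_mL",
    "hours",
    "n_tech_reps",
]

#: Status tokens an animal may carry (comma separated in files).
STATUS_TOKENS = ("ok", "alive", "died", "male")


def well_name(row: str, column: int) -> str:
    return f"{row}{column}"


def split_well(well: str) -> tuple[str, int]:
    """Split ``"A1"``–``"H12"`` into (row, column); raise on anything else."""
    well = str(well).strip().upper()
    row, col_s = well[:1], well[1:]
    if row not in ROWS or not col_s.isdigit() or int(col_s) not in COLUMNS:
        raise PlateFormatError(
            f"invalid well address {well!r}: expected row A-H and column 1-12"
        )
    return row, int(col_s)


@dataclass(frozen=True)
class WellAddress:
    """Location of one well: plate label, row letter A-H, column 1-12."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise PlateFormatError(f"row {self.row!r} not in A-H")
        if self.column not in COLUMNS:
            raise PlateFormatError(f"column {self.column!r} not in 1-12")

    @property
    def well(self) -> str:
        return well_name(self.row, self.column)


@dataclass(frozen=True)
class WellRecord:
    """One fluorescence measurement tied to a well and its role."""

    address: WellAddress
    fluorescence: float
    role: str = "empty"
    sample_id: str | None = None
    read_gain: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.fluorescence) or self.fluorescence < 0:
            raise PlateFormatError(
                f"well {self.address.plate_id}:{self.address.well}: "
                f"fluorescence must be finite and >= 0, got {self.fluorescence!r}"
            )
        if self.role not in ROLES:
            raise PlateFormatError(f"unknown role {self.role!r}")
        if self.role == "sample" and not self.sample_id:
            raise PlateFormatError(
                f"well {self.address.plate_id}:{self.address.well}: "
                "role 'sample' requires a sample_id"
            )
        if self.role != "sample" and self.sample_id:
            raise PlateFormatError(
                f"well {self.address.plate_id}:{self.address.well}: "
                f"role {self.role!r} must not carry a sample_id"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Per-animal metadata: genotype, temporal block, status flags, V and t."""

    sample_id: str
    genotype: str
    block: str
    status: frozenset = frozenset({"ok"})
    tube_volume_mL: float | None = None
    assay_hours: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.status) - set(STATUS_TOKENS)
        if bad:
            raise LayoutError(f"sample {self.sample_id}: unknown status {sorted(bad)}")
        if self.tube_volume_mL is not None and self.tube_volume_mL <= 0:
            raise LayoutError(f"sample {self.sample_id}: tube_volume_mL must be > 0")
        if self.assay_hours is not None and self.assay_hours <= 0:
            raise LayoutError(f"sample {self.sample_id}: assay_hours must be > 0")


@dataclass
class AssayConfig:
    """Assay-wide defaults and estimator settings.

    ``default_volume_mL`` / ``default_hours`` follow the original protocol
    (10 mL tubes read after 7 h) and are overridable per animal via the
    metadata table.  ``output_units`` selects the reporting unit of the
    clearance rate; internally everything is mL hr^-1 ind^-1.
    """

    default_volume_mL: float = 10.0
    default_hours: float = 7.0
    output_units: str = "mL_per_hr"
    tech_rep_cv_warn: float = 0.15
    bootstrap_B: int = 2000
    rng_seed: int = 0
    blank_subtract: bool = False
    bootstrap_method: str = "plate_pooled"
    gain_range: tuple[float, float] = (112.0, 120.0)

    def __post_init__(self) -> None:
        if self.default_volume_mL <= 0 or self.default_hours <= 0:
            raise LayoutError("default volume and duration must be positive")
        if not 0 < self.tech_rep_cv_warn < 1:
            raise LayoutError("tech_rep_cv_warn must be in (0, 1)")
        if self.bootstrap_B < 0:
            raise LayoutError("bootstrap_B must be >= 0")
        if self.output_units not in ("mL_per_hr", "L_per_day"):
            raise LayoutError(f"unknown output_units {self.output_units!r}")
        if self.bootstrap_method not in ("plate_pooled", "wells"):
            raise LayoutError(f"unknown bootstrap_method {self.bootstrap_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "AssayConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise LayoutError(f"unknown config keys: {sorted(unknown)}")
        if "gain_range" in raw:
            raw["gain_range"] = tuple(raw["gain_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["gain_range"] = list(self.gain_range)
        return d


def _as_source(table) -> io.StringIO | str | Path:
    """Accept a path, file-like object, or raw CSV text."""
    if isinstance(table, str):
        # Raw CSV text contains a newline; a path does not.
        if "\n" in table:
            return io.StringIO(table)
        return Path(table)
    return table


def parse_plate_grid(table, plate_id: str) -> pd.DataFrame:
    """Parse one 8x12 grid CSV into a tidy well table.

    Parameters
    ----------
    table
        Path, file-like object, or CSV text.  Row labels A-H in the first
        column, column headers 1-12.
    plate_id
        Label attached to all 96 wells.

    Returns
    -------
    DataFrame with :data:`WELL_COLUMNS`; role is ``"empty"`` until a layout
    is joined.
    """
    try:
        raw = pd.read_csv(_as_source(table), index_col=0, dtype=str)
    except Exception as exc:  # malformed CSV
        raise PlateFormatError(f"plate {plate_id}: cannot read grid: {exc}") from exc
    raw.index = raw.index.astype(str).str.strip().str.upper()
    raw.columns = [str(c).strip() for c in raw.columns]

    missing_rows = [r for r in ROWS if r not in raw.index]
    if missing_rows:
        raise PlateFormatError(
            f"plate {plate_id}: row{'s' if len(missing_rows) > 1 else ''} "
            f"{' '.join(missing_rows)} absent"
        )
    missing_cols = [c for c in COLUMNS if str(c) not in raw.columns]
    if missing_cols:
        raise PlateFormatError(
            f"plate {plate_id}: column(s) {missing_cols} absent"
        )
    extra_rows = [r for r in raw.index if r not in ROWS]
    if extra_rows:
        raise PlateFormatError(f"plate {plate_id}: unexpected row label(s) {extra_rows}")

    records = []
    for r in ROWS:
        for c in COLUMNS:
            cell = raw.at[r, str(c)]
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise PlateFormatError(
                    f"non-numeric fluorescence at {plate_id}:{well_name(r, c)}: {cell!r}"
                ) from None
            if not np.isfinite(value) or value < 0:
                raise PlateFormatError(
                    f"fluorescence at {plate_id}:{well_name(r, c)} must be finite "
                    f"and >= 0, got {value!r}"
                )
            records.append((plate_id, well_name(r, c), r, c, value, "empty", None, None))
    return pd.DataFrame(records, columns=WELL_COLUMNS)


def parse_long_table(table) -> pd.DataFrame:
    """Parse a long-format read CSV (plate_id, well, fluorescence[, role, sample_id, gain])."""
    df = pd.read_csv(_as_source(table), dtype={"plate_id": str, "well": str})
    required = {"plate_id", "well", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise PlateFormatError(f"long table missing column(s): {sorted(missing)}")

    rows, cols = [], []
    for well in df["well"]:
        r, c = split_well(well)
        rows.append(r)
        cols.append(c)
    df = df.assign(row=rows, column=cols, well=[well_name(r, c) for r, c in zip(rows, cols)])

    dup = df.duplicated(subset=["plate_id", "well"], keep=False)
    if dup.any():
        pairs = sorted(
            {f"{p}:{w}" for p, w in df.loc[dup, ["plate_id", "well"]].itertuples(index=False)}
        )
        raise PlateFormatError(f"duplicate wells: {', '.join(pairs)}")

    fl = pd.to_numeric(df["fluorescence"], errors="coerce")
    bad = ~np.isfinite(fl) | (fl < 0)
    if bad.any():
        first = df.loc[bad].iloc[0]
        raise PlateFormatError(
            f"fluorescence at {first['plate_id']}:{first['well']} must be finite and >= 0, "
            f"got {first['fluorescence']!r}"
        )
    df["fluorescence"] = fl.astype(float)

    if "role" not in df.columns:
        df["role"] = "empty"
    df["role"] = df["role"].fillna("empty")
    bad_roles = set(df["role"]) - set(ROLES)
    if bad_roles:
        raise PlateFormatError(f"unknown role(s) {sorted(bad_roles)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = None
    if "gain" not in df.columns:
        df["gain"] = None
    return df[WELL_COLUMNS].reset_index(drop=True)


def wells_to_grid(wells: pd.DataFrame, plate_id: str) -> pd.DataFrame:
    """Pivot one plate of a well table back into the 8x12 grid (lossless inverse)."""
    sub = wells[wells["plate_id"] == plate_id]
    if len(sub) != 96:
        raise PlateFormatError(
            f"plate {plate_id}: grid export needs all 96 wells, found {len(sub)}"
        )
    grid = sub.pivot(index="row", columns="column", values="fluorescence")
    return grid.reindex(index=list(ROWS), columns=list(COLUMNS))


def grid_to_csv(wells: pd.DataFrame, plate_id: str, path) -> None:
    wells_to_grid(wells, plate_id).to_csv(path, index_label="")


def read_layout(table) -> pd.DataFrame:
    """Read a layout CSV (plate_id, well, role[, sample_id])."""
    df = pd.read_csv(_as_source(table), dtype={"plate_id": str, "well": str, "sample_id": str})
    missing = {"plate_id", "well", "role"} - set(df.columns)
    if missing:
        raise LayoutError(f"layout missing column(s): {sorted(missing)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = None
    df["well"] = [well_name(*split_well(w)) for w in df["well"]]
    return df


def read_metadata(table) -> pd.DataFrame:
    """Read a metadata CSV (sample_id, genotype, block[, status, volume_mL, hours])."""
    df = pd.read_csv(_as_source(table), dtype={"sample_id": str, "genotype": str, "block": str})
    missing = {"sample_id", "genotype", "block"} - set(df.columns)
    if missing:
        raise LayoutError(f"metadata missing column(s): {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise LayoutError(f"duplicate sample_id in metadata: {dups}")
    if "status" not in df.columns:
        df["status"] = "ok"
    df["status"] = df["status"].fillna("ok")
    for col in ("volume_mL", "hours"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0, "sample_id"].tolist()
            raise LayoutError(f"{col} must be > 0 for sample(s) {bad}")
    for st in df["status"]:
        toks = {t.strip() for t in str(st).split(",") if t.strip()}
        bad = toks - set(STATUS_TOKENS)
        if bad:
            raise LayoutError(f"unknown status token(s) {sorted(bad)}")
    return df


def join_layout(
    wells: pd.DataFrame,
    layout: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    config: AssayConfig | None = None,
) -> pd.DataFrame:
    """Annotate a well table with roles and sample metadata.

    Fluorescence values are never altered.  Raises :class:`LayoutError` if
    the layout names a well absent from the reads, or a sample lacks
    metadata.  An empty layout leaves every well ``role="empty"`` and warns.
    """
    wells = wells.copy()
    if len(layout) == 0:
        warnings.warn("empty layout: all wells remain role='empty'", stacklevel=2)
    key = ["plate_id", "well"]
    known = set(map(tuple, wells[key].itertuples(index=False)))
    asked = list(map(tuple, layout[key].itertuples(index=False)))
    missing = sorted(set(asked) - known)
    if missing:
        names = ", ".join(f"{p}:{w}" for p, w in missing)
        raise LayoutError(f"layout names well(s) not present in reads: {names}")
    if len(asked) != len(set(asked)):
        raise LayoutError("layout assigns the same well more than once")

    bad_roles = set(layout["role"]) - set(ROLES)
    if bad_roles:
        raise LayoutError(f"unknown role(s) in layout: {sorted(bad_roles)}")
    needs_id = layout["role"].eq("sample") & layout["sample_id"].isna()
    if needs_id.any():
        ws = [f"{p}:{w}" for p, w in layout.loc[needs_id, key].itertuples(index=False)]
        raise LayoutError(f"role 'sample' without sample_id at {', '.join(ws)}")
    stray = ~layout["role"].eq("sample") & layout["sample_id"].notna()
    if stray.any():
        ws = [f"{p}:{w}" for p, w in layout.loc[stray, key].itertuples(index=False)]
        raise LayoutError(f"non-sample wells must not carry sample_id: {', '.join(ws)}")

    wells = wells.drop(columns=["role", "sample_id"]).merge(
        layout[key + ["role", "sample_id"]], on=key, how="left"
    )
    wells["role"] = wells["role"].fillna("empty")

    if meta is None:
        meta = pd.DataFrame(columns=["sample_id", "genotype", "block", "status", "volume_mL", "hours"])
    sample_ids = set(wells.loc[wells["role"] == "sample", "sample_id"])
    lacking = sorted(sample_ids - set(meta["sample_id"]))
    if lacking:
        raise LayoutError(f"sample(s) in layout without metadata: {lacking}")

    out = wells.merge(
        meta[["sample_id", "genotype", "block", "status", "volume_mL", "hours"]],
        on="sample_id",
        how="left",
    )
    cfg = config or AssayConfig()
    for col, default in (("volume_mL", cfg.default_volume_mL), ("hours", cfg.default_hours)):
        out[col] = pd.to_numeric(out[col], errors="coerce").fillna(default)

    reps = out[out["role"] == "sample"].groupby("sample_id")["well"].size()
    out["n_tech_reps"] = out["sample_id"].map(reps)

    gains = pd.to_numeric(out["gain"], errors="coerce").dropna()
    lo, hi = cfg.gain_range
    if len(gains) and ((gains < lo) | (gains > hi)).any():
        warnings.warn(
            f"read gain outside accepted range [{lo:g}, {hi:g}] on some wells",
            stacklevel=2,
        )
    return out[ANNOTATED_COLUMNS]


def read_plate_files(paths: Iterable, plate_ids: Mapping | None = None) -> pd.DataFrame:
    """Read several grid CSVs (plate_id defaults to the file stem) into one well table."""
    frames = []
    for p in paths:
        pid = (plate_ids or {}).get(p, Path(p).stem)
        frames.append(parse_plate_grid(p, pid))
    if not frames:
        raise PlateFormatError("no plate files given")
    return pd.concat(frames, ignore_index=True)
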