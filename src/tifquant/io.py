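"""Tabular I/O for the quantification pipeline.

All artifacts are plain UTF-8 CSV with a header row.  The three core
containers live here:

* :class:`StandardsLibrary` — per-metabolite quantification metadata: pool
  assignment, nominal pool concentrations per dilution level, retention time,
  m/z, limit of detection (LOD), quantification mode (stable isotope dilution
  vs external calibration) and the paired labeled internal standard.
* :class:`SampleSheet` — sample metadata (matrix type, group factors, tumor
  mass, TIF volume, dilution level for standard-pool injections).
* :class:`PeakTable` — long-form (sample_id, species_id, peak_area) integrated
  LC/MS peak areas, where a species is either an unlabeled analyte or an
  isotopically labeled standard.  Missing areas are NaN, never 0: a zero is a
  measurement, absence is information for detection filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    CrossReferenceError,
    SchemaError,
    ValidationError,
)

QUANT_MODES = ("isotope_dilution", "external_calibration")
MATRIX_TYPES = (
    "plasma",
    "tif",
    "standard_dilution",
    "water",
    "tumor_lysate",
    "tumor_powder",
)

#: prefix of the library columns that carry nominal pool concentrations;
#: the suffix is the dilution-level tag, file column order = decreasing conc.
NOMINAL_PREFIX = "nominal_"


@dataclass(frozen=True)
class StandardEntry:
    """One metabolite of the chemical-standards library."""

    metabolite_id: str
    pool_id: str
    nominal_conc_by_level: dict[str, float]  # level tag -> µM, decreasing
    mz: float
    retention_time: float  # minutes
    lod: float  # µM
    quant_mode: str
    paired_standard_id: str

    def __post_init__(self) -> None:
        if self.quant_mode not in QUANT_MODES:
            raise ValidationError(
                f"{self.metabolite_id}: unknown quant_mode {self.quant_mode!r}"
            )
        if not self.paired_standard_id:
            raise ValidationError(f"{self.metabolite_id}: empty paired_standard_id")
        if not self.lod > 0:
            raise ValidationError(f"{self.metabolite_id}: lod must be > 0")
        concs = list(self.nominal_conc_by_level.values())
        if not concs:
            raise ValidationError(f"{self.metabolite_id}: no dilution levels")
        if any(c <= 0 for c in concs):
            raise ValidationError(f"{self.metabolite_id}: non-positive nominal conc")
        if any(b >= a for a, b in zip(concs, concs[1:])):
            raise ValidationError(
                f"{self.metabolite_id}: nominal concentrations must be strictly "
                "decreasing across dilution levels"
            )


class StandardsLibrary:
    """Validated collection of :class:`StandardEntry`, unique by metabolite_id."""

    def __init__(self, entries: Iterable[StandardEntry]):
        entries = list(entries)
        seen: dict[str, StandardEntry] = {}
        dups = []
        for e in entries:
            if e.metabolite_id in seen:
                dups.append(e.metabolite_id)
            seen[e.metabolite_id] = e
        if dups:
            raise ValidationError(f"duplicate metabolite_id(s): {sorted(set(dups))}")
        self._entries = {e.metabolite_id: e for e in entries}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, metabolite_id: str) -> bool:
        return metabolite_id in self._entries

    def __getitem__(self, metabolite_id: str) -> StandardEntry:
        return self._entries[metabolite_id]

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self._entries)

    @property
    def pool_ids(self) -> list[str]:
        return sorted({e.pool_id for e in self})

    def by_mode(self, quant_mode: str) -> list[StandardEntry]:
        return [e for e in self if e.quant_mode == quant_mode]

    def pool_members(self, pool_id: str) -> list[StandardEntry]:
        return [e for e in self if e.pool_id == pool_id]

    def levels(self) -> list[str]:
        """Dilution-level tags in decreasing-concentration order (first entry's order)."""
        first = next(iter(self))
        return list(first.nominal_conc_by_level)

    def to_frame(self) -> pd.DataFrame:
        levels: list[str] = []
        for e in self:
            for lv in e.nominal_conc_by_level:
                if lv not in levels:
                    levels.append(lv)
        rows = []
        for e in self:
            row: dict[str, object] = {
                "metabolite_id": e.metabolite_id,
                "pool_id": e.pool_id,
                "mz": e.mz,
                "retention_time": e.retention_time,
                "lod": e.lod,
                "quant_mode": e.quant_mode,
                "paired_standard_id": e.paired_standard_id,
            }
            for lv in levels:
                row[NOMINAL_PREFIX + lv] = e.nominal_conc_by_level.get(lv, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


REQUIRED_LIBRARY_COLUMNS = (
    "metabolite_id",
    "pool_id",
    "mz",
    "retention_time",
    "lod",
    "quant_mode",
    "paired_standard_id",
)


def read_standards_library(path: str | Path) -> StandardsLibrary:
    """Read and validate a standards-library CSV.

    Nominal pool concentrations are taken from every column named
    ``nominal_<level>``; column order in the file defines the level order and
    concentrations must strictly decrease along it.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_LIBRARY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"standards library is missing column {col!r}")
    level_cols = [c for c in df.columns if c.startswith(NOMINAL_PREFIX)]
    if not level_cols:
        raise SchemaError(
            f"standards library has no nominal-concentration ({NOMINAL_PREFIX}*) columns"
        )
    dup = df["metabolite_id"][df["metabolite_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate metabolite_id(s): {sorted(dup.unique())}")
    entries = []
    for _, row in df.iterrows():
        nominal = {
            c[len(NOMINAL_PREFIX):]: float(row[c])
            for c in level_cols
            if pd.notna(row[c])
        }
        entries.append(
            StandardEntry(
                metabolite_id=str(row["metabolite_id"]),
                pool_id=str(row["pool_id"]),
                nominal_conc_by_level=nominal,
                mz=float(row["mz"]),
                retention_time=float(row["retention_time"]),
                lod=float(row["lod"]),
                quant_mode=str(row["quant_mode"]),
                paired_standard_id=str(row["paired_standard_id"]),
            )
        )
    return StandardsLibrary(entries)


class SampleSheet:
    """Sample metadata keyed by unique sample_id."""

    REQUIRED = ("sample_id", "matrix_type")
    OPTIONAL = ("dilution_level", "tumor_mass", "tif_volume", "tissue_mass")

    def __init__(self, frame: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise SchemaError(f"sample sheet is missing column {col!r}")
        dup = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id(s): {sorted(dup.unique())}")
        bad = set(frame["matrix_type"]) - set(MATRIX_TYPES)
        if bad:
            raise ValidationError(f"unknown matrix_type(s): {sorted(bad)}")
        std = frame[frame["matrix_type"] == "standard_dilution"]
        if len(std) and (
            "dilution_level" not in frame.columns
            or std["dilution_level"].isna().any()
        ):
            raise ValidationError(
                "standard_dilution samples must carry a dilution_level"
            )
        powder = frame[frame["matrix_type"] == "tumor_powder"]
        if len(powder):
            if "tissue_mass" not in frame.columns or not (
                powder["tissue_mass"] > 0
            ).all():
                raise ValidationError("tumor_powder samples must carry tissue_mass > 0")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def group_factors(self) -> list[str]:
        skip = set(self.REQUIRED) | set(self.OPTIONAL)
        return [c for c in self.frame.columns if c not in skip]

    def record(self, sample_id: str) -> pd.Series:
        match = self.frame[self.frame["sample_id"] == sample_id]
        if not len(match):
            raise CrossReferenceError(f"unknown sample_id {sample_id!r}")
        return match.iloc[0]

    def samples_where(self, **conditions: object) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        for col, value in conditions.items():
            if col not in self.frame.columns:
                raise CrossReferenceError(f"unknown sample-sheet column {col!r}")
            mask &= self.frame[col] == value
        return list(self.frame.loc[mask, "sample_id"])

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


LONG_COLUMNS = ("sample_id", "species_id", "peak_area")


class PeakTable:
    """Long-form peak areas; one row per (sample, species), NaN = missing."""

    def __init__(self, frame: pd.DataFrame):
        for col in LONG_COLUMNS:
            if col not in frame.columns:
                raise SchemaError(f"peak table is missing column {col!r}")
        frame = frame.loc[:, list(LONG_COLUMNS)].reset_index(drop=True)
        frame["peak_area"] = frame["peak_area"].astype(float)
        dup = frame.duplicated(subset=["sample_id", "species_id"])
        if dup.any():
            pairs = frame.loc[dup, ["sample_id", "species_id"]].apply(tuple, axis=1)
            raise ValidationError(f"duplicate (sample, species) pairs: {list(pairs)[:5]}")
        if (frame["peak_area"].dropna() < 0).any():
            raise ValidationError("negative peak areas are not allowed")
        self.frame = frame
        self._lookup = frame.set_index(["sample_id", "species_id"])["peak_area"]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    @property
    def species_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["species_id"]))

    def area(self, sample_id: str, species_id: str) -> float:
        """Peak area; NaN when the cell is missing or absent from the table."""
        try:
            return float(self._lookup.loc[(sample_id, species_id)])
        except KeyError:
            return float("nan")

    def areas_of(self, species_id: str, sample_ids: Iterable[str] | None = None) -> pd.Series:
        sub = self.frame[self.frame["species_id"] == species_id]
        ser = sub.set_index("sample_id")["peak_area"]
        if sample_ids is not None:
            ser = ser.reindex(list(sample_ids))
        return ser

    def wide(self) -> pd.DataFrame:
        return self.frame.pivot(index="sample_id", columns="species_id", values="peak_area")

    def scaled(self, sample_id: str, factor: float) -> "PeakTable":
        """New table with every area of one sample multiplied by ``factor``."""
        frame = self.frame.copy()
        mask = frame["sample_id"] == sample_id
        frame.loc[mask, "peak_area"] *= factor
        return PeakTable(frame)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "PeakTable":
        return cls(pd.DataFrame(records, columns=list(LONG_COLUMNS)))

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def read_peak_table(path: str | Path, sample_sheet: SampleSheet | None = None) -> PeakTable:
    """Read a peak table, accepting long or wide layout.

    Long layout has exactly the columns (sample_id, species_id, peak_area);
    anything else is treated as wide: a sample_id column plus one column per
    species.  Empty cells stay missing (NaN).  When a sample sheet is given,
    every sample_id must appear in it.
    """
    df = pd.read_csv(path)
    if set(LONG_COLUMNS) <= set(df.columns) and len(df.columns) == 3:
        table = PeakTable(df)
    else:
        if "sample_id" not in df.columns:
            raise SchemaError("wide peak table must have a sample_id column")
        long = df.melt(id_vars="sample_id", var_name="species_id", value_name="peak_area")
        table = PeakTable(long)
    if sample_sheet is not None:
        unknown = set(table.sample_ids) - set(sample_sheet.sample_ids)
        if unknown:
            raise CrossReferenceError(
                f"peak table references unknown sample_id(s): {sorted(unknown)}"
            )
    return table


def write_concentration_table(table, path: str | Path) -> None:
    """Serialize a ConcentrationTable (delegates to the table's own writer)."""
    table.write_csv(path)


def read_concentration_table(path: str | Path):
    from .quantify import ConcentrationTable

    return ConcentrationTable.read_csv(path)


def load_config(path: str | Path) -> dict:
    """Load a run-level config from YAML or JSON (by extension, YAML default)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return dict(cfg)


def validate_thresholds(cfg: Mapping) -> None:
    """Range-check the analysis thresholds of a run config."""
    checks = {
        "r2_gate": (0.0, 1.0),
        "detection_threshold": (0.0, 1.0),
        "alpha_normality": (0.0, 1.0),
        "sig_threshold": (0.0, 1.0),
    }
    for key, (lo, hi) in checks.items():
        if key in cfg:
            v = float(cfg[key])
            if not (lo < v <= hi):
                raise ConfigError(f"{key}={v} outside ({lo}, {hi}]")
    if "fc_threshold" in cfg and float(cfg["fc_threshold"]) < 1.0:
        raise ConfigError("fc_threshold must be >= 1 (a ratio)")
    if "sig_mode" in cfg and cfg["sig_mode"] not in ("raw_p", "fdr_q"):
        raise ConfigError(f"unknown sig_mode {cfg['sig_mode']!r}")
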