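"""Convert biological peak areas into absolute concentrations.

Each metabolite follows exactly one path:

* isotope dilution — conc(s, m) = area_unlabeled / area_labeled × [IS], where
  [IS] is the quantified internal-standard concentration.  Because the labeled
  and unlabeled species share the sample's matrix factor, it cancels: this
  path is matrix-robust (quantitative).
* external calibration — conc(s, m) = (normalized area − intercept) / slope
  from the calibration curve.  The matrix factor does not cancel against the
  water-matrix curve, so these values are semi-quantitative.

Every (sample, metabolite) cell carries exactly one status; a concentration is
present if and only if the status starts with "quantified".  Below-LOD and
missing cells are censored, not imputed (an optional LOD/2 accessor exists for
sensitivity analyses but is never the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .errors import AssemblyError, ConfigError, ValidationError
from .io import PeakTable, SampleSheet, StandardsLibrary

STATUS_QUANT_ID = "quantified_isotope_dilution"
STATUS_QUANT_EXT = "quantified_external"
STATUS_BELOW_LOD = "below_lod"
STATUS_MISSING = "missing_peak"
STATUS_EXCLUDED_QC = "excluded_qc"
STATUS_EXCLUDED_DETECTION = "excluded_detection_filter"

ALL_STATUSES = (
    STATUS_QUANT_ID,
    STATUS_QUANT_EXT,
    STATUS_BELOW_LOD,
    STATUS_MISSING,
    STATUS_EXCLUDED_QC,
    STATUS_EXCLUDED_DETECTION,
)

_COLUMNS = ("sample_id", "metabolite_id", "concentration", "status")


@dataclass
class ConcentrationTable:
    """Long-form (sample, metabolite) concentrations with status flags.

    ``frame`` columns: sample_id, metabolite_id, concentration (µM, NaN unless
    quantified), status.  ``meta`` columns: metabolite_id, quant_path, lod.
    """

    frame: pd.DataFrame
    meta: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["metabolite_id", "quant_path", "lod"])
    )

    def __post_init__(self) -> None:
        for col in _COLUMNS:
            if col not in self.frame.columns:
                raise ValidationError(f"concentration table missing column {col!r}")
        self.frame = self.frame.loc[:, list(_COLUMNS)].reset_index(drop=True)
        bad_status = set(self.frame["status"]) - set(ALL_STATUSES)
        if bad_status:
            raise ValidationError(f"unknown status value(s): {sorted(bad_status)}")
        dup = self.frame.duplicated(subset=["sample_id", "metabolite_id"])
        if dup.any():
            raise ValidationError("duplicate (sample, metabolite) cells")
        quantified = self.frame["status"].str.startswith("quantified")
        conc = self.frame["concentration"]
        if conc[quantified].isna().any():
            raise ValidationError("quantified cells must carry a concentration")
        if not (conc[quantified] > 0).all():
            raise ValidationError("concentrations must be positive")
        if conc[~quantified].notna().any():
            raise ValidationError("non-quantified cells must not carry a concentration")

    # -- accessors -----------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    @property
    def metabolite_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["metabolite_id"]))

    def wide(self, impute_lod_half: bool = False) -> pd.DataFrame:
        """Samples × metabolites concentration matrix (NaN where censored).

        ``impute_lod_half`` fills below-LOD cells with LOD/2 for sensitivity
        analyses; the default leaves them censored.
        """
        frame = self.frame
        values = frame.pivot(
            index="sample_id", columns="metabolite_id", values="concentration"
        )
        if impute_lod_half:
            lod = self.meta.set_index("metabolite_id")["lod"]
            statuses = frame.pivot(
                index="sample_id", columns="metabolite_id", values="status"
            )
            for m in values.columns:
                if m in lod.index and np.isfinite(lod[m]):
                    mask = statuses[m] == STATUS_BELOW_LOD
                    values.loc[mask, m] = lod[m] / 2.0
        return values

    def statuses(self) -> pd.DataFrame:
        return self.frame.pivot(index="sample_id", columns="metabolite_id", values="status")

    def status_counts(self) -> pd.Series:
        return self.frame["status"].value_counts()

    # -- serialization -------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)
        meta_path = Path(path).with_suffix(".meta.csv")
        self.meta.to_csv(meta_path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConcentrationTable":
        frame = pd.read_csv(path)
        if len(frame) == 0:
            frame = pd.DataFrame(columns=list(_COLUMNS))
        meta_path = Path(path).with_suffix(".meta.csv")
        meta = (
            pd.read_csv(meta_path)
            if meta_path.exists()
            else pd.DataFrame(columns=["metabolite_id", "quant_path", "lod"])
        )
        return cls(frame=frame, meta=meta)


def _finish_cell(conc: float, lod: float, quant_status: str) -> tuple[float, str]:
    if not np.isfinite(conc) or conc <= 0 or conc < lod:
        return np.nan, STATUS_BELOW_LOD
    return conc, quant_status


def quantify_isotope_dilution(
    sample_peaks: PeakTable,
    model: CalibrationModel,
    library: StandardsLibrary,
    sample_ids: Iterable[str] | None = None,
) -> ConcentrationTable:
    """Isotope-dilution path: ratio to the quantified labeled standard."""
    samples = list(sample_ids) if sample_ids is not None else sample_peaks.sample_ids
    rows, meta = [], []
    for entry in library.by_mode("isotope_dilution"):
        m = entry.metabolite_id
        lod = model.lods.get(m, entry.lod)
        quant = model.is_quants.get(entry.paired_standard_id)
        meta.append({"metabolite_id": m, "quant_path": "isotope_dilution", "lod": lod})
        for sid in samples:
            if quant is None:
                rows.append((sid, m, np.nan, STATUS_EXCLUDED_QC))
                continue
            a_u = sample_peaks.area(sid, m)
            a_l = sample_peaks.area(sid, entry.paired_standard_id)
            if np.isnan(a_u) or np.isnan(a_l) or a_l <= 0:
                rows.append((sid, m, np.nan, STATUS_MISSING))
                continue
            conc = a_u / a_l * quant.estimated_conc
            conc, status = _finish_cell(conc, lod, STATUS_QUANT_ID)
            rows.append((sid, m, conc, status))
    return ConcentrationTable(
        frame=pd.DataFrame(rows, columns=list(_COLUMNS)), meta=pd.DataFrame(meta)
    )


def quantify_external(
    sample_peaks: PeakTable,
    model: CalibrationModel,
    library: StandardsLibrary,
    sample_ids: Iterable[str] | None = None,
) -> ConcentrationTable:
    """External-calibration path: invert the fitted curve on normalized areas."""
    samples = list(sample_ids) if sample_ids is not None else sample_peaks.sample_ids
    rows, meta = [], []
    for entry in library.by_mode("external_calibration"):
        m = entry.metabolite_id
        lod = model.lods.get(m, entry.lod)
        curve = model.curves.get(m)
        usable = curve is not None and curve.passes_qc and curve.slope > 0
        meta.append({"metabolite_id": m, "quant_path": "external", "lod": lod})
        for sid in samples:
            if not usable:
                rows.append((sid, m, np.nan, STATUS_EXCLUDED_QC))
                continue
            a = sample_peaks.area(sid, m)
            a_norm = sample_peaks.area(sid, entry.paired_standard_id)
            if np.isnan(a) or np.isnan(a_norm) or a_norm <= 0:
                rows.append((sid, m, np.nan, STATUS_MISSING))
                continue
            y = a / a_norm
            conc = (y - curve.intercept) / curve.slope
            conc, status = _finish_cell(conc, lod, STATUS_QUANT_EXT)
            rows.append((sid, m, conc, status))
    return ConcentrationTable(
        frame=pd.DataFrame(rows, columns=list(_COLUMNS)), meta=pd.DataFrame(meta)
    )


def assemble_concentration_table(
    parts: Iterable[ConcentrationTable],
    sample_sheet: SampleSheet | None = None,
    group_factor: str | None = None,
    detection_threshold: float = 0.8,
) -> ConcentrationTable:
    """Merge the per-path tables and apply the detection filter.

    A metabolite is kept when it is quantified in at least
    ``detection_threshold`` of the samples of at least one biological group
    (groups taken from ``group_factor`` in the sample sheet; all samples form
    one group when no factor is given).  Filtered metabolites keep their rows
    with status ``excluded_detection_filter`` so the exclusion is auditable.
    """
    if not 0 < detection_threshold <= 1:
        raise ConfigError(f"detection_threshold must be in (0, 1], got {detection_threshold}")
    parts = list(parts)
    seen: set[str] = set()
    for part in parts:
        overlap = seen & set(part.metabolite_ids)
        if overlap:
            raise AssemblyError(
                f"metabolite(s) present in more than one partial table: {sorted(overlap)}"
            )
        seen |= set(part.metabolite_ids)
    frame = pd.concat([p.frame for p in parts], ignore_index=True)
    meta = pd.concat([p.meta for p in parts], ignore_index=True)

    if sample_sheet is not None and group_factor is not None:
        groups = sample_sheet.frame.set_index("sample_id")[group_factor]
        group_of = frame["sample_id"].map(groups)
    else:
        group_of = pd.Series("all", index=frame.index)
    quantified = frame["status"].str.startswith("quantified")
    detect = (
        pd.DataFrame(
            {
                "metabolite_id": frame["metabolite_id"],
                "group": group_of,
                "q": quantified,
            }
        )
        .groupby(["metabolite_id", "group"], sort=False)["q"]
        .mean()
    )
    max_rate = detect.groupby("metabolite_id").max()
    dropped = set(max_rate.index[max_rate < detection_threshold])
    if dropped:
        mask = frame["metabolite_id"].isin(dropped)
        frame.loc[mask, "concentration"] = np.nan
        frame.loc[mask, "status"] = STATUS_EXCLUDED_DETECTION
    return ConcentrationTable(frame=frame, meta=meta)


def relative_tissue_levels(
    tissue_peaks: PeakTable,
    sample_sheet: SampleSheet,
    pairing: Mapping[str, str],
) -> pd.DataFrame:
    """Internal-standard- and mass-normalized relative levels in tumor powder.

    level = peak area / normalizer standard area / tissue mass (arb. per mg).
    ``pairing`` maps each metabolite to its normalizer species (e.g. succinate
    to the ¹³C₄ succinate standard, most metabolites to labeled leucine).
    Records without a tissue mass are skipped with a warning.
    """
    import warnings

    rows = []
    sheet = sample_sheet.frame.set_index("sample_id")
    for sid in tissue_peaks.sample_ids:
        if sid not in sheet.index:
            continue
        mass = sheet.loc[sid].get("tissue_mass", np.nan)
        if not np.isfinite(mass) or mass <= 0:
            warnings.warn(f"sample {sid}: missing tissue mass; skipped", stacklevel=2)
            continue
        for metabolite, normalizer in pairing.items():
            a = tissue_peaks.area(sid, metabolite)
            a_n = tissue_peaks.area(sid, normalizer)
            if np.isnan(a) or np.isnan(a_n) or a_n <= 0:
                continue
            rows.append(
                {
                    "sample_id": sid,
                    "metabolite_id": metabolite,
                    "normalized_level_per_mg": a / a_n / mass,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "metabolite_id", "normalized_level_per_mg"]
    )
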