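"""Calibration from external-standard pool dilution series.

Two quantification paths are prepared here:

* **Stable isotope dilution** — the concentration of each ¹³C labeled internal
  standard in the extraction mix is unknown a priori (the standards come from
  labeled yeast extract); it is quantified by comparing its peak area with the
  unlabeled metabolite's area at known nominal concentrations in the pool
  dilutions:  estimate(level) = nominal(level) * area_labeled / area_unlabeled,
  combined across usable levels by the median.
* **External calibration** — for metabolites without a labeled twin, the
  analyte area is normalized to an RT-paired labeled amino acid standard and
  an unweighted ordinary-least-squares line of normalized area vs nominal
  concentration is fitted.  Curves with r² below the gate (default 0.95) fail
  QC and are excluded downstream.

The module also estimates detection limits from blank injections and computes
the matrix-effect statistic (log2 fold change of labeled-standard areas in
water vs plasma) that motivates the two-path design.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, ConfigError
from .io import PeakTable, SampleSheet, StandardsLibrary


@dataclass
class InternalStandardQuant:
    """Quantified concentration of one labeled internal standard."""

    standard_id: str
    estimated_conc: float  # µM in the extraction context
    n_levels_used: int
    cv_across_levels: float

    def __post_init__(self) -> None:
        if not self.estimated_conc > 0:
            raise CalibrationError(
                f"{self.standard_id}: estimated concentration must be positive"
            )
        if self.n_levels_used < 1:
            raise CalibrationError(f"{self.standard_id}: no usable levels")


@dataclass
class CalibrationCurve:
    """OLS external-calibration line for one metabolite."""

    metabolite_id: str
    slope: float  # normalized-area per µM
    intercept: float
    r_squared: float
    levels_used: list[str]
    passes_qc: bool


@dataclass
class CalibrationModel:
    """Everything needed to convert biological peak areas to concentrations."""

    is_quants: dict[str, InternalStandardQuant]
    curves: dict[str, CalibrationCurve]
    lods: dict[str, float]  # µM per metabolite
    exclusions: dict[str, str]  # metabolite_id -> reason
    provenance: dict = field(default_factory=dict)

    def quant_path(self, metabolite_id: str, library: StandardsLibrary) -> str:
        """'isotope_dilution', 'external', or 'excluded' for one metabolite."""
        if metabolite_id in self.exclusions:
            return "excluded"
        entry = library[metabolite_id]
        if entry.quant_mode == "isotope_dilution":
            return "isotope_dilution" if entry.paired_standard_id in self.is_quants else "excluded"
        curve = self.curves.get(metabolite_id)
        return "external" if curve is not None and curve.passes_qc else "excluded"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "is_quants": {k: asdict(v) for k, v in self.is_quants.items()},
            "curves": {k: asdict(v) for k, v in self.curves.items()},
            "lods": self.lods,
            "exclusions": self.exclusions,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            is_quants={
                k: InternalStandardQuant(**v) for k, v in payload["is_quants"].items()
            },
            curves={k: CalibrationCurve(**v) for k, v in payload["curves"].items()},
            lods=payload["lods"],
            exclusions=payload["exclusions"],
            provenance=payload.get("provenance", {}),
        )


def _dilution_samples(sheet: SampleSheet, pool_id: str) -> dict[str, str]:
    """level tag -> sample_id for one pool's dilution injections."""
    frame = sheet.frame
    mask = frame["matrix_type"] == "standard_dilution"
    if "pool_id" in frame.columns:
        mask &= frame["pool_id"] == pool_id
    sub = frame.loc[mask]
    return dict(zip(sub["dilution_level"], sub["sample_id"]))


def estimate_is_concentration(
    pool_peaks: PeakTable,
    library: StandardsLibrary,
    dilution_sheet: SampleSheet,
) -> dict[str, InternalStandardQuant]:
    """Quantify each labeled internal standard against the pool dilutions.

    A dilution level is usable for metabolite m when both the unlabeled and
    the labeled area are present and the nominal concentration is at or above
    the metabolite's LOD.  Per-level estimates are combined by the median for
    robustness to a single saturated or censored level.
    """
    quants: dict[str, InternalStandardQuant] = {}
    for entry in library.by_mode("isotope_dilution"):
        by_level = _dilution_samples(dilution_sheet, entry.pool_id)
        estimates = []
        for level, nominal in entry.nominal_conc_by_level.items():
            sid = by_level.get(level)
            if sid is None or nominal < entry.lod:
                continue
            a_u = pool_peaks.area(sid, entry.metabolite_id)
            a_l = pool_peaks.area(sid, entry.paired_standard_id)
            if np.isnan(a_u) or np.isnan(a_l) or a_u <= 0:
                continue
            estimates.append(nominal * a_l / a_u)
        if not estimates:
            raise CalibrationError(
                f"no usable dilution level for internal standard "
                f"{entry.paired_standard_id!r} (metabolite {entry.metabolite_id})"
            )
        est = np.asarray(estimates)
        cv = float(est.std(ddof=1) / est.mean()) if len(est) > 1 else 0.0
        quants[entry.paired_standard_id] = InternalStandardQuant(
            standard_id=entry.paired_standard_id,
            estimated_conc=float(np.median(est)),
            n_levels_used=len(est),
            cv_across_levels=cv,
        )
    return quants


def fit_external_curve(
    pool_peaks: PeakTable,
    library: StandardsLibrary,
    dilution_sheet: SampleSheet,
    r2_gate: float = 0.95,
    min_levels: int = 3,
) -> tuple[dict[str, CalibrationCurve], dict[str, str]]:
    """Fit normalized-area vs concentration lines for external metabolites.

    Returns (curves, exclusions); a metabolite lands in ``exclusions`` when it
    has fewer than ``min_levels`` usable levels.  Curves failing the r² gate
    are kept with ``passes_qc=False`` so the exclusion is auditable.
    """
    if not 0 < r2_gate <= 1:
        raise ConfigError(f"r2_gate must be in (0, 1], got {r2_gate}")
    curves: dict[str, CalibrationCurve] = {}
    exclusions: dict[str, str] = {}
    for entry in library.by_mode("external_calibration"):
        by_level = _dilution_samples(dilution_sheet, entry.pool_id)
        xs, ys, levels = [], [], []
        for level, nominal in entry.nominal_conc_by_level.items():
            sid = by_level.get(level)
            if sid is None or nominal < entry.lod:
                continue
            a = pool_peaks.area(sid, entry.metabolite_id)
            a_norm = pool_peaks.area(sid, entry.paired_standard_id)
            if np.isnan(a) or np.isnan(a_norm) or a_norm <= 0:
                continue
            xs.append(nominal)
            ys.append(a / a_norm)
            levels.append(level)
        if len(xs) < min_levels:
            exclusions[entry.metabolite_id] = (
                f"insufficient usable levels ({len(xs)} < {min_levels})"
            )
            continue
        x, y = np.asarray(xs), np.asarray(ys)
        if np.allclose(y, y[0]):
            slope, intercept, r2 = 0.0, float(y[0]), 0.0
        else:
            fit = stats.linregress(x, y)
            slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
        curves[entry.metabolite_id] = CalibrationCurve(
            metabolite_id=entry.metabolite_id,
            slope=slope,
            intercept=intercept,
            r_squared=r2,
            levels_used=levels,
            passes_qc=(r2 >= r2_gate and len(levels) >= min_levels),
        )
    return curves, exclusions


def detection_threshold(blank_mean: float, blank_sd: float, k: float = 3.0) -> float:
    """Area threshold separating signal from blank: mean + k·SD."""
    return blank_mean + k * blank_sd


def estimate_lod(
    pool_peaks: PeakTable,
    blank_peaks: PeakTable | None,
    library: StandardsLibrary,
    dilution_sheet: SampleSheet,
    k: float = 3.0,
    use_library_lod: bool = True,
) -> dict[str, float]:
    """Limit of detection (µM) per metabolite.

    A library-provided LOD takes precedence (``use_library_lod``).  Otherwise
    the LOD is the lowest dilution level whose area exceeds blank mean + k·SD
    in every replicate injection of that level.
    """
    lods: dict[str, float] = {}
    for entry in library:
        if use_library_lod and entry.lod > 0:
            lods[entry.metabolite_id] = entry.lod
            continue
        if blank_peaks is None:
            raise ConfigError(
                f"{entry.metabolite_id}: no library LOD and no blank injections"
            )
        blanks = blank_peaks.areas_of(entry.metabolite_id).dropna()
        mean = float(blanks.mean()) if len(blanks) else 0.0
        sd = float(blanks.std(ddof=1)) if len(blanks) > 1 else 0.0
        threshold = detection_threshold(mean, sd, k)
        by_level = _dilution_samples(dilution_sheet, entry.pool_id)
        detected = [
            nominal
            for level, nominal in sorted(
                entry.nominal_conc_by_level.items(), key=lambda kv: kv[1]
            )
            if (sid := by_level.get(level)) is not None
            and pool_peaks.area(sid, entry.metabolite_id) > threshold
        ]
        if not detected:
            raise CalibrationError(f"{entry.metabolite_id}: never detected above blank")
        lods[entry.metabolite_id] = float(min(detected))
    return lods


def lowest_detected_level(
    levels_um: list[float], areas: list[float], threshold: float
) -> float:
    """LOD rule on explicit (concentration, area) pairs: lowest level above threshold."""
    detected = [c for c, a in zip(levels_um, areas) if a > threshold]
    if not detected:
        raise CalibrationError("no level detected above the blank threshold")
    return float(min(detected))


def matrix_effect_log2fc(
    water_peaks: PeakTable,
    plasma_peaks: PeakTable,
    direction: str = "water_over_plasma",
) -> pd.DataFrame:
    """Per-standard log2 fold change of mean peak area between matrices.

    Equal amounts of each labeled standard are spiked into water and plasma;
    a nonzero value is pure matrix effect.  ``direction`` fixes the numerator
    (default log2(water / plasma)).
    """
    if direction not in ("water_over_plasma", "plasma_over_water"):
        raise ConfigError(f"unknown direction {direction!r}")
    rows = []
    for species in water_peaks.species_ids:
        w = water_peaks.areas_of(species).dropna()
        p = plasma_peaks.areas_of(species).dropna()
        if not len(w) or not len(p):
            continue  # standard missing in one matrix: excluded
        fc = np.log2(w.mean() / p.mean())
        if direction == "plasma_over_water":
            fc = -fc
        rows.append(
            {
                "species_id": species,
                "log2_fold_change": float(fc),
                "n_water": int(len(w)),
                "n_plasma": int(len(p)),
            }
        )
    return pd.DataFrame(rows, columns=["species_id", "log2_fold_change", "n_water", "n_plasma"])


def build_calibration_model(
    pool_peaks: PeakTable,
    library: StandardsLibrary,
    dilution_sheet: SampleSheet,
    r2_gate: float = 0.95,
    min_levels: int = 3,
    blank_peaks: PeakTable | None = None,
    lod_k: float = 3.0,
    provenance: dict | None = None,
) -> CalibrationModel:
    """Run both calibration paths and assemble the full model."""
    is_quants = estimate_is_concentration(pool_peaks, library, dilution_sheet)
    curves, exclusions = fit_external_curve(
        pool_peaks, library, dilution_sheet, r2_gate=r2_gate, min_levels=min_levels
    )
    for mid, curve in curves.items():
        if not curve.passes_qc:
            exclusions[mid] = f"calibration curve failed QC (r²={curve.r_squared:.4f})"
    lods = estimate_lod(pool_peaks, blank_peaks, library, dilution_sheet, k=lod_k)
    return CalibrationModel(
        is_quants=is_quants,
        curves=curves,
        lods=lods,
        exclusions=exclusions,
        provenance=provenance or {},
    )
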