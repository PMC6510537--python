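"""Lactate dehydrogenase (LDH) activity from NADH A340 kinetic reads.

LDH converts pyruvate + NADH to lactate + NAD+; NADH absorbs at 340 nm, so
activity is read as the linear initial rate of A340 loss.  Activity in units
is assigned by inverting a standard curve of rate vs known LDH amounts, then
corrected for sample dilution.  The TIF-purity check compares total LDH
activity in the entire isolated TIF volume with the whole-tumor lysate total:
a small ratio means the fluid is interstitial, not spilled cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, ConfigError, ValidationError


@dataclass
class KineticTrace:
    """A340 vs time; times in seconds, strictly increasing, >= 5 points."""

    times: np.ndarray
    a340: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.times.shape != self.a340.shape or self.times.ndim != 1:
            raise ValidationError("times and a340 must be 1-D arrays of equal length")
        if len(self.times) < 5:
            raise ValidationError("a kinetic trace needs at least 5 points")
        if not (np.isfinite(self.times).all() and np.isfinite(self.a340).all()):
            raise ValidationError("trace contains non-finite values")
        if not (np.diff(self.times) > 0).all():
            raise ValidationError("times must be strictly increasing")


@dataclass
class SlopeFit:
    """Magnitude of the A340 consumption rate (ΔA340/min) and fit quality."""

    slope_per_min: float
    r_squared: float


def fit_kinetic_slope(
    trace: KineticTrace, window: tuple[float, float] | None = None
) -> SlopeFit:
    """OLS slope of A340 vs time, returned as a positive rate per minute.

    ``window`` restricts the fit to times (seconds) within [t0, t1]; the
    default uses the whole trace.
    """
    t, y = trace.times, trace.a340
    if window is not None:
        t0, t1 = window
        mask = (t >= t0) & (t <= t1)
        if mask.sum() < 5:
            raise ValidationError("window must contain at least 5 points")
        t, y = t[mask], y[mask]
    t_min = t / 60.0
    if np.allclose(y, y[0]):
        return SlopeFit(slope_per_min=0.0, r_squared=0.0)
    fit = stats.linregress(t_min, y)
    r2 = float(fit.rvalue**2)
    return SlopeFit(slope_per_min=abs(float(fit.slope)), r_squared=r2)


@dataclass
class LDHStandardCurve:
    """Fit of consumption rate (ΔA340/min) against known LDH activity (units)."""

    points: list[tuple[float, float]]  # (activity units, slope magnitude)
    slope: float  # ΔA340/min per unit
    intercept: float
    r_squared: float


#: the six standard activities (units) used by the reference assay
DEFAULT_STANDARD_ACTIVITIES = (0.0, 0.005838, 0.007783, 0.011675, 0.02335, 0.0467)


def fit_ldh_standard_curve(points: list[tuple[float, float]]) -> LDHStandardCurve:
    """OLS fit of rate vs activity over the standard points.

    Requires >= 3 points including a blank (activity 0) and >= 2 positive
    activities; a non-positive fitted slope means the curve carries no
    information and is an error.
    """
    if len(points) < 3:
        raise CalibrationError("standard curve needs at least 3 points")
    activities = np.array([p[0] for p in points], dtype=float)
    slopes = np.array([p[1] for p in points], dtype=float)
    if (activities == 0).sum() < 1 or (activities > 0).sum() < 2:
        raise CalibrationError(
            "standard curve needs a blank and at least 2 positive activities"
        )
    if np.allclose(slopes, slopes[0]):
        raise CalibrationError("uninformative standard curve (fitted slope is 0)")
    fit = stats.linregress(activities, slopes)
    if not np.isfinite(fit.slope) or fit.slope <= 0:
        raise CalibrationError("uninformative standard curve (fitted slope <= 0)")
    return LDHStandardCurve(
        points=[(float(a), float(s)) for a, s in points],
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def compute_ldh_activity(
    slope_per_min: float, curve: LDHStandardCurve, dilution_factor: float = 1.0
) -> float:
    """Invert the standard curve and correct for sample dilution.

    activity = ((rate - intercept) / curve slope) * dilution_factor; a
    slightly negative inversion (blank noise) is clipped to zero.
    """
    if dilution_factor < 1:
        raise ConfigError("dilution_factor must be >= 1")
    activity = (slope_per_min - curve.intercept) / curve.slope * dilution_factor
    if activity < 0:
        import warnings

        warnings.warn("negative LDH activity clipped to 0", stacklevel=2)
        return 0.0
    return float(activity)


def tif_tumor_ldh_ratio(
    tif_activity_per_volume: float,
    tif_volume_ul: float,
    tumor_lysate_activity_per_ml: float,
    tumor_mass_g: float,
    lysate_conc_mg_per_ml: float = 10.0,
) -> float:
    """Total LDH activity in the isolated TIF volume over the whole-tumor total.

    The tumor is homogenized and resuspended at ``lysate_conc_mg_per_ml``
    (default 10 mg/mL); the lysate's measured activity per mL is converted to
    activity per mg of tumor and scaled to the whole tumor mass.  A plasma
    comparison uses the same formula with an equal volume of plasma.
    """
    if tif_volume_ul <= 0 or tumor_mass_g <= 0 or lysate_conc_mg_per_ml <= 0:
        raise ConfigError("volumes, masses and lysate concentration must be positive")
    tumor_total = (
        tumor_lysate_activity_per_ml / lysate_conc_mg_per_ml * tumor_mass_g * 1000.0
    )
    if tumor_total <= 0:
        raise ValidationError("whole-tumor LDH total is zero; ratio undefined")
    return float(tif_activity_per_volume * tif_volume_ul / tumor_total)


def read_kinetic_trace(path) -> KineticTrace:
    """Two-column CSV (time_s, a340) -> KineticTrace."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"time_s", "a340"} <= set(df.columns):
        from .errors import SchemaError

        raise SchemaError("kinetic trace CSV needs columns time_s, a340")
    return KineticTrace(times=df["time_s"].to_numpy(), a340=df["a340"].to_numpy())
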