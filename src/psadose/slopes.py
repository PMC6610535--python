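"""Per-patient PSA slope: OLS rate of PSA change over time after radiotherapy.

The slope is computed over the serial post-treatment PSA measurements with
the last pre-treatment value (time <= 0) included as the anchor point, in
ng/ml per month.  A slope strictly greater than zero marks a rising PSA
("positive"); zero or falling is "nonpositive".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import StatError, pearson_r

__all__ = [
    "PsaSeries",
    "SlopeResult",
    "SlopeCohortSummary",
    "UndefinedSlopeError",
    "compute_psa_slope",
    "dichotomize_slope",
    "slope_cohort_summary",
    "slope_table",
]

POSITIVE = "positive"
NONPOSITIVE = "nonpositive"


class UndefinedSlopeError(ValueError):
    """Raised when a patient's slope cannot be computed."""

    def __init__(self, patient_id, reason: str):
        self.patient_id = patient_id
        super().__init__(f"slope undefined for patient {patient_id!r}: {reason}")


@dataclass(frozen=True)
class PsaSeries:
    """Time-stamped PSA measurements for one patient.

    Times are months relative to the start of radiotherapy (a non-positive
    time is a pre-treatment measurement); PSA in ng/ml, >= 0.
    """

    patient_id: str
    times: np.ndarray
    psa: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.psa, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and psa must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"patient {self.patient_id!r}: times must be strictly increasing"
            )
        if np.any(y < 0):
            raise ValueError(f"patient {self.patient_id!r}: PSA must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "psa", y)

    @classmethod
    def from_points(cls, patient_id, points: Iterable[tuple]) -> "PsaSeries":
        pts = sorted(points, key=lambda p: p[0])
        t = np.array([p[0] for p in pts], dtype=float)
        y = np.array([p[1] for p in pts], dtype=float)
        return cls(str(patient_id), t, y)

    def __len__(self) -> int:
        return int(self.times.size)

    def keep_last_pretreatment(self) -> "PsaSeries":
        """Drop all but the latest pre-treatment (time <= 0) measurement."""
        pre = self.times <= 0
        if pre.sum() <= 1:
            return self
        keep = ~pre
        keep[np.flatnonzero(pre)[-1]] = True
        return PsaSeries(self.patient_id, self.times[keep], self.psa[keep])


@dataclass(frozen=True)
class SlopeResult:
    patient_id: str
    slope: float  # ng/ml/month
    n_points: int
    sign: str  # POSITIVE | NONPOSITIVE

    def __post_init__(self):
        if self.sign != dichotomize_slope(self.slope):
            raise ValueError("sign inconsistent with slope value")


def compute_psa_slope(series: PsaSeries) -> SlopeResult:
    """Simple OLS slope of PSA vs. time for one patient.

    Multiple pre-treatment values are reduced to the latest one before the
    fit.  Requires >= 2 points at >= 2 distinct times.
    """
    s = series.keep_last_pretreatment()
    t, y = s.times, s.psa
    if t.size < 2:
        raise UndefinedSlopeError(series.patient_id, "fewer than 2 usable points")
    tc = t - t.mean()
    sxx = float(np.dot(tc, tc))
    if sxx == 0.0:
        raise UndefinedSlopeError(series.patient_id, "zero time variance")
    slope = float(np.dot(tc, y - y.mean()) / sxx)
    if not np.isfinite(slope):
        raise UndefinedSlopeError(series.patient_id, "non-finite slope")
    return SlopeResult(
        patient_id=s.patient_id,
        slope=slope,
        n_points=int(t.size),
        sign=dichotomize_slope(slope),
    )


def dichotomize_slope(slope: float) -> str:
    """positive iff slope > 0; zero and negative are nonpositive."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return POSITIVE if slope > 0 else NONPOSITIVE


@dataclass(frozen=True)
class SlopeCohortSummary:
    """Cohort-level slope counts and follow-up correlations."""

    n_negative: int           # slope strictly < 0
    n_nonnegative: int        # slope >= 0 (positive or exactly zero)
    r_followup_npoints: float
    p_followup_npoints: float
    r_followup_slope: float
    p_followup_slope: float


def slope_cohort_summary(
    results: Sequence[SlopeResult],
    followup_months: Mapping[str, float],
) -> SlopeCohortSummary:
    """Counts of falling vs non-falling PSA and follow-up correlations.

    ``followup_months`` maps patient_id to follow-up duration; patients
    missing from it are an error (the summary must cover one cohort).
    """
    if len(results) < 3:
        raise StatError("cohort summary needs at least 3 patients")
    slopes = np.array([r.slope for r in results])
    npts = np.array([r.n_points for r in results], dtype=float)
    try:
        fu = np.array([followup_months[r.patient_id] for r in results], dtype=float)
    except KeyError as exc:
        raise KeyError(f"follow-up missing for patient {exc.args[0]!r}") from exc
    r1 = pearson_r(fu, npts)
    r2 = pearson_r(fu, slopes)
    n_neg = int(np.sum(slopes < 0))
    return SlopeCohortSummary(
        n_negative=n_neg,
        n_nonnegative=int(slopes.size - n_neg),
        r_followup_npoints=r1.statistic,
        p_followup_npoints=r1.p_value,
        r_followup_slope=r2.statistic,
        p_followup_slope=r2.p_value,
    )


def slope_table(results: Sequence[SlopeResult]) -> pd.DataFrame:
    """Per-patient slope table for downstream modules and on-disk output."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "slope": [r.slope for r in results],
            "n_points": [r.n_points for r in results],
            "sign": [r.sign for r in results],
        }
    )
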