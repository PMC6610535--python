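"""Reading, validation and stratification of the patient-level tables.

Two delimited inputs drive the analysis: a patient table (one row per
patient: baseline PSA, Gleason score, clinical T stage, total radiation
dose, recurrence indicator and follow-up) and a long-format PSA trajectory
table (one row per measurement).  This module validates both, applies the
D'Amico risk stratification and the four-level total-dose grouping, and
builds the dose x risk frequency summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .slopes import PsaSeries

__all__ = [
    "PatientRecord",
    "RiskGroup",
    "DoseGroupScheme",
    "TrajectoryData",
    "SchemaError",
    "RowError",
    "T_STAGES",
    "DOSE_GROUP_LABELS",
    "PATIENT_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "read_patient_table",
    "write_patient_table",
    "read_psa_trajectories",
    "write_trajectory_table",
    "records_to_frame",
    "classify_damico",
    "assign_dose_group",
    "summarize_cohort",
    "format_cohort_summary",
]

T_STAGES = ("T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3", "T4")
_STAGE_INDEX = {s.lower(): i for i, s in enumerate(T_STAGES)}

DOSE_GROUP_LABELS = ("<50 Gy", "[50 70) Gy", "=70 Gy", "70< Gy")

PATIENT_COLUMNS = (
    "patient_id",
    "ipsa",
    "gleason",
    "t_stage",
    "total_dose",
    "followup_months",
    "recurrence",
    "time_to_event_months",
)
TRAJECTORY_COLUMNS = ("patient_id", "time_months", "psa")

# slack on time_to_event <= followup comparisons (rounding in source tables)
_TIME_TOL = 1e-6


class SchemaError(ValueError):
    """The table is missing a required column or has a malformed layout."""


class RowError(ValueError):
    """A specific row fails validation; carries the row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def stage_index(t_stage: str) -> int:
    """Ordinal position of a clinical T-stage label (case-insensitive)."""
    try:
        return _STAGE_INDEX[str(t_stage).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown T stage label: {t_stage!r}") from None


class RiskGroup:
    """D'Amico risk levels (exhaustive, exclusive)."""

    LOW = "Low"
    INTERMEDIATE = "Intermediate"
    HIGH = "High"
    LEVELS = (LOW, INTERMEDIATE, HIGH)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, dose, follow-up and event data."""

    patient_id: str
    ipsa: float                 # baseline PSA, ng/ml
    gleason: int                # 2..10
    t_stage: str                # T1a..T4
    total_dose: float           # Gy
    followup_months: float
    recurrence: bool
    time_to_event_months: float

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not (self.ipsa > 0):
            raise ValueError(f"iPSA must be > 0, got {self.ipsa}")
        if not (2 <= self.gleason <= 10):
            raise ValueError(f"Gleason score must be in [2, 10], got {self.gleason}")
        stage_index(self.t_stage)  # validates the label
        if not (self.total_dose > 0):
            raise ValueError(f"total dose must be > 0 Gy, got {self.total_dose}")
        if self.followup_months < 0:
            raise ValueError("follow-up must be >= 0 months")
        if not (self.time_to_event_months > 0):
            raise ValueError("time to event must be > 0 months")
        if self.time_to_event_months > self.followup_months + _TIME_TOL:
            raise ValueError(
                f"time to event ({self.time_to_event_months}) exceeds "
                f"follow-up ({self.followup_months})"
            )

    @property
    def risk_group(self) -> str:
        return classify_damico(self.ipsa, self.gleason, self.t_stage)


@dataclass(frozen=True)
class DoseGroupScheme:
    """Four total-dose bins: <50, [50, 70), =70 and >70 Gy.

    ``equality_tol`` absorbs rounding in recorded prescriptions around the
    nominal 70 Gy level; ``representative_doses`` feed the dose-distance
    factors of the Bayesian model.
    """

    low_cut: float = 50.0
    mid_cut: float = 70.0
    equality_tol: float = 0.005
    representative_doses: tuple = (45.0, 60.0, 70.0, 75.0)

    def __post_init__(self):
        if not all(
            a < b
            for a, b in zip(self.representative_doses, self.representative_doses[1:])
        ):
            raise ValueError("representative doses must be strictly increasing")


DEFAULT_DOSE_SCHEME = DoseGroupScheme()


def classify_damico(ipsa: float, gleason: int, t_stage: str) -> str:
    """D'Amico risk stratification from iPSA, Gleason score and T stage.

    High if iPSA > 20 OR Gleason >= 8 OR stage >= T2c; Low if iPSA <= 10
    AND Gleason <= 6 AND stage <= T2a; otherwise Intermediate.  High takes
    precedence where the published conditions overlap.
    """
    if not ipsa > 0:
        raise ValueError("iPSA must be positive")
    if not (2 <= gleason <= 10):
        raise ValueError("Gleason score out of range [2, 10]")
    si = stage_index(t_stage)
    if ipsa > 20 or gleason >= 8 or si >= stage_index("T2c"):
        return RiskGroup.HIGH
    if ipsa <= 10 and gleason <= 6 and si <= stage_index("T2a"):
        return RiskGroup.LOW
    return RiskGroup.INTERMEDIATE


def assign_dose_group(
    total_dose: float, scheme: DoseGroupScheme = DEFAULT_DOSE_SCHEME
) -> int:
    """Map a total dose in Gy to the group index 1..4.

    1: dose < 50; 2: 50 <= dose < 70; 3: dose == 70 (within
    ``scheme.equality_tol``); 4: dose > 70.
    """
    if not total_dose > 0:
        raise ValueError("total dose must be positive")
    if abs(total_dose - scheme.mid_cut) <= scheme.equality_tol:
        return 3
    if total_dose < scheme.low_cut:
        return 1
    if total_dose < scheme.mid_cut:
        return 2
    return 4


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    try:
        return bool(int(float(s)))
    except ValueError:
        raise RowError(row, f"unparseable boolean in column {column!r}: {value!r}")


def _resolve_columns(
    frame: pd.DataFrame, required: Sequence[str], column_map: Optional[Mapping[str, str]]
) -> pd.DataFrame:
    """Rename file columns to canonical names and check presence."""
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"missing required column: {col!r}")
    return frame


def read_patient_table(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[PatientRecord]:
    """Read and validate the one-row-per-patient table (CSV, header row).

    ``column_map`` maps canonical names to the file's column names, so
    externally produced tables only need a mapping, not a rewrite.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"patient table not found: {path}")
    frame = pd.read_csv(path, dtype={0: str})
    frame = _resolve_columns(frame, PATIENT_COLUMNS, column_map)
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        pid = str(row["patient_id"]).strip()
        if pid in seen:
            raise RowError(int(idx), f"duplicate patient_id {pid!r}")
        seen.add(pid)
        try:
            rec = PatientRecord(
                patient_id=pid,
                ipsa=float(row["ipsa"]),
                gleason=int(row["gleason"]),
                t_stage=str(row["t_stage"]).strip(),
                total_dose=float(row["total_dose"]),
                followup_months=float(row["followup_months"]),
                recurrence=_parse_bool(row["recurrence"], int(idx), "recurrence"),
                time_to_event_months=float(row["time_to_event_months"]),
            )
        except RowError:
            raise
        except (TypeError, ValueError) as exc:
            raise RowError(int(idx), str(exc)) from exc
        records.append(rec)
    return records


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "patient_id": r.patient_id,
            "ipsa": r.ipsa,
            "gleason": r.gleason,
            "t_stage": r.t_stage,
            "total_dose": r.total_dose,
            "followup_months": r.followup_months,
            "recurrence": int(r.recurrence),
            "time_to_event_months": r.time_to_event_months,
        }
        for r in records
    ])


def write_patient_table(records: Sequence[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


@dataclass
class TrajectoryData:
    """Per-patient PSA series plus validation flags.

    ``orphans`` lists trajectory patients absent from the patient table
    (kept, not dropped); ``short_series`` lists patients with fewer than two
    measurements, whose slope is undefined.
    """

    series: dict = field(default_factory=dict)
    orphans: list = field(default_factory=list)
    short_series: list = field(default_factory=list)


def read_psa_trajectories(
    path,
    known_patients: Optional[Sequence[str]] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> TrajectoryData:
    """Read the long-format PSA trajectory table into per-patient series.

    Series are sorted ascending by time; duplicate (patient, time) rows are
    rejected.  When ``known_patients`` is given, trajectory-only patients
    are reported in ``orphans`` rather than silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory table not found: {path}")
    frame = pd.read_csv(path, dtype={0: str})
    frame = _resolve_columns(frame, TRAJECTORY_COLUMNS, column_map)
    frame["patient_id"] = frame["patient_id"].astype(str).str.strip()

    dup = frame.duplicated(subset=["patient_id", "time_months"], keep=False)
    if dup.any():
        first = frame.loc[dup].iloc[0]
        raise RowError(
            int(frame.loc[dup].index[0]),
            f"duplicate measurement for patient {first['patient_id']!r} "
            f"at time {first['time_months']}",
        )

    out = TrajectoryData()
    for pid, grp in frame.groupby("patient_id", sort=False):
        grp = grp.sort_values("time_months")
        try:
            series = PsaSeries(
                pid,
                grp["time_months"].to_numpy(dtype=float),
                grp["psa"].to_numpy(dtype=float),
            )
        except ValueError as exc:
            raise RowError(int(grp.index[0]), str(exc)) from exc
        out.series[pid] = series
        if len(series) < 2:
            out.short_series.append(pid)
    if known_patients is not None:
        known = set(map(str, known_patients))
        out.orphans = [pid for pid in out.series if pid not in known]
    return out


def write_trajectory_table(series: Mapping[str, PsaSeries], path) -> None:
    rows = []
    for pid, s in series.items():
        for t, y in zip(s.times, s.psa):
            rows.append({"patient_id": pid, "time_months": t, "psa": y})
    pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS)).to_csv(path, index=False)


def summarize_cohort(
    records: Sequence[PatientRecord],
    scheme: DoseGroupScheme = DEFAULT_DOSE_SCHEME,
) -> pd.DataFrame:
    """Dose-group frequency distribution, overall and per D'Amico stratum.

    Returns a tidy frame with one row per (stratum, dose group): counts and
    row percentages (100 * count / stratum size, 2 decimals).  Strata with
    no patients are omitted.
    """
    if not records:
        raise ValueError("summarize_cohort needs a non-empty cohort")
    rows = []
    strata = [("All", records)] + [
        (level, [r for r in records if r.risk_group == level])
        for level in RiskGroup.LEVELS
    ]
    n_total = len(records)
    for name, members in strata:
        if not members:
            continue  # omitted stratum; rendering shows remaining rows only
        counts = np.zeros(4, dtype=int)
        for r in members:
            counts[assign_dose_group(r.total_dose, scheme) - 1] += 1
        n_row = counts.sum()
        for g, label in enumerate(DOSE_GROUP_LABELS):
            rows.append(
                {
                    "stratum": name,
                    "dose_group": label,
                    "count": int(counts[g]),
                    "pct": round(100.0 * counts[g] / n_row, 2),
                }
            )
        rows.append(
            {
                "stratum": name,
                "dose_group": "Total",
                "count": int(n_row),
                "pct": round(100.0 * n_row / n_total, 2),
            }
        )
    return pd.DataFrame(rows)


def format_cohort_summary(summary: pd.DataFrame) -> str:
    """Render the frequency summary as text; empty cells print as a dash."""
    lines = []
    header = ["Stratum"] + list(DOSE_GROUP_LABELS) + ["Total"]
    lines.append("\t".join(header))
    for stratum in summary["stratum"].unique():
        block = summary[summary["stratum"] == stratum].set_index("dose_group")
        cells = [str(stratum)]
        for label in DOSE_GROUP_LABELS:
            c = int(block.loc[label, "count"])
            cells.append("-" if c == 0 else f"{c} ({block.loc[label, 'pct']:.2f})")
        tot = block.loc["Total"]
        cells.append(f"{int(tot['count'])} ({tot['pct']:.2f})")
        lines.append("\t".join(cells))
    return "\n".join(lines)
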