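"""End-to-end orchestration and the four-criterion Prentice evaluation.

A surrogate endpoint (here: the post-radiotherapy PSA slope) stands in for
a true endpoint (prostate-cancer recurrence) only if it passes the four
Prentice conditions:

  I   treatment (total dose) predicts the true endpoint;
  II  treatment predicts the surrogate;
  III the surrogate predicts the true endpoint;
  IV  the surrogate captures the full treatment effect — once the
      surrogate is accounted for, dose carries no residual effect.

Criterion III is evaluated both with the slope dichotomized at zero
(log-rank by slope sign) and as a continuous variable (Mann-Whitney of
slope by recurrence status); the two can disagree, so the report always
carries both and a config switch selects which feeds the overall verdict.
Criterion IV combines the joint logistic model (dose must lose
significance while slope retains it) with dose log-rank tests inside each
slope-sign stratum (both must be non-significant).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bayes, io, slopes, stats, synthetic
from .io import DOSE_GROUP_LABELS, DoseGroupScheme, PatientRecord, assign_dose_group
from .slopes import NONPOSITIVE, POSITIVE, SlopeResult
from .stats import SeparationError, StatError, TestResult

__all__ = [
    "CriterionResult",
    "PrenticeReport",
    "evaluate_prentice",
    "combine_verdicts",
    "run_pipeline",
    "render_report",
    "load_config",
]

logger = logging.getLogger(__name__)

NOT_EVALUABLE = "not evaluable"


@dataclass(frozen=True)
class CriterionResult:
    """Verdict for one Prentice criterion with its supporting statistics."""

    name: str
    met: bool
    evaluable: bool
    tests: tuple = ()
    detail: str = ""

    def as_dict(self) -> dict:
        return {
            "criterion": self.name,
            "met": self.met,
            "evaluable": self.evaluable,
            "detail": self.detail,
            "tests": [t.as_dict() for t in self.tests],
        }


@dataclass(frozen=True)
class PrenticeReport:
    """Verdicts for criteria I-IV plus the overall surrogacy conclusion."""

    alpha: float
    criterion_1: CriterionResult
    criterion_2: CriterionResult
    criterion_3_dichotomized: CriterionResult
    criterion_3_continuous: CriterionResult
    criterion_4: CriterionResult
    criterion_3_form: str  # which form feeds the overall verdict
    overall_valid: bool
    n_patients: int
    excluded_patients: tuple = ()

    @property
    def criterion_3(self) -> CriterionResult:
        if self.criterion_3_form == "dichotomized":
            return self.criterion_3_dichotomized
        return self.criterion_3_continuous

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "criterion_1": self.criterion_1.as_dict(),
            "criterion_2": self.criterion_2.as_dict(),
            "criterion_3_dichotomized": self.criterion_3_dichotomized.as_dict(),
            "criterion_3_continuous": self.criterion_3_continuous.as_dict(),
            "criterion_4": self.criterion_4.as_dict(),
            "criterion_3_form": self.criterion_3_form,
            "overall_valid": self.overall_valid,
            "n_patients": self.n_patients,
            "excluded_patients": list(self.excluded_patients),
        }


def combine_verdicts(c1: bool, c2: bool, c3: bool, c4: bool) -> bool:
    """The surrogate is valid only if all four criteria are met."""
    return bool(c1) and bool(c2) and bool(c3) and bool(c4)


def _aligned_frame(
    records: Sequence[PatientRecord],
    slope_results: Sequence[SlopeResult],
    scheme: DoseGroupScheme,
) -> tuple[pd.DataFrame, list]:
    by_id = {r.patient_id: r for r in slope_results}
    rows, excluded = [], []
    for rec in records:
        sr = by_id.get(rec.patient_id)
        if sr is None:
            excluded.append(rec.patient_id)
            continue
        rows.append(
            {
                "patient_id": rec.patient_id,
                "dose": rec.total_dose,
                "dose_group": assign_dose_group(rec.total_dose, scheme),
                "slope": sr.slope,
                "sign": sr.sign,
                "event": rec.recurrence,
                "time": rec.time_to_event_months,
            }
        )
    if not rows:
        raise ValueError("no patients with both clinical data and a slope")
    return pd.DataFrame(rows), excluded


def _safe(testcall, name: str) -> tuple[Optional[TestResult], str]:
    try:
        return testcall(), ""
    except (StatError, ValueError) as exc:
        logger.warning("%s not evaluable: %s", name, exc)
        return None, str(exc)


def evaluate_prentice(
    records: Sequence[PatientRecord],
    slope_results: Sequence[SlopeResult],
    posterior: Optional[bayes.DoseResponsePosterior] = None,
    alpha: float = 0.05,
    criterion2_test: str = "anova",
    criterion3_form: str = "continuous",
    scheme: DoseGroupScheme = io.DEFAULT_DOSE_SCHEME,
) -> PrenticeReport:
    """Evaluate the four Prentice surrogacy criteria on one cohort.

    Sub-tests that cannot be computed (e.g. an event-free stratum) are
    flagged not-evaluable and count conservatively as "not met".
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if criterion2_test not in {"anova", "kruskal"}:
        raise ValueError("criterion2_test must be 'anova' or 'kruskal'")
    if criterion3_form not in {"continuous", "dichotomized"}:
        raise ValueError("criterion3_form must be 'continuous' or 'dichotomized'")
    df, excluded = _aligned_frame(records, slope_results, scheme)

    # --- criterion I: dose -> recurrence -------------------------------
    lr1, note1 = _safe(
        lambda: stats.log_rank_test(df["time"], df["event"], df["dose_group"]),
        "criterion I log-rank",
    )
    mw1, note1b = _safe(
        lambda: stats.mann_whitney(
            df.loc[df["event"], "dose"], df.loc[~df["event"], "dose"]
        ),
        "criterion I Mann-Whitney",
    )
    c1_tests = tuple(t for t in (lr1, mw1) if t is not None)
    c1_eval = lr1 is not None and mw1 is not None
    c1_met = c1_eval and lr1.p_value < alpha and mw1.p_value < alpha
    c1 = CriterionResult(
        name="I: dose predicts recurrence",
        met=c1_met,
        evaluable=c1_eval,
        tests=c1_tests,
        detail="; ".join(filter(None, [note1, note1b])),
    )

    # --- criterion II: dose -> slope -----------------------------------
    by_group = [
        df.loc[df["dose_group"] == g, "slope"].to_numpy() for g in range(1, 5)
    ]
    present = [g for g in by_group if g.size > 0]
    if criterion2_test == "anova":
        t2, note2 = _safe(lambda: stats.one_way_anova(present), "criterion II ANOVA")
    else:
        t2, note2 = _safe(
            lambda: stats.kruskal_wallis(present), "criterion II Kruskal-Wallis"
        )
    c2_tests = [t2] if t2 is not None else []
    detail2 = note2
    if posterior is not None:
        overlap = bayes.credible_overlap(posterior)
        n_overlap = int(overlap["overlap"].sum())
        detail2 = (
            f"{detail2}; " if detail2 else ""
        ) + f"95% credible intervals overlap in {n_overlap}/{len(overlap)} dose pairs"
    c2_met = t2 is not None and t2.p_value < alpha
    c2 = CriterionResult(
        name="II: dose predicts PSA slope",
        met=c2_met,
        evaluable=t2 is not None,
        tests=tuple(c2_tests),
        detail=detail2,
    )

    # --- criterion III: slope -> recurrence ----------------------------
    lr3, note3 = _safe(
        lambda: stats.log_rank_test(df["time"], df["event"], df["sign"]),
        "criterion III log-rank by slope sign",
    )
    c3d_met = lr3 is not None and lr3.p_value < alpha
    c3d = CriterionResult(
        name="III (dichotomized): slope sign predicts recurrence",
        met=c3d_met,
        evaluable=lr3 is not None,
        tests=(lr3,) if lr3 is not None else (),
        detail=note3,
    )
    mw3, note3c = _safe(
        lambda: stats.mann_whitney(
            df.loc[df["event"], "slope"], df.loc[~df["event"], "slope"]
        ),
        "criterion III Mann-Whitney",
    )
    c3c_met = mw3 is not None and mw3.p_value < alpha
    c3c = CriterionResult(
        name="III (continuous): slope predicts recurrence",
        met=c3c_met,
        evaluable=mw3 is not None,
        tests=(mw3,) if mw3 is not None else (),
        detail=note3c,
    )

    # --- criterion IV: slope captures the full dose effect -------------
    c4_tests: list[TestResult] = []
    notes4: list[str] = []
    try:
        fit = stats.logistic_fit(
            df["event"].to_numpy(),
            df[["dose", "slope"]],
        )
        dose_coef = fit.coef("dose")
        slope_coef = fit.coef("slope")
        c4_tests.append(
            TestResult("logistic dose", dose_coef.coef, dose_coef.p_value,
                       note=f"se={dose_coef.se:.4g}")
        )
        c4_tests.append(
            TestResult("logistic slope", slope_coef.coef, slope_coef.p_value,
                       note=f"se={slope_coef.se:.4g}")
        )
        logistic_ok = dose_coef.p_value >= alpha and slope_coef.p_value < alpha
    except (SeparationError, StatError) as exc:
        logger.warning("criterion IV logistic model not evaluable: %s", exc)
        notes4.append(f"logistic model: {exc}")
        logistic_ok = False

    strata_ok, strata_eval = True, True
    for sign in (NONPOSITIVE, POSITIVE):
        sub = df[df["sign"] == sign]
        name = f"stratified log-rank (slope {sign})"
        if sub["dose_group"].nunique() < 2 or not sub["event"].any():
            notes4.append(f"{name}: {NOT_EVALUABLE}")
            strata_eval = False
            continue
        lr, note = _safe(
            lambda s=sub: stats.log_rank_test(s["time"], s["event"], s["dose_group"]),
            name,
        )
        if lr is None:
            notes4.append(f"{name}: {note}")
            strata_eval = False
            continue
        c4_tests.append(dataclasses.replace(lr, name=name))
        if lr.p_value < alpha:
            strata_ok = False
    # a non-evaluable stratum is conservative: full capture is unproven
    c4_met = logistic_ok and strata_eval and strata_ok
    c4 = CriterionResult(
        name="IV: slope captures the full dose effect",
        met=c4_met,
        evaluable=strata_eval,
        tests=tuple(c4_tests),
        detail="; ".join(notes4),
    )

    c3_selected = c3d if criterion3_form == "dichotomized" else c3c
    overall = combine_verdicts(c1.met, c2.met, c3_selected.met, c4.met)
    return PrenticeReport(
        alpha=alpha,
        criterion_1=c1,
        criterion_2=c2,
        criterion_3_dichotomized=c3d,
        criterion_3_continuous=c3c,
        criterion_4=c4,
        criterion_3_form=criterion3_form,
        overall_valid=overall,
        n_patients=len(df),
        excluded_patients=tuple(excluded),
    )


# ----------------------------------------------------------------------
# end-to-end pipeline
# ----------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def _build_synthetic_config(block: Mapping, seed: Optional[int]) -> synthetic.SyntheticCohortConfig:
    kwargs = dict(block or {})
    if "recurrence_model" in kwargs and isinstance(kwargs["recurrence_model"], Mapping):
        kwargs["recurrence_model"] = synthetic.RecurrenceModel(**kwargs["recurrence_model"])
    for key in ("dose_group_probs", "representative_doses", "true_group_slope_means",
                "followup_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if seed is not None:
        kwargs["seed"] = seed
    return synthetic.default_config(**kwargs)


def run_pipeline(config: Mapping | str | Path, outdir, seed: Optional[int] = None):
    """Run read -> stratify -> slopes -> Bayes fit -> surrogacy, writing
    every artifact (tables, posterior, test results, report, log) to
    ``outdir``.  Returns the PrenticeReport.

    ``config`` is a mapping (or YAML path) with either a ``synthetic``
    block (generator parameters) or an ``inputs`` block naming the patient
    and trajectory CSVs, plus optional ``mcmc``, ``alpha``,
    ``criterion2_test``, ``criterion3_form`` keys.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("psadose")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    t_start = time.perf_counter()
    stage = "configure"
    try:
        # ---- stage: acquire cohort ----
        stage = "read"
        t0 = time.perf_counter()
        if "synthetic" in config or "inputs" not in config:
            syn_cfg = _build_synthetic_config(config.get("synthetic", {}), seed)
            records, series = synthetic.generate_records(syn_cfg)
            io.write_patient_table(records, outdir / "patients.csv")
            io.write_trajectory_table(series, outdir / "trajectories.csv")
            effective_seed = syn_cfg.seed
        else:
            inputs = config["inputs"]
            records = io.read_patient_table(
                inputs["patients"], column_map=inputs.get("patient_columns")
            )
            traj = io.read_psa_trajectories(
                inputs["trajectories"],
                known_patients=[r.patient_id for r in records],
                column_map=inputs.get("trajectory_columns"),
            )
            if traj.orphans:
                logger.warning(
                    "%d trajectory patients missing from patient table: %s",
                    len(traj.orphans), traj.orphans[:10],
                )
            series = traj.series
            effective_seed = seed
        logger.info("stage read: %d patients (%.2fs)", len(records),
                    time.perf_counter() - t0)

        # ---- stage: stratify ----
        stage = "stratify"
        scheme = DoseGroupScheme(**config.get("dose_scheme", {}))
        summary = io.summarize_cohort(records, scheme)
        summary.to_csv(outdir / "cohort_summary.csv", index=False)

        # ---- stage: slopes ----
        stage = "slopes"
        t0 = time.perf_counter()
        slope_results, skipped = [], []
        for rec in records:
            s = series.get(rec.patient_id)
            if s is None or len(s) < 2:
                skipped.append(rec.patient_id)
                continue
            try:
                slope_results.append(slopes.compute_psa_slope(s))
            except slopes.UndefinedSlopeError as exc:
                logger.warning("%s", exc)
                skipped.append(rec.patient_id)
        if skipped:
            logger.warning("slope undefined for %d patients: %s",
                           len(skipped), skipped[:10])
        slopes.slope_table(slope_results).to_csv(outdir / "slopes.csv", index=False)
        followup = {r.patient_id: r.followup_months for r in records}
        cohort_stats = slopes.slope_cohort_summary(slope_results, followup)
        logger.info("stage slopes: %d slopes, %d negative (%.2fs)",
                    len(slope_results), cohort_stats.n_negative,
                    time.perf_counter() - t0)

        # ---- stage: Bayes fit ----
        stage = "fit-bayes"
        t0 = time.perf_counter()
        slope_by_id = {r.patient_id: r.slope for r in slope_results}
        groups = [[] for _ in range(4)]
        for rec in records:
            if rec.patient_id in slope_by_id:
                g = assign_dose_group(rec.total_dose, scheme)
                groups[g - 1].append(slope_by_id[rec.patient_id])
        mcmc_kwargs = dict(config.get("mcmc", {}))
        if seed is not None and "seed" not in mcmc_kwargs:
            mcmc_kwargs["seed"] = seed
        mcmc = bayes.McmcConfig(**mcmc_kwargs)
        rep_doses = _representative_doses(records, scheme, slope_by_id)
        distances = bayes.build_distances(
            rep_doses, reference_dose=config.get("reference_dose", 0.0)
        )
        chains = bayes.gibbs_fit(groups, distances, config=mcmc)
        posterior = bayes.summarize_posterior(chains, dose_labels=DOSE_GROUP_LABELS)
        posterior.to_frame().to_csv(outdir / "posterior.csv", index=False)
        bayes.credible_overlap(posterior).to_csv(
            outdir / "credible_overlap.csv", index=False
        )
        logger.info("stage fit-bayes: %d chains x %d draws (%.2fs)",
                    mcmc.n_chains, mcmc.n_iterations, time.perf_counter() - t0)

        # ---- stage: surrogacy ----
        stage = "surrogacy"
        t0 = time.perf_counter()
        report = evaluate_prentice(
            records,
            slope_results,
            posterior=posterior,
            alpha=float(config.get("alpha", 0.05)),
            criterion2_test=config.get("criterion2_test", "anova"),
            criterion3_form=config.get("criterion3_form", "continuous"),
            scheme=scheme,
        )
        with open(outdir / "prentice.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        _write_test_table(report, outdir / "tests.csv")
        text = render_report(
            report, posterior=posterior, cohort_summary=summary,
            slope_summary=cohort_stats,
        )
        (outdir / "report.txt").write_text(text)
        with open(outdir / "run_config.json", "w") as fh:
            json.dump({"config": _jsonable(config), "seed": effective_seed}, fh,
                      indent=2, default=str)
        logger.info("stage surrogacy done (%.2fs); total %.2fs",
                    time.perf_counter() - t0, time.perf_counter() - t_start)
        return report
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _representative_doses(records, scheme, slope_by_id):
    """Mean observed dose per group; nominal fallback when degenerate."""
    doses = [[] for _ in range(4)]
    for rec in records:
        if rec.patient_id in slope_by_id:
            doses[assign_dose_group(rec.total_dose, scheme) - 1].append(rec.total_dose)
    means = [float(np.mean(d)) if d else np.nan for d in doses]
    if any(np.isnan(m) for m in means) or np.any(np.diff(means) <= 0):
        return scheme.representative_doses
    return tuple(means)


def _write_test_table(report: PrenticeReport, path) -> None:
    rows = []
    for crit in (
        report.criterion_1,
        report.criterion_2,
        report.criterion_3_dichotomized,
        report.criterion_3_continuous,
        report.criterion_4,
    ):
        for t in crit.tests:
            rows.append({"criterion": crit.name, **t.as_dict()})
    pd.DataFrame(rows).to_csv(path, index=False)


def render_report(
    report: PrenticeReport,
    posterior: Optional[bayes.DoseResponsePosterior] = None,
    cohort_summary: Optional[pd.DataFrame] = None,
    slope_summary=None,
) -> str:
    """Single human-readable document: cohort, posterior and verdict trail."""
    lines = ["PSA-slope dose-response surrogacy report", "=" * 42, ""]
    if cohort_summary is not None:
        lines += ["Cohort frequency distribution (dose x risk group)",
                  io.format_cohort_summary(cohort_summary), ""]
    if slope_summary is not None:
        lines += [
            "PSA slopes: "
            f"{slope_summary.n_negative} negative, "
            f"{slope_summary.n_nonnegative} zero/positive; "
            f"r(follow-up, #measurements) = {slope_summary.r_followup_npoints:.2f} "
            f"(p = {slope_summary.p_followup_npoints:.3g}); "
            f"r(follow-up, slope) = {slope_summary.r_followup_slope:.2f} "
            f"(p = {slope_summary.p_followup_slope:.3g})",
            "",
        ]
    if posterior is not None:
        lines += ["Posterior PSA-slope means by dose level (ng/ml/month)",
                  posterior.to_frame().to_string(index=False, float_format="%.4f"),
                  ""]
    lines += [f"Prentice criteria at alpha = {report.alpha} "
              "(no multiple-testing correction applied)", ""]
    for crit in (
        report.criterion_1,
        report.criterion_2,
        report.criterion_3_dichotomized,
        report.criterion_3_continuous,
        report.criterion_4,
    ):
        verdict = "MET" if crit.met else ("NOT MET" if crit.evaluable
                                          else "NOT EVALUABLE (counted not met)")
        lines.append(f"  {crit.name}: {verdict}")
        for t in crit.tests:
            df_txt = f", df={t.df:g}" if t.df is not None else ""
            note = f" [{t.note}]" if t.note else ""
            lines.append(
                f"    {t.name}: statistic={t.statistic:.4g}{df_txt}, "
                f"p={t.p_value:.4g}{note}"
            )
        if crit.detail:
            lines.append(f"    note: {crit.detail}")
    lines += [
        "",
        f"Overall (criterion III form: {report.criterion_3_form}): "
        + ("PSA slope is a valid surrogate for recurrence"
           if report.overall_valid
           else "PSA slope is NOT a reliable surrogate for recurrence"),
        f"Patients analyzed: {report.n_patients}"
        + (f" (excluded, no slope: {len(report.excluded_patients)})"
           if report.excluded_patients else ""),
    ]
    return "\n".join(lines)
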