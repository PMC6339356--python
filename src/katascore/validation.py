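"""Validation pipeline for the prognostic score on a patient cohort.

:class:`KatagiriValidation` is the modelling entry point: build it from a
list of patient records (or a frame in the CSV schema) and call
:meth:`~KatagiriValidation.fit` to obtain a :class:`ValidationResults`
holding the four standard analysis artifacts:

* cohort characteristics — counts and percentages per factor level;
* univariate screening — per-level Kaplan–Meier median survival with a
  per-factor log-rank p-value, patients missing a factor excluded from that
  factor's test only;
* multivariate Cox models — sex and ECOG performance status are fitted in
  separate models (plus a combined, non-canonical model), categorical
  covariates expanded against declared reference levels which report
  hazard ratio 1.000;
* risk-group validation — per risk group: n, median survival, survival
  percentages at 3/6/12/24 months, the overall 3-group log-rank p, and
  plotting-ready KM step coordinates.

No multiple-testing correction is applied; the number of tests performed is
recorded in the report footer instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import KatagiriResult, PatientRecord
from .scoring import classify_primary_growth, component_scores, recommend_fractionation
from .survival import (
    CoxPH,
    km_estimate,
    km_median,
    logrank_test,
    median_follow_up_survivors,
)

__all__ = [
    "FactorDefinition",
    "default_factors",
    "CovariateSpec",
    "default_covariate_specs",
    "filter_scorable",
    "characteristics_table",
    "univariate_analysis",
    "multivariate_analysis",
    "risk_group_validation",
    "KatagiriValidation",
    "ValidationResults",
]

RISK_ORDER = ("low", "intermediate", "high")


# ---------------------------------------------------------------------------
# Factor definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorDefinition:
    """A categorical analysis factor: ordered levels plus a mapper.

    ``mapper(record, score)`` returns one of ``levels`` or ``None``;
    unmappable patients are excluded from this factor's analyses only.
    """

    name: str
    levels: tuple
    mapper: Callable[[PatientRecord, Optional[KatagiriResult]], Optional[str]]

    def level_of(self, record, score=None) -> Optional[str]:
        return self.mapper(record, score)


def _lab_level(record, score):
    from .scoring import categorize_labs

    cat = categorize_labs(record.labs, record.rt_start)
    return None if cat == "undetermined" else cat


def _growth_level(record, score):
    if record.primary_site is None:
        return None
    return classify_primary_growth(record.primary_site)


def _lesion_level(record, score):
    if record.primary_site is None:
        return None
    if record.primary_site in ("lung", "breast", "prostate"):
        return record.primary_site
    return "others"


def default_factors() -> list:
    """The standard factor list for the characteristics and screening
    tables: demographics, performance status, tumour factors, labs, and the
    risk group itself."""
    def opt(attr, fmt=lambda v: v):
        return lambda r, s: None if getattr(r, attr) is None else fmt(getattr(r, attr))

    yn = lambda v: "yes" if v else "no"
    return [
        FactorDefinition("sex", ("male", "female"), opt("sex")),
        FactorDefinition(
            "age_band", ("<=64", ">=65"),
            opt("age_years", lambda a: "<=64" if a <= 64 else ">=65"),
        ),
        FactorDefinition(
            "kps_band", ("10-60", "70-80", "90-100"),
            opt("kps", lambda k: "10-60" if k <= 60 else ("70-80" if k <= 80 else "90-100")),
        ),
        FactorDefinition(
            "ecog_band", ("0-2", "3-4"),
            opt("ecog", lambda e: "0-2" if e <= 2 else "3-4"),
        ),
        FactorDefinition(
            "primary_lesion", ("lung", "breast", "prostate", "others"), _lesion_level
        ),
        FactorDefinition("growth", ("slow", "moderate", "rapid"), _growth_level),
        FactorDefinition(
            "visceral", ("none", "nodular", "disseminated"), opt("visceral")
        ),
        FactorDefinition("lab_category", ("normal", "abnormal", "critical"), _lab_level),
        FactorDefinition("prior_chemo", ("no", "yes"), opt("prior_chemo", yn)),
        FactorDefinition(
            "multiple_bone_mets", ("no", "yes"), opt("multiple_bone_mets", yn)
        ),
        FactorDefinition(
            "risk_group", RISK_ORDER,
            lambda r, s: s.risk_group if s is not None and s.scorable else None,
        ),
    ]


# ---------------------------------------------------------------------------
# Covariate specifications for the multivariate models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """A named Cox model: factors with their reference levels."""

    name: str
    factors: tuple          # of (factor_name, reference_level)
    canonical: bool = True


def default_covariate_specs() -> list:
    """Sex and ECOG are fitted separately (two canonical models); a
    combined model with both is also reported but marked non-canonical."""
    core = (
        ("kps_band", "90-100"),
        ("lab_category", "critical"),
        ("growth", "rapid"),
        ("visceral", "disseminated"),
    )
    return [
        CovariateSpec("with_ecog", (("ecog_band", "3-4"),) + core),
        CovariateSpec("with_sex", (("sex", "female"),) + core),
        CovariateSpec(
            "combined", (("sex", "female"), ("ecog_band", "3-4")) + core,
            canonical=False,
        ),
    ]


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------

def _score_all(records, vocabulary=None):
    return [component_scores(r, vocabulary) for r in records]


def build_score_frame(records, scores) -> pd.DataFrame:
    """One row per patient: component points, total, risk group,
    scorability, missing components and fractionation recommendation."""
    rows = []
    for record, score in zip(records, scores):
        rec = (
            recommend_fractionation(score.risk_group).schedule
            if score.scorable else None
        )
        rows.append({
            "patient_id": record.patient_id,
            "primary_pts": score.primary_pts,
            "visceral_pts": score.visceral_pts,
            "lab_pts": score.lab_pts,
            "ecog_pts": score.ecog_pts,
            "chemo_pts": score.chemo_pts,
            "multiplicity_pts": score.multiplicity_pts,
            "total": score.total,
            "risk_group": score.risk_group,
            "scorable": score.scorable,
            "missing_components": ";".join(score.missing_components),
            "recommendation": rec,
        })
    return pd.DataFrame(rows)


def filter_scorable(records, scores=None, vocabulary=None):
    """Split a cohort into scorable patients and an exclusion log.

    Returns ``(scorable_records, scorable_scores, exclusions)`` where each
    exclusion is ``(patient_id, missing_components)``.
    """
    if not records:
        raise ValueError("empty cohort")
    if scores is None:
        scores = _score_all(records, vocabulary)
    kept_r, kept_s, excluded = [], [], []
    for record, score in zip(records, scores):
        if score.scorable:
            kept_r.append(record)
            kept_s.append(score)
        else:
            excluded.append((record.patient_id, list(score.missing_components)))
    return kept_r, kept_s, excluded


def characteristics_table(records, factors, scores=None) -> pd.DataFrame:
    """Counts and percentages per factor level.

    Percentages use the full cohort as denominator, so levels of a factor
    with missing data sum to < 100%.  Zero-count levels are retained.
    """
    if scores is None:
        scores = _score_all(records)
    n = len(records)
    rows = []
    for factor in factors:
        counts = {level: 0 for level in factor.levels}
        for record, score in zip(records, scores):
            level = factor.level_of(record, score)
            if level is not None:
                counts[level] += 1
        for level in factor.levels:
            rows.append({
                "factor": factor.name,
                "level": level,
                "n": counts[level],
                "percent": round(100.0 * counts[level] / n, 1),
            })
    return pd.DataFrame(rows)


def univariate_analysis(records, factors, scores=None) -> pd.DataFrame:
    """Per-level KM median survival and per-factor log-rank p.

    Patients unmappable for a factor are excluded from that factor's test
    only.  A factor collapsing to fewer than two non-empty levels is
    flagged (``p`` is NaN) and no test is run.
    """
    if scores is None:
        scores = _score_all(records)
    rows = []
    for factor in factors:
        by_level = {level: ([], []) for level in factor.levels}
        for record, score in zip(records, scores):
            level = factor.level_of(record, score)
            if level is not None:
                by_level[level][0].append(record.survival_months)
                by_level[level][1].append(record.died)
        occupied = [lv for lv in factor.levels if by_level[lv][0]]
        if len(occupied) >= 2:
            result = logrank_test([by_level[lv] for lv in occupied])
            p = result.p_value
        else:
            p = math.nan
        for level in factor.levels:
            times, died = by_level[level]
            if times:
                med = km_median(km_estimate(times, died))
            else:
                med = None
            rows.append({
                "factor": factor.name,
                "level": level,
                "n": len(times),
                "median_months": med,
                "median_rounded": None if med is None else int(round(med)),
                "p": p,
            })
    return pd.DataFrame(rows)


def _design_matrix(records, scores, factors_by_name, spec):
    """Dummy-expand the spec's factors against their reference levels on
    listwise-complete patients."""
    levels = []
    for record, score in zip(records, scores):
        row = {}
        for fname, _ref in spec.factors:
            row[fname] = factors_by_name[fname].level_of(record, score)
        levels.append(row)
    complete = [
        i for i, row in enumerate(levels) if all(v is not None for v in row.values())
    ]
    columns, names = [], []
    for fname, ref in spec.factors:
        factor = factors_by_name[fname]
        if ref not in factor.levels:
            raise ValueError(f"reference level {ref!r} not a level of {fname!r}")
        for level in factor.levels:
            if level == ref:
                continue
            names.append(f"{fname}[{level}]")
            columns.append([1.0 if levels[i][fname] == level else 0.0 for i in complete])
    X = np.array(columns, dtype=float).T
    durations = np.array([records[i].survival_months for i in complete])
    died = np.array([records[i].died for i in complete])
    return X, names, durations, died, complete


def multivariate_analysis(
    records, factors=None, specs=None, scores=None, ties="breslow"
) -> dict:
    """Fit the configured Cox models; returns ``{spec name: result dict}``.

    Each result dict carries the fitted :class:`~katascore.survival.CoxPHResults`
    (``fit``), a display table with explicit reference rows (HR 1.000, no
    CI), the listwise-complete n, and any diagnostic that prevented a fit
    (rank deficiency or suspected separation) instead of coefficients.
    """
    factors = default_factors() if factors is None else factors
    specs = default_covariate_specs() if specs is None else specs
    if scores is None:
        scores = _score_all(records)
    factors_by_name = {f.name: f for f in factors}
    out = {}
    for spec in specs:
        X, names, durations, died, complete = _design_matrix(
            records, scores, factors_by_name, spec
        )
        entry = {
            "spec": spec,
            "n": len(complete),
            "events": int(died.sum()),
            "fit": None,
            "table": None,
            "diagnostic": None,
        }
        try:
            fit = CoxPH(durations, died, X, names=names, ties=ties).fit()
        except (ValueError, np.linalg.LinAlgError) as exc:
            entry["diagnostic"] = str(exc)
            out[spec.name] = entry
            continue
        if fit.separation_suspected:
            entry["diagnostic"] = "monotone likelihood (possible perfect separation)"
        entry["fit"] = fit
        frame = fit.summary_frame()
        rows = []
        for fname, ref in spec.factors:
            for level in factors_by_name[fname].levels:
                if level == ref:
                    rows.append({
                        "model": spec.name, "factor": fname, "level": level,
                        "HR": 1.0, "hr_lower95": math.nan,
                        "hr_upper95": math.nan, "p": math.nan,
                        "reference": True,
                    })
                else:
                    key = f"{fname}[{level}]"
                    rows.append({
                        "model": spec.name, "factor": fname, "level": level,
                        "HR": float(frame.loc[key, "HR"]),
                        "hr_lower95": float(frame.loc[key, "hr_lower95"]),
                        "hr_upper95": float(frame.loc[key, "hr_upper95"]),
                        "p": float(frame.loc[key, "p"]),
                        "reference": False,
                    })
        entry["table"] = pd.DataFrame(rows)
        out[spec.name] = entry
    return out


def risk_group_validation(
    records, scores=None, timepoints=(3.0, 6.0, 12.0, 24.0)
) -> dict:
    """Risk-group survival validation on a scorable cohort.

    Returns a dict with the per-group table (n, median, survival
    percentages at the requested timepoints), the overall log-rank result,
    and KM step coordinates per group for plotting.
    """
    if scores is None:
        scores = _score_all(records)
    by_group = {g: ([], []) for g in RISK_ORDER}
    for record, score in zip(records, scores):
        if score.scorable:
            by_group[score.risk_group][0].append(record.survival_months)
            by_group[score.risk_group][1].append(record.died)

    rows, km_rows, absent = [], [], []
    for group in RISK_ORDER:
        times, died = by_group[group]
        if not times:
            absent.append(group)
            rows.append({
                "group": group, "n": 0, "median_months": None,
                "median_rounded": None,
                **{f"surv_{int(t)}m": math.nan for t in timepoints},
            })
            continue
        curve = km_estimate(times, died)
        med = km_median(curve)
        row = {
            "group": group,
            "n": len(times),
            "median_months": med,
            "median_rounded": None if med is None else int(round(med)),
        }
        for t in timepoints:
            s = curve.survival_at(t)
            row[f"surv_{int(t)}m"] = round(100.0 * s, 1) if not math.isnan(s) else math.nan
        rows.append(row)
        km_rows.append({"group": group, "time": 0.0, "survival": 1.0,
                        "at_risk": curve.n})
        for t, s, r_ in zip(curve.event_times, curve.survival, curve.at_risk):
            km_rows.append({
                "group": group, "time": float(t), "survival": float(s),
                "at_risk": int(r_),
            })

    occupied = [g for g in RISK_ORDER if by_group[g][0]]
    if len(occupied) >= 2:
        lr = logrank_test([by_group[g] for g in occupied])
        p, chi2, df = lr.p_value, lr.chi_square, lr.degrees_of_freedom
    else:
        p = chi2 = math.nan
        df = 0
    return {
        "table": pd.DataFrame(rows),
        "km_curves": pd.DataFrame(km_rows),
        "logrank_p": p,
        "logrank_chi2": chi2,
        "logrank_df": df,
        "absent_groups": absent,
    }


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class KatagiriValidation:
    """End-to-end validation model for a cohort of patient records."""

    def __init__(
        self,
        records: Sequence[PatientRecord],
        factors=None,
        covariate_specs=None,
        timepoints=(3.0, 6.0, 12.0, 24.0),
        vocabulary=None,
        ties: str = "breslow",
    ):
        if not records:
            raise ValueError("empty cohort")
        self.records = list(records)
        self.factors = default_factors() if factors is None else list(factors)
        self.covariate_specs = (
            default_covariate_specs() if covariate_specs is None
            else list(covariate_specs)
        )
        self.timepoints = tuple(float(t) for t in timepoints)
        self.vocabulary = vocabulary
        self.ties = ties

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "KatagiriValidation":
        from .io import frame_to_records

        return cls(frame_to_records(df), **kwargs)

    def fit(self) -> "ValidationResults":
        scores = _score_all(self.records, self.vocabulary)
        scorable_r, scorable_s, exclusions = filter_scorable(self.records, scores)
        table2 = characteristics_table(scorable_r, self.factors, scorable_s)
        table3 = univariate_analysis(scorable_r, self.factors, scorable_s)
        table4 = multivariate_analysis(
            scorable_r, self.factors, self.covariate_specs, scorable_s, self.ties
        )
        rgv = risk_group_validation(scorable_r, scorable_s, self.timepoints)
        durations = [r.survival_months for r in self.records]
        died = [r.died for r in self.records]
        try:
            follow_up = median_follow_up_survivors(durations, died)
        except ValueError:
            follow_up = None
        n_tests = int(table3["p"].notna().sum()) + 1  # + risk-group log-rank
        return ValidationResults(
            model=self,
            scores=scores,
            n_total=len(self.records),
            n_scorable=len(scorable_r),
            exclusions=exclusions,
            table2=table2,
            table3=table3,
            table4=table4,
            risk_validation=rgv,
            median_follow_up_survivors=follow_up,
            n_tests=n_tests,
        )


@dataclass
class ValidationResults:
    """Analysis artifacts of one validation run."""

    model: KatagiriValidation
    scores: list
    n_total: int
    n_scorable: int
    exclusions: list
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: dict
    risk_validation: dict
    median_follow_up_survivors: Optional[float]
    n_tests: int

    @property
    def table5(self) -> pd.DataFrame:
        return self.risk_validation["table"]

    @property
    def km_curves(self) -> pd.DataFrame:
        return self.risk_validation["km_curves"]

    @property
    def logrank_p(self) -> float:
        return self.risk_validation["logrank_p"]

    def score_frame(self) -> pd.DataFrame:
        """Per-patient score table (see :func:`build_score_frame`)."""
        return build_score_frame(self.model.records, self.scores)

    def multivariate_frame(self) -> pd.DataFrame:
        frames = [e["table"] for e in self.table4.values() if e["table"] is not None]
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    def to_report_dict(self) -> dict:
        def df_records(df):
            return json.loads(df.to_json(orient="records"))

        table4 = {}
        for name, entry in self.table4.items():
            table4[name] = {
                "canonical": entry["spec"].canonical,
                "n": entry["n"],
                "events": entry["events"],
                "diagnostic": entry["diagnostic"],
                "rows": df_records(entry["table"]) if entry["table"] is not None else None,
            }
        return {
            "n_total": self.n_total,
            "n_scorable": self.n_scorable,
            "exclusions": [
                {"patient_id": pid, "missing_components": mc}
                for pid, mc in self.exclusions
            ],
            "median_follow_up_survivors": self.median_follow_up_survivors,
            "characteristics": df_records(self.table2),
            "univariate": df_records(self.table3),
            "multivariate": table4,
            "risk_groups": df_records(self.table5),
            "logrank_p": self.logrank_p,
            "logrank_chi2": self.risk_validation["logrank_chi2"],
            "logrank_df": self.risk_validation["logrank_df"],
            "n_tests_performed": self.n_tests,
        }

    def write(self, out_dir) -> list:
        """Write table2..table5.csv, km_curves.csv and report.json.

        Deterministic: rerunning on identical inputs produces byte-identical
        files.  Returns the list of paths written.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []

        def emit_csv(df, name):
            p = out / name
            df.to_csv(p, index=False)
            paths.append(p)

        emit_csv(self.table2, "table2.csv")
        emit_csv(self.table3, "table3.csv")
        emit_csv(self.multivariate_frame(), "table4.csv")
        emit_csv(self.table5, "table5.csv")
        emit_csv(self.km_curves, "km_curves.csv")
        report = out / "report.json"
        report.write_text(
            json.dumps(self.to_report_dict(), indent=2, sort_keys=True) + "\n"
        )
        paths.append(report)
        return paths

    def summary(self) -> str:
        lines = [
            "Prognostic-score validation",
            f"patients: {self.n_total} total, {self.n_scorable} scorable "
            f"({len(self.exclusions)} excluded for missing components)",
        ]
        if self.median_follow_up_survivors is not None:
            lines.append(
                "median follow-up of survivors: "
                f"{self.median_follow_up_survivors:.1f} months"
            )
        lines.append("")
        lines.append("Risk-group validation:")
        lines.append(self.table5.to_string(index=False))
        p = self.logrank_p
        lines.append(
            "3-group log-rank: chi2 = "
            f"{self.risk_validation['logrank_chi2']:.2f}, "
            f"df = {self.risk_validation['logrank_df']}, "
            + ("p < 0.001" if p < 0.001 else f"p = {p:.3f}")
        )
        lines.append(f"[{self.n_tests} hypothesis tests performed; no "
                     "multiplicity correction applied]")
        return "\n".join(lines)
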