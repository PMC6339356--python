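"""Seeded synthetic cohort generator.

No patient-level data accompany the published validation study, so the
pipeline is exercised on synthetic cohorts whose *marginal* structure is
calibrated to the published summary tables:

* each risk group's survival follows a piecewise-exponential distribution
  with knots at the 3/6/12/24-month reporting times, whose segment hazards
  reproduce the published group survival percentages exactly
  (:func:`calibrate_piecewise_hazards`);
* replica modes draw the published group sizes (18 low / 133 intermediate /
  205 high), decode each patient's component scores into concrete covariate
  values that re-score to the intended risk group, and apply administrative
  censoring with a per-patient horizon uniform on 24-137 months;
* ``replica_entire`` adds the non-scorable patients (260 of 616: 244 with a
  missing laboratory panel, 16 with labs but missing visceral status);
* ``covariate_effect`` mode draws covariates independently at the published
  validation-cohort frequencies and event times from a proportional-hazards
  model with the published multivariate hazard ratios, for parameter-recovery
  studies.

The joint covariate distribution within risk groups is unpublished; the
score-combination decoding samples uniformly over the component
combinations compatible with each group, which is a stand-in, not an
estimate of the real joint distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import COLUMNS as _CSV_COLUMNS
from .records import LAB_ANALYTES

__all__ = [
    "HazardSegments",
    "CohortConfig",
    "calibrate_piecewise_hazards",
    "analytic_median",
    "simulate_cohort",
    "GROUP_PROFILES",
    "TABLE4_HAZARD_RATIOS",
    "VALIDATION_FREQUENCIES",
]

# Published survival percentages at 3/6/12/24 months per risk group and the
# low-risk tail median (months) that pins down the hazard beyond 24 months.
GROUP_PROFILES = {
    "low": (94.4, 77.8, 61.1, 55.6),
    "intermediate": (67.7, 48.7, 31.2, 16.0),
    "high": (39.1, 22.1, 9.0, 3.0),
}
ENTIRE_COHORT_PROFILE = (57.7, 40.5, 23.4, 12.2)
LOW_RISK_TAIL_MEDIAN = 27.0

#: Published multivariate hazard ratios (reference level = 1.0 implicitly).
TABLE4_HAZARD_RATIOS = {
    "sex": {"male": 0.479, "female": 1.0},
    "kps_band": {"10-60": 1.796, "70-80": 1.479, "90-100": 1.0},
    "ecog_band": {"0-2": 0.690, "3-4": 1.0},
    "lab_category": {"normal": 0.312, "abnormal": 0.697, "critical": 1.0},
    "growth": {"slow": 0.278, "moderate": 0.708, "rapid": 1.0},
    "visceral": {"none": 0.428, "nodular": 0.753, "disseminated": 1.0},
}

#: Validation-cohort covariate frequencies (proportions of n=356).
VALIDATION_FREQUENCIES = {
    "sex": {"male": 225 / 356, "female": 131 / 356},
    "age_band": {"<=64": 174 / 356, ">=65": 182 / 356},
    "kps_band": {"10-60": 188 / 356, "70-80": 100 / 356, "90-100": 66 / 356},
    "ecog_band": {"0-2": 201 / 356, "3-4": 155 / 356},
    "lab_category": {"normal": 32 / 356, "abnormal": 232 / 356, "critical": 92 / 356},
    "growth": {"slow": 44 / 356, "moderate": 44 / 356, "rapid": 268 / 356},
    "visceral": {"none": 42 / 356, "nodular": 248 / 356, "disseminated": 66 / 356},
    "prior_chemo": {"no": 146 / 356, "yes": 210 / 356},
    "multiple_bone_mets": {"no": 86 / 356, "yes": 270 / 356},
}


# ---------------------------------------------------------------------------
# Piecewise-exponential survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardSegments:
    """Piecewise-constant hazard; the last segment extends to infinity.

    ``breakpoints`` has one more entry than ``hazards`` and starts at 0;
    the implied survival S(t) = exp(-integral of the hazard) is continuous,
    strictly decreasing and S(0) = 1.
    """

    breakpoints: tuple      # (0, t1, ..., tk); last finite knot
    hazards: tuple          # per-month rates, one per segment incl. tail

    def __post_init__(self):
        b = np.asarray(self.breakpoints, dtype=float)
        h = np.asarray(self.hazards, dtype=float)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("breakpoints must start at 0 and increase")
        if h.size != b.size or np.any(h <= 0):
            raise ValueError("need one positive hazard per segment incl. tail")

    def _grid(self):
        b = np.asarray(self.breakpoints, dtype=float)
        h = np.asarray(self.hazards, dtype=float)
        # cumulative hazard at each breakpoint
        ch = np.concatenate([[0.0], np.cumsum(h[:-1] * np.diff(b))])
        return b, h, ch

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        b, h, ch = self._grid()
        idx = np.clip(np.searchsorted(b, t, side="right") - 1, 0, b.size - 1)
        return ch[idx] + h[idx] * (t - b[idx])

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))

    def quantile(self, u):
        """t such that S(t) = u, by inverting the piecewise-linear
        cumulative hazard."""
        u = np.asarray(u, dtype=float)
        target = -np.log(u)
        b, h, ch = self._grid()
        idx = np.clip(np.searchsorted(ch, target, side="right") - 1, 0, b.size - 1)
        return b[idx] + (target - ch[idx]) / h[idx]

    def median(self) -> float:
        return float(self.quantile(0.5))

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Inverse-transform sample of n event times."""
        return np.asarray(self.quantile(rng.uniform(size=n)), dtype=float)


def calibrate_piecewise_hazards(
    profile_percent: Sequence[float],
    times: Sequence[float] = (3.0, 6.0, 12.0, 24.0),
    tail_median: Optional[float] = None,
) -> HazardSegments:
    """Solve segment hazards so S(t) matches a survival profile exactly.

    ``profile_percent`` gives survival percentages at ``times`` (strictly
    decreasing, in (0, 100]).  Each segment hazard is
    ``ln(S(t_{i-1})/S(t_i)) / (t_i - t_{i-1})``.  The tail hazard beyond the
    last knot either continues the last segment's hazard or, when
    ``tail_median`` is given (required if S(last) > 50%), is solved so that
    S(tail_median) = 0.5.
    """
    s = np.asarray(profile_percent, dtype=float) / 100.0
    t = np.asarray(times, dtype=float)
    if s.size != t.size or np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be positive and increasing, one per value")
    if np.any(s <= 0) or np.any(s > 1) or np.any(np.diff(s) >= 0):
        raise ValueError("profile must be strictly decreasing within (0, 100]")
    s_full = np.concatenate([[1.0], s])
    t_full = np.concatenate([[0.0], t])
    hazards = np.log(s_full[:-1] / s_full[1:]) / np.diff(t_full)
    if s[-1] > 0.5 and tail_median is None:
        raise ValueError(
            "S at the last knot exceeds 50%: a tail_median is required to "
            "pin down the tail hazard"
        )
    if tail_median is not None:
        if s[-1] <= 0.5:
            raise ValueError("tail_median given but the median lies inside the profile")
        if tail_median <= t[-1]:
            raise ValueError("tail_median must exceed the last knot")
        tail = math.log(s[-1] / 0.5) / (tail_median - t[-1])
    else:
        tail = hazards[-1]
    return HazardSegments(
        breakpoints=tuple(t_full), hazards=tuple(hazards) + (float(tail),)
    )


def analytic_median(segments: HazardSegments) -> float:
    """Exact t solving S(t) = 0.5, per-segment closed form."""
    return segments.median()


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Calibration of the synthetic generator; ``seed`` is mandatory."""

    seed: int
    mode: str = "replica_validation"   # replica_validation | replica_entire | covariate_effect
    group_sizes: dict = field(
        default_factory=lambda: {"low": 18, "intermediate": 133, "high": 205}
    )
    profiles: dict = field(default_factory=lambda: dict(GROUP_PROFILES))
    tail_median_low: float = LOW_RISK_TAIL_MEDIAN
    report_times: tuple = (3.0, 6.0, 12.0, 24.0)
    censor_horizon: tuple = (24.0, 137.0)
    covariate_freqs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in VALIDATION_FREQUENCIES.items()}
    )
    effect_hrs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE4_HAZARD_RATIOS.items()}
    )
    baseline_hazard: float = math.log(2.0) / 2.0  # reference-patient median 2 mo
    n_patients: int = 5000                        # covariate_effect mode only
    entire_total: int = 616
    missing_labs: int = 244
    missing_visceral: int = 16
    rt_start: str = "2010-01-01"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.mode not in ("replica_validation", "replica_entire", "covariate_effect"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        scorable = sum(self.group_sizes.values())
        extra = self.missing_labs + self.missing_visceral
        if self.mode == "replica_entire" and scorable + extra != self.entire_total:
            raise ValueError(
                "group sizes + missing-component patients must total "
                f"{self.entire_total}"
            )

    def group_segments(self, group: str) -> HazardSegments:
        tail = self.tail_median_low if group == "low" else None
        return calibrate_piecewise_hazards(
            self.profiles[group], self.report_times, tail_median=tail
        )


# ---------------------------------------------------------------------------
# Score-combination decoding
# ---------------------------------------------------------------------------

_COMPONENT_LEVELS = ((0, 2, 3), (0, 1, 2), (0, 1, 2), (0, 1), (0, 1), (0, 1))

_GROUP_RANGES = {"low": (0, 3), "intermediate": (4, 6), "high": (7, 10)}


def _combinations_by_group() -> dict:
    combos = {g: [] for g in _GROUP_RANGES}
    for combo in itertools.product(*_COMPONENT_LEVELS):
        total = sum(combo)
        for g, (lo, hi) in _GROUP_RANGES.items():
            if lo <= total <= hi:
                combos[g].append(combo)
    return combos


_SITES_BY_GROWTH = {
    "slow": (
        ("breast", 0.55), ("prostate", 0.30), ("thyroid", 0.07),
        ("multiple_myeloma", 0.05), ("lymphoma", 0.03),
    ),
    "moderate": (
        ("renal_cell", 0.50), ("sarcoma", 0.20), ("ovarian", 0.12),
        ("endometrial", 0.08), ("other", 0.10),
    ),
    "rapid": (
        ("lung", 0.61), ("colorectal", 0.09), ("hepatocellular", 0.08),
        ("gastric", 0.06), ("pancreatic", 0.06), ("head_and_neck", 0.05),
        ("esophageal", 0.05),
    ),
}

_GROWTH_BY_PTS = {0: "slow", 2: "moderate", 3: "rapid"}
_VISCERAL_BY_PTS = {0: "none", 1: "nodular", 2: "disseminated"}

# Concrete analyte values realising each laboratory category; one marker of
# the tier is pushed across its threshold, the rest stay normal.
_NORMAL_LABS = {
    "crp": 0.1, "ldh": 180.0, "albumin": 4.2,
    "platelets": 250_000.0, "calcium": 9.2, "bilirubin": 0.6,
}
_ABNORMAL_MARKERS = (("crp", 1.5), ("ldh", 320.0), ("albumin", 3.2))
_CRITICAL_MARKERS = (("platelets", 60_000.0), ("calcium", 10.9), ("bilirubin", 2.2))


def _choice(rng, items):
    """Weighted choice over (value, weight) pairs (weights renormalised)."""
    values = [v for v, _ in items]
    w = np.array([p for _, p in items], dtype=float)
    return values[rng.choice(len(values), p=w / w.sum())]


def _freq_choice(rng, freq: dict):
    return _choice(rng, tuple(freq.items()))


def _decode_labs(rng, lab_pts: int) -> dict:
    labs = dict(_NORMAL_LABS)
    if lab_pts == 1:
        name, value = _ABNORMAL_MARKERS[rng.integers(len(_ABNORMAL_MARKERS))]
        labs[name] = value
    elif lab_pts == 2:
        name, value = _CRITICAL_MARKERS[rng.integers(len(_CRITICAL_MARKERS))]
        labs[name] = value
    return labs


def _decode_ecog(rng, ecog_pts: int) -> int:
    if ecog_pts == 0:
        return int(_choice(rng, ((0, 0.2), (1, 0.4), (2, 0.4))))
    return int(_choice(rng, ((3, 0.7), (4, 0.3))))


def _kps_value(rng, band: str) -> int:
    steps = {
        "10-60": (10, 20, 30, 40, 50, 60),
        "70-80": (70, 80),
        "90-100": (90, 100),
    }[band]
    return int(steps[rng.integers(len(steps))])


def _age_value(rng, band: str) -> int:
    lo, hi = (30, 64) if band == "<=64" else (65, 88)
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _base_row(cfg, rng, pid: int) -> dict:
    freqs = cfg.covariate_freqs
    rt = pd.Timestamp(cfg.rt_start)
    return {
        "patient_id": f"P{pid:05d}",
        "sex": _freq_choice(rng, freqs["sex"]),
        "age_years": _age_value(rng, _freq_choice(rng, freqs["age_band"])),
        "kps": _kps_value(rng, _freq_choice(rng, freqs["kps_band"])),
        "lab_date": (rt - pd.Timedelta(days=14)).date().isoformat(),
        "rt_start": rt.date().isoformat(),
    }


def _censor(cfg, rng, event_time: float) -> tuple[float, str]:
    lo, hi = cfg.censor_horizon
    horizon = rng.uniform(lo, hi)
    if event_time <= horizon:
        return float(event_time), "died"
    return float(horizon), "censored"


def _replica_rows(cfg: CohortConfig, rng: np.random.Generator) -> list:
    combos = _combinations_by_group()
    rows = []
    pid = 1
    for group in ("low", "intermediate", "high"):
        segments = cfg.group_segments(group)
        n = cfg.group_sizes[group]
        event_times = segments.draw(rng, n)
        group_combos = combos[group]
        for i in range(n):
            combo = group_combos[rng.integers(len(group_combos))]
            primary_pts, visceral_pts, lab_pts, ecog_pts, chemo_pts, mult_pts = combo
            row = _base_row(cfg, rng, pid)
            growth = _GROWTH_BY_PTS[primary_pts]
            row["primary_site"] = _choice(rng, _SITES_BY_GROWTH[growth])
            row["visceral"] = _VISCERAL_BY_PTS[visceral_pts]
            row["ecog"] = _decode_ecog(rng, ecog_pts)
            row["prior_chemo"] = "yes" if chemo_pts else "no"
            row["multiple_bone_mets"] = "yes" if mult_pts else "no"
            row.update(_decode_labs(rng, lab_pts))
            row["survival_months"], row["event"] = _censor(
                cfg, rng, event_times[i]
            )
            rows.append(row)
            pid += 1
    return rows


def _entire_extra_rows(cfg: CohortConfig, rng: np.random.Generator, start_pid: int) -> list:
    """Non-scorable patients: missing lab panel first, then visceral status."""
    segments = calibrate_piecewise_hazards(ENTIRE_COHORT_PROFILE, cfg.report_times)
    n = cfg.missing_labs + cfg.missing_visceral
    event_times = segments.draw(rng, n)
    freqs = cfg.covariate_freqs
    rows = []
    for i in range(n):
        pid = start_pid + i
        row = _base_row(cfg, rng, pid)
        growth = _freq_choice(rng, freqs["growth"])
        row["primary_site"] = _choice(rng, _SITES_BY_GROWTH[growth])
        row["ecog"] = _decode_ecog(
            rng, 0 if _freq_choice(rng, freqs["ecog_band"]) == "0-2" else 1
        )
        row["prior_chemo"] = _freq_choice(rng, freqs["prior_chemo"])
        row["multiple_bone_mets"] = _freq_choice(rng, freqs["multiple_bone_mets"])
        if i < cfg.missing_labs:
            row["visceral"] = _freq_choice(rng, freqs["visceral"])
            for analyte in LAB_ANALYTES:
                row[analyte] = None
            row["lab_date"] = None
        else:
            row["visceral"] = None
            cat = _freq_choice(rng, freqs["lab_category"])
            row.update(_decode_labs(rng, {"normal": 0, "abnormal": 1, "critical": 2}[cat]))
        row["survival_months"], row["event"] = _censor(cfg, rng, event_times[i])
        rows.append(row)
    return rows


def _covariate_effect_rows(cfg: CohortConfig, rng: np.random.Generator) -> list:
    freqs = cfg.covariate_freqs
    hrs = cfg.effect_hrs
    rows = []
    for pid in range(1, cfg.n_patients + 1):
        row = _base_row(cfg, rng, pid)
        growth = _freq_choice(rng, freqs["growth"])
        lab_cat = _freq_choice(rng, freqs["lab_category"])
        ecog_band = _freq_choice(rng, freqs["ecog_band"])
        kps_band = "10-60" if row["kps"] <= 60 else ("70-80" if row["kps"] <= 80 else "90-100")
        row["primary_site"] = _choice(rng, _SITES_BY_GROWTH[growth])
        row["visceral"] = _freq_choice(rng, freqs["visceral"])
        row["ecog"] = _decode_ecog(rng, 0 if ecog_band == "0-2" else 1)
        row["prior_chemo"] = _freq_choice(rng, freqs["prior_chemo"])
        row["multiple_bone_mets"] = _freq_choice(rng, freqs["multiple_bone_mets"])
        row.update(
            _decode_labs(rng, {"normal": 0, "abnormal": 1, "critical": 2}[lab_cat])
        )
        rate = cfg.baseline_hazard * (
            hrs["sex"][row["sex"]]
            * hrs["kps_band"][kps_band]
            * hrs["ecog_band"][ecog_band]
            * hrs["lab_category"][lab_cat]
            * hrs["growth"][growth]
            * hrs["visceral"][row["visceral"]]
        )
        event_time = rng.exponential(1.0 / rate)
        row["survival_months"], row["event"] = _censor(cfg, rng, event_time)
        rows.append(row)
    return rows


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a synthetic cohort as a pipeline-ready patient table.

    The returned frame uses the documented CSV schema; re-running with the
    same configuration and seed reproduces the table exactly.
    """
    rng = np.random.default_rng(config.seed)
    if config.mode in ("replica_validation", "replica_entire"):
        rows = _replica_rows(config, rng)
        if config.mode == "replica_entire":
            rows += _entire_extra_rows(config, rng, start_pid=len(rows) + 1)
    else:
        rows = _covariate_effect_rows(config, rng)
    df = pd.DataFrame(rows)
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            df[col] = None
    return df[_CSV_COLUMNS]
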