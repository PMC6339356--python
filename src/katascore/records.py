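"""Patient-level data model for the bone-metastases prognostic score.

One :class:`PatientRecord` holds everything the score and the survival
analyses need for a single patient: demographics, performance status,
primary-tumour site, visceral/cerebral metastasis status, a six-analyte
laboratory panel with measurement dates, prior-chemotherapy and
skeletal-multiplicity flags, the radiotherapy start date, and the survival
outcome measured from that start date.

Missing values are represented as ``None`` throughout — an absent analyte is
*missing*, never zero — because missingness drives scorability downstream.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "LabPanel",
    "PatientRecord",
    "KatagiriResult",
    "Recommendation",
    "LAB_ANALYTES",
    "EVENT_DIED",
    "EVENT_CENSORED",
]

#: The six analytes of the laboratory component, in canonical order.
LAB_ANALYTES = ("crp", "ldh", "albumin", "platelets", "calcium", "bilirubin")

EVENT_DIED = "died"
EVENT_CENSORED = "censored"

_VISCERAL_LEVELS = ("none", "nodular", "disseminated")
_KPS_LEVELS = tuple(range(10, 101, 10))


@dataclass
class LabPanel:
    """Six-analyte laboratory panel with optional per-analyte dates.

    Units follow clinical convention: CRP mg/dL, LDH IU/L, albumin g/dL,
    platelets counts per microlitre (absolute, not thousands), calcium mg/dL,
    total bilirubin mg/dL. ``measured_on`` maps analyte name to the date the
    value was drawn; analytes without a date fall back to ``panel_date``.
    """

    crp: Optional[float] = None
    ldh: Optional[float] = None
    albumin: Optional[float] = None
    platelets: Optional[float] = None
    calcium: Optional[float] = None
    bilirubin: Optional[float] = None
    panel_date: Optional[_dt.date] = None
    measured_on: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in LAB_ANALYTES:
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")

    def value(self, analyte: str) -> Optional[float]:
        if analyte not in LAB_ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}")
        return getattr(self, analyte)

    def date_of(self, analyte: str) -> Optional[_dt.date]:
        return self.measured_on.get(analyte, self.panel_date)


@dataclass
class PatientRecord:
    """One patient's covariates, lab panel, RT start and survival outcome.

    ``survival_months`` is measured from the start of radiotherapy until
    death or censoring; ``event`` is ``"died"`` or ``"censored"``.
    """

    patient_id: str
    survival_months: float
    event: str
    sex: Optional[str] = None            # "male" / "female"
    age_years: Optional[int] = None
    kps: Optional[int] = None            # 10..100 step 10
    ecog: Optional[int] = None           # 0..4
    primary_site: Optional[str] = None
    visceral: Optional[str] = None       # none / nodular / disseminated
    prior_chemo: Optional[bool] = None
    multiple_bone_mets: Optional[bool] = None
    labs: LabPanel = field(default_factory=LabPanel)
    rt_start: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if self.survival_months < 0:
            raise ValueError("survival_months must be >= 0")
        if self.event not in (EVENT_DIED, EVENT_CENSORED):
            raise ValueError(f"event must be 'died' or 'censored', got {self.event!r}")
        if self.kps is not None and self.kps not in _KPS_LEVELS:
            raise ValueError(f"kps must be one of {_KPS_LEVELS}, got {self.kps!r}")
        if self.ecog is not None and not 0 <= self.ecog <= 4:
            raise ValueError(f"ecog must be in 0..4, got {self.ecog!r}")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.visceral is not None and self.visceral not in _VISCERAL_LEVELS:
            raise ValueError(
                f"visceral must be one of {_VISCERAL_LEVELS}, got {self.visceral!r}"
            )

    @property
    def died(self) -> bool:
        return self.event == EVENT_DIED


@dataclass
class KatagiriResult:
    """Component points, total (0-10) and risk group for one patient.

    When any of the six components cannot be resolved (missing covariate or
    an ``undetermined`` laboratory category) the patient is not scorable:
    ``total`` and ``risk_group`` are ``None`` and ``missing_components``
    names the unresolved components.
    """

    primary_pts: Optional[int] = None        # 0 / 2 / 3
    visceral_pts: Optional[int] = None       # 0 / 1 / 2
    lab_pts: Optional[int] = None            # 0 / 1 / 2
    ecog_pts: Optional[int] = None           # 0 / 1
    chemo_pts: Optional[int] = None          # 0 / 1
    multiplicity_pts: Optional[int] = None   # 0 / 1
    total: Optional[int] = None
    risk_group: Optional[str] = None         # low / intermediate / high
    scorable: bool = False
    missing_components: list = field(default_factory=list)

    COMPONENTS = (
        "primary_pts",
        "visceral_pts",
        "lab_pts",
        "ecog_pts",
        "chemo_pts",
        "multiplicity_pts",
    )

    def component_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in self.COMPONENTS)


@dataclass
class Recommendation:
    """Fractionation guidance derived from the risk group."""

    risk_group: str
    schedule: str                 # "single-fraction" / "multi-fraction"
    example_regimens: tuple
    caveat: str
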