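"""Modified Katagiri prognostic score for bone metastases.

The score sums six components — primary-tumour growth class, visceral or
cerebral metastasis status, laboratory category, ECOG performance status,
previous chemotherapy and skeletal-metastasis multiplicity — into a total of
0-10 points, stratified into low- (0-3), intermediate- (4-6) and high-risk
(7-10) groups.  The modification relative to the original score collapses
all lung cancers into the rapid-growth class and all breast and prostate
cancers into the slow-growth class, dropping the targeted-agent and
hormone-sensitivity subclassifications.

Laboratory categorisation uses two tiers: *abnormal* markers (CRP >= 0.4
mg/dL, LDH >= 250 IU/L, albumin < 3.7 g/dL) score 1 point and *critical*
markers (platelets < 100,000/uL, albumin-corrected calcium >= 10.3 mg/dL,
total bilirubin >= 1.4 mg/dL) score 2; the worst tier crossed dominates.
Only measurements dated within two months (61 days) before the start of
radiotherapy are eligible.  A panel with no crossing but at least one
missing analyte is *undetermined* and makes the patient non-scorable.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources
from typing import Optional

from .records import (
    LAB_ANALYTES,
    KatagiriResult,
    LabPanel,
    PatientRecord,
    Recommendation,
)

__all__ = [
    "corrected_calcium",
    "categorize_labs",
    "classify_primary_growth",
    "component_scores",
    "total_score",
    "assign_risk_group",
    "recommend_fractionation",
    "load_site_vocabulary",
    "score_patient",
    "SiteClassificationError",
    "NotScorableError",
    "LAB_WINDOW_DAYS",
    "RISK_GROUPS",
]

#: Lab measurements older than this many days before RT start are ignored.
LAB_WINDOW_DAYS = 61

RISK_GROUPS = ("low", "intermediate", "high")

# Threshold crossings per tier: (analyte, predicate)
_ABNORMAL_RULES = (
    ("crp", lambda v: v >= 0.4),
    ("ldh", lambda v: v >= 250.0),
    ("albumin", lambda v: v < 3.7),
)
_CRITICAL_RULES = (
    ("platelets", lambda v: v < 100_000.0),
    ("calcium", lambda v: v >= 10.3),      # after albumin correction
    ("bilirubin", lambda v: v >= 1.4),
)

_PRIMARY_POINTS = {"slow": 0, "moderate": 2, "rapid": 3}
_VISCERAL_POINTS = {"none": 0, "nodular": 1, "disseminated": 2}
_LAB_POINTS = {"normal": 0, "abnormal": 1, "critical": 2}


class SiteClassificationError(KeyError):
    """Raised for a primary-site code outside the controlled vocabulary."""


class NotScorableError(ValueError):
    """Raised when a total is requested for a non-scorable result."""


def load_site_vocabulary(path=None) -> dict:
    """Load the site-code -> growth-class mapping.

    With no argument the packaged default vocabulary is used; pass a path to
    a two-column tab-separated file (``site<TAB>class``, ``#`` comments) to
    override or extend it.
    """
    if path is None:
        text = (
            resources.files("katascore").joinpath("data/site_growth.tsv").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    vocab = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        site, growth = line.split("\t")
        growth = growth.strip()
        if growth not in _PRIMARY_POINTS:
            raise ValueError(f"invalid growth class {growth!r} for site {site!r}")
        vocab[site.strip()] = growth
    return vocab


_DEFAULT_VOCAB = None


def _default_vocab() -> dict:
    global _DEFAULT_VOCAB
    if _DEFAULT_VOCAB is None:
        _DEFAULT_VOCAB = load_site_vocabulary()
    return _DEFAULT_VOCAB


def corrected_calcium(
    calcium: float, albumin: Optional[float]
) -> tuple[float, bool]:
    """Albumin-corrected serum calcium (Payne formula), mg/dL.

    ``corrected = measured + 0.8 * (4.0 - albumin)`` applied only when
    albumin < 4.0 g/dL, so the corrected value is never below the measured
    one.  Returns ``(value, corrected_flag)``; with albumin missing the
    measured calcium is returned uncorrected (flag ``False``).
    """
    if calcium is None or calcium <= 0:
        raise ValueError("calcium must be present and > 0")
    if albumin is None:
        return calcium, False
    if albumin <= 0:
        raise ValueError("albumin must be > 0 when present")
    if albumin < 4.0:
        return calcium + 0.8 * (4.0 - albumin), True
    return calcium, True


def _windowed_panel(panel: LabPanel, rt_start: Optional[_dt.date]) -> dict:
    """Analyte values restricted to the two-month pre-RT validity window.

    Values dated outside ``[rt_start - 61 d, rt_start]`` are treated as
    missing.  Undated values are kept only when no RT date is available to
    check them against (dates are then the caller's responsibility).
    """
    out = {}
    for name in LAB_ANALYTES:
        value = panel.value(name)
        if value is None:
            out[name] = None
            continue
        when = panel.date_of(name)
        if rt_start is not None and when is not None:
            age = (rt_start - when).days
            if age < 0 or age > LAB_WINDOW_DAYS:
                value = None
        out[name] = value
    return out


def categorize_labs(
    panel: LabPanel, rt_start: Optional[_dt.date] = None
) -> str:
    """Categorise the panel as normal / abnormal / critical / undetermined.

    Critical-tier crossings dominate abnormal-tier ones.  ``normal``
    requires all six analytes present (within the validity window) and
    within limits; otherwise, with no crossing, the category is
    ``undetermined`` — a valid answer that makes the score non-scorable.
    """
    values = _windowed_panel(panel, rt_start)
    if values["calcium"] is not None:
        values["calcium"], _ = corrected_calcium(
            values["calcium"], values["albumin"]
        )
    for name, crossed in _CRITICAL_RULES:
        if values[name] is not None and crossed(values[name]):
            return "critical"
    for name, crossed in _ABNORMAL_RULES:
        if values[name] is not None and crossed(values[name]):
            return "abnormal"
    if all(values[name] is not None for name in LAB_ANALYTES):
        return "normal"
    return "undetermined"


def classify_primary_growth(primary_site: str, vocabulary: Optional[dict] = None) -> str:
    """Growth class (slow / moderate / rapid) of a primary-site code.

    Unrecognised codes raise :class:`SiteClassificationError`: mapping an
    unlisted site to ``"other"`` (moderate) is a deliberate caller decision,
    never silent.
    """
    vocab = _default_vocab() if vocabulary is None else vocabulary
    try:
        return vocab[primary_site]
    except KeyError:
        raise SiteClassificationError(
            f"unrecognised primary site {primary_site!r}; map it to 'other' "
            "explicitly or extend the site vocabulary"
        ) from None


def component_scores(
    record: PatientRecord, vocabulary: Optional[dict] = None
) -> KatagiriResult:
    """Resolve the six score components for one patient.

    Absent covariates and an undetermined laboratory category are listed in
    ``missing_components``; the patient is scorable iff all six components
    resolve.  ``total`` and ``risk_group`` are filled in when scorable.
    """
    result = KatagiriResult()
    missing = []

    if record.primary_site is None:
        missing.append("primary")
    else:
        growth = classify_primary_growth(record.primary_site, vocabulary)
        result.primary_pts = _PRIMARY_POINTS[growth]

    if record.visceral is None:
        missing.append("visceral")
    else:
        result.visceral_pts = _VISCERAL_POINTS[record.visceral]

    lab_cat = categorize_labs(record.labs, record.rt_start)
    if lab_cat == "undetermined":
        missing.append("labs")
    else:
        result.lab_pts = _LAB_POINTS[lab_cat]

    if record.ecog is None:
        missing.append("ecog")
    else:
        result.ecog_pts = 0 if record.ecog <= 2 else 1

    if record.prior_chemo is None:
        missing.append("chemo")
    else:
        result.chemo_pts = 1 if record.prior_chemo else 0

    if record.multiple_bone_mets is None:
        missing.append("multiplicity")
    else:
        result.multiplicity_pts = 1 if record.multiple_bone_mets else 0

    result.missing_components = missing
    result.scorable = not missing
    if result.scorable:
        result.total = total_score(result)
        result.risk_group = assign_risk_group(result.total)
    return result


def total_score(result: KatagiriResult) -> int:
    """Sum of the six component points; defined only for scorable results."""
    components = result.component_tuple()
    if any(c is None for c in components):
        raise NotScorableError(
            f"not scorable; missing components: {result.missing_components}"
        )
    total = int(sum(components))
    if not 0 <= total <= 10:
        raise ValueError(f"total score {total} outside [0, 10]")
    return total


def assign_risk_group(total: int) -> str:
    """Risk stratum of a total score: 0-3 low, 4-6 intermediate, 7-10 high."""
    if not 0 <= total <= 10:
        raise ValueError(f"total score must be in [0, 10], got {total!r}")
    if total <= 3:
        return "low"
    if total <= 6:
        return "intermediate"
    return "high"


_CAVEAT = (
    "Schedule choice should also weigh patient preference and the priority "
    "of systemic therapy."
)


def recommend_fractionation(risk_group: str) -> Recommendation:
    """Palliative RT fractionation guidance for a risk group.

    High-risk patients (expected survival of a few months) are steered to
    single-fraction schedules for pain or cord-compression management;
    low- and intermediate-risk patients to multi-fraction schedules.
    """
    if risk_group not in RISK_GROUPS:
        raise ValueError(f"unknown risk group {risk_group!r}")
    if risk_group == "high":
        return Recommendation(
            risk_group=risk_group,
            schedule="single-fraction",
            example_regimens=("8 Gy x 1",),
            caveat=_CAVEAT,
        )
    return Recommendation(
        risk_group=risk_group,
        schedule="multi-fraction",
        example_regimens=("20 Gy / 5 fx", "30 Gy / 10 fx"),
        caveat=_CAVEAT,
    )


def score_patient(
    record: PatientRecord, vocabulary: Optional[dict] = None
) -> KatagiriResult:
    """Convenience wrapper: component resolution + total + risk group."""
    return component_scores(record, vocabulary)
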