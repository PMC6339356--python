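"""Scoring module: lab categorisation, growth classes, points, strata."""

import datetime
import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from katascore.records import KatagiriResult, LabPanel
from katascore.scoring import (
    NotScorableError,
    SiteClassificationError,
    assign_risk_group,
    categorize_labs,
    classify_primary_growth,
    component_scores,
    corrected_calcium,
    load_site_vocabulary,
    recommend_fractionation,
    total_score,
)

from conftest import LAB_DATE, NORMAL_LABS, RT_START, make_record


class TestCorrectedCalcium:
    @pytest.mark.parametrize(
        "calcium, albumin, expected",
        [
            (10.0, 4.0, 10.0),   # zero correction at the 4.0 g/dL pivot
            (9.0, 3.0, 9.8),     # 9.0 + 0.8 * 1.0
            (9.5, 2.5, 10.7),    # 9.5 + 0.8 * 1.5, crosses the 10.3 threshold
            (9.0, 4.5, 9.0),     # no downward correction above the pivot
        ],
    )
    def test_payne_formula(self, calcium, albumin, expected):
        value, corrected = corrected_calcium(calcium, albumin)
        assert value == pytest.approx(expected)
        assert corrected

    def test_missing_albumin_returns_measured_uncorrected(self):
        value, corrected = corrected_calcium(9.7, None)
        assert value == 9.7
        assert not corrected

    @given(st.floats(min_value=5.0, max_value=13.0))
    def test_identity_at_pivot(self, calcium):
        assert corrected_calcium(calcium, 4.0)[0] == calcium

    @given(
        st.floats(min_value=5.0, max_value=13.0),
        st.floats(min_value=1.0, max_value=6.0),
    )
    def test_never_below_measured(self, calcium, albumin):
        assert corrected_calcium(calcium, albumin)[0] >= calcium


def panel(**overrides):
    values = dict(NORMAL_LABS)
    values.update(overrides)
    return LabPanel(panel_date=LAB_DATE, **values)


class TestLabCategorisation:
    def test_all_normal(self):
        assert categorize_labs(panel(), RT_START) == "normal"

    @pytest.mark.parametrize(
        "overrides",
        [dict(crp=1.2), dict(crp=0.4), dict(ldh=250.0), dict(albumin=3.6)],
    )
    def test_abnormal_tier(self, overrides):
        assert categorize_labs(panel(**overrides), RT_START) == "abnormal"

    @pytest.mark.parametrize(
        "overrides",
        [
            dict(platelets=80_000.0, crp=5.0),  # critical dominates abnormal
            dict(platelets=99_999.0),
            dict(calcium=10.3),
            dict(bilirubin=1.4),
        ],
    )
    def test_critical_tier(self, overrides):
        assert categorize_labs(panel(**overrides), RT_START) == "critical"

    def test_calcium_compared_after_albumin_correction(self):
        # measured 9.9 below threshold; corrected 9.9 + 0.8*1.5 = 11.1 above
        assert categorize_labs(panel(calcium=9.9, albumin=2.5), RT_START) == "critical"

    def test_undetermined_when_no_crossing_but_missing_analyte(self):
        p = LabPanel(crp=0.1, panel_date=LAB_DATE)
        assert categorize_labs(p, RT_START) == "undetermined"

    def test_crossing_beats_missingness(self):
        p = LabPanel(crp=2.0, panel_date=LAB_DATE)
        assert categorize_labs(p, RT_START) == "abnormal"

    def test_stale_measurements_are_missing(self):
        old = RT_START - datetime.timedelta(days=90)
        assert categorize_labs(panel(), RT_START) == "normal"
        assert (
            categorize_labs(LabPanel(panel_date=old, **NORMAL_LABS), RT_START)
            == "undetermined"
        )

    def test_future_measurements_are_missing(self):
        after = RT_START + datetime.timedelta(days=5)
        p = LabPanel(panel_date=after, **NORMAL_LABS)
        assert categorize_labs(p, RT_START) == "undetermined"

    def test_idempotent_and_date_agnostic_within_window(self):
        p = panel(ldh=500.0)
        first = categorize_labs(p, RT_START)
        assert first == categorize_labs(p, RT_START) == "abnormal"


class TestGrowthClassification:
    @pytest.mark.parametrize(
        "site, expected",
        [
            ("breast", "slow"),
            ("prostate", "slow"),
            ("thyroid", "slow"),
            ("multiple_myeloma", "slow"),
            ("renal_cell", "moderate"),
            ("ovarian", "moderate"),
            ("sarcoma", "moderate"),
            ("other", "moderate"),
            ("lung", "rapid"),
            ("colorectal", "rapid"),
            ("melanoma", "rapid"),
            ("unknown_origin", "rapid"),
        ],
    )
    def test_default_vocabulary(self, site, expected):
        assert classify_primary_growth(site) == expected

    def test_unrecognised_site_is_an_explicit_error(self):
        with pytest.raises(SiteClassificationError):
            classify_primary_growth("appendix")

    def test_vocabulary_override(self, tmp_path):
        path = tmp_path / "vocab.tsv"
        path.write_text("breast\trapid\n")
        vocab = load_site_vocabulary(path)
        assert classify_primary_growth("breast", vocab) == "rapid"


class TestComponentScores:
    def test_all_adverse(self, adverse_record):
        result = component_scores(adverse_record)
        assert result.component_tuple() == (3, 2, 2, 1, 1, 1)
        assert result.total == 10
        assert result.risk_group == "high"

    def test_all_favorable(self, favorable_record):
        result = component_scores(favorable_record)
        assert result.component_tuple() == (0, 0, 0, 0, 0, 0)
        assert result.total == 0
        assert result.risk_group == "low"

    def test_missing_visceral_not_scorable(self):
        record = make_record(visceral=None)
        result = component_scores(record)
        assert not result.scorable
        assert result.missing_components == ["visceral"]
        assert result.total is None and result.risk_group is None

    def test_undetermined_labs_not_scorable(self):
        record = make_record(labs=LabPanel(crp=0.1, panel_date=LAB_DATE))
        result = component_scores(record)
        assert not result.scorable
        assert "labs" in result.missing_components

    def test_total_score_raises_on_non_scorable(self):
        result = component_scores(make_record(visceral=None))
        with pytest.raises(NotScorableError):
            total_score(result)

    @pytest.mark.parametrize(
        "components, expected",
        [((3, 2, 2, 1, 1, 1), 10), ((0, 0, 0, 0, 0, 0), 0), ((3, 1, 1, 0, 1, 1), 7)],
    )
    def test_total_is_component_sum(self, components, expected):
        result = KatagiriResult(*components)
        assert total_score(result) == expected


class TestRiskGroups:
    @pytest.mark.parametrize(
        "total, group",
        [(0, "low"), (3, "low"), (4, "intermediate"), (6, "intermediate"),
         (7, "high"), (10, "high")],
    )
    def test_boundaries(self, total, group):
        assert assign_risk_group(total) == group

    @pytest.mark.parametrize("total", [-1, 11])
    def test_range_error(self, total):
        with pytest.raises(ValueError):
            assign_risk_group(total)

    def test_partition_is_exhaustive(self):
        groups = [assign_risk_group(t) for t in range(11)]
        assert groups == ["low"] * 4 + ["intermediate"] * 3 + ["high"] * 4


LEVELS = ((0, 2, 3), (0, 1, 2), (0, 1, 2), (0, 1), (0, 1), (0, 1))


class TestEnumerationOracle:
    def test_all_216_combinations_match_hand_sum(self):
        totals = []
        for combo in itertools.product(*LEVELS):
            result = KatagiriResult(*combo)
            # independent oracle: plain Python sum of the tuple
            assert total_score(result) == sum(combo)
            totals.append(sum(combo))
        assert len(totals) == 216
        assert min(totals) == 0 and max(totals) == 10

    @given(
        st.tuples(*[st.sampled_from(lv) for lv in LEVELS]),
        st.integers(min_value=0, max_value=5),
    )
    def test_worsening_one_component_is_monotone(self, combo, which):
        """Raising any single component never lowers total or risk group."""
        rank = {"low": 0, "intermediate": 1, "high": 2}
        levels = LEVELS[which]
        idx = levels.index(combo[which])
        if idx == len(levels) - 1:
            return
        worse = list(combo)
        worse[which] = levels[idx + 1]
        t0, t1 = sum(combo), sum(worse)
        assert t1 >= t0
        assert rank[assign_risk_group(t1)] >= rank[assign_risk_group(t0)]


class TestRecommendation:
    def test_high_risk_single_fraction(self):
        rec = recommend_fractionation("high")
        assert rec.schedule == "single-fraction"
        assert "8 Gy" in rec.example_regimens[0]

    @pytest.mark.parametrize("group", ["low", "intermediate"])
    def test_other_groups_multi_fraction(self, group):
        rec = recommend_fractionation(group)
        assert rec.schedule == "multi-fraction"
        assert rec.caveat

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            recommend_fractionation("medium")
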