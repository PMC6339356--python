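"""Validation pipeline: tables, screening, multivariate models, strata."""

import math

import numpy as np
import pytest
from conftest import make_record

from katascore.simulate import CohortConfig, simulate_cohort
from katascore.validation import (
    CovariateSpec,
    KatagiriValidation,
    characteristics_table,
    default_factors,
    filter_scorable,
    multivariate_analysis,
    risk_group_validation,
    univariate_analysis,
)

FACTORS = default_factors()


def factor(name):
    return next(f for f in FACTORS if f.name == name)


class TestFilterScorable:
    def test_missing_visceral_excluded_and_logged(self):
        records = [make_record(patient_id="A"), make_record(patient_id="B", visceral=None)]
        kept, scores, excluded = filter_scorable(records)
        assert [r.patient_id for r in kept] == ["A"]
        assert excluded == [("B", ["visceral"])]

    def test_complete_cohort_identity(self):
        records = [make_record(patient_id=f"P{i}") for i in range(5)]
        kept, _, excluded = filter_scorable(records)
        assert len(kept) == 5 and not excluded

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            filter_scorable([])


class TestCharacteristicsTable:
    def test_two_patient_toy(self):
        records = [make_record(sex="male"), make_record(sex="female")]
        table = characteristics_table(records, [factor("sex")])
        assert list(table.n) == [1, 1]
        assert list(table.percent) == [50.0, 50.0]

    def test_zero_count_level_retained(self):
        records = [make_record(visceral="nodular")]
        table = characteristics_table(records, [factor("visceral")])
        assert set(table.level) == {"none", "nodular", "disseminated"}
        assert table.loc[table.level == "none", "n"].iloc[0] == 0

    def test_missing_data_levels_sum_below_total(self):
        records = [make_record(), make_record(kps=None)]
        table = characteristics_table(records, [factor("kps_band")])
        assert table.n.sum() == 1  # one patient unmappable for KPS

    def test_replica_risk_group_rows(self):
        df = simulate_cohort(CohortConfig(seed=11))
        model = KatagiriValidation.from_dataframe(df)
        res = model.fit()
        rows = res.table2[res.table2.factor == "risk_group"]
        assert list(rows.n) == [18, 133, 205]
        assert list(rows.percent) == [5.1, 37.4, 57.6]


class TestUnivariate:
    def test_identical_survival_across_levels_gives_p_one(self):
        base = [(3.0, "died"), (6.0, "died"), (9.0, "censored"), (12.0, "died")]
        records = [
            make_record(patient_id=f"{sex}{i}", sex=sex, survival_months=t, event=e)
            for sex in ("male", "female")
            for i, (t, e) in enumerate(base)
        ]
        table = univariate_analysis(records, [factor("sex")])
        assert table.p.iloc[0] == pytest.approx(1.0)

    def test_two_level_simulation_recovery(self):
        rng = np.random.default_rng(77)
        records = []
        for sex, median in (("male", 3.0), ("female", 9.0)):
            times = rng.exponential(median / math.log(2), size=200)
            records += [
                make_record(patient_id=f"{sex}{i}", sex=sex,
                            survival_months=float(t), event="died")
                for i, t in enumerate(times)
            ]
        table = univariate_analysis(records, [factor("sex")])
        assert table.p.iloc[0] < 0.001
        med = dict(zip(table.level, table.median_months))
        assert med["male"] == pytest.approx(3.0, abs=1.0)
        assert med["female"] == pytest.approx(9.0, abs=2.0)

    def test_single_level_factor_flagged_without_test(self):
        records = [make_record(patient_id=str(i), sex="male") for i in range(4)]
        table = univariate_analysis(records, [factor("sex")])
        assert table.p.isna().all()

    def test_level_name_permutation_leaves_p_unchanged(self):
        rng = np.random.default_rng(8)
        records = [
            make_record(
                patient_id=str(i),
                sex="male" if i % 2 else "female",
                survival_months=float(rng.exponential(5)),
                event="died",
            )
            for i in range(60)
        ]
        p1 = univariate_analysis(records, [factor("sex")]).p.iloc[0]
        for r in records:
            r.sex = "female" if r.sex == "male" else "male"
        p2 = univariate_analysis(records, [factor("sex")]).p.iloc[0]
        assert p1 == pytest.approx(p2, rel=1e-10)


class TestMultivariate:
    def test_null_binary_covariate(self):
        rng = np.random.default_rng(13)
        records = [
            make_record(
                patient_id=str(i),
                sex="male" if rng.uniform() < 0.5 else "female",
                survival_months=float(rng.exponential(5)),
                event="died",
            )
            for i in range(2000)
        ]
        out = multivariate_analysis(
            records, specs=[CovariateSpec("sex_only", (("sex", "female"),))]
        )
        table = out["sex_only"]["table"]
        male = table[table.level == "male"].iloc[0]
        assert 0.9 < male.HR < 1.1
        assert male.hr_lower95 < 1.0 < male.hr_upper95

    def test_reference_levels_report_unit_hazard_ratio(self):
        df = simulate_cohort(CohortConfig(seed=21, mode="covariate_effect",
                                          n_patients=400))
        out = multivariate_analysis(KatagiriValidation.from_dataframe(df).records)
        for entry in out.values():
            refs = entry["table"][entry["table"].reference]
            assert (refs.HR == 1.0).all()
            assert refs.hr_lower95.isna().all()

    def test_canonical_models_separate_sex_and_ecog(self):
        df = simulate_cohort(CohortConfig(seed=22, mode="covariate_effect",
                                          n_patients=400))
        out = multivariate_analysis(KatagiriValidation.from_dataframe(df).records)
        assert "sex" not in set(out["with_ecog"]["table"].factor)
        assert "ecog_band" not in set(out["with_sex"]["table"].factor)
        assert not out["combined"]["spec"].canonical

    def test_rank_deficiency_reported_as_diagnostic(self):
        # every patient male: the sex indicator column is constant
        records = [
            make_record(patient_id=str(i), sex="male",
                        survival_months=float(i + 1), event="died")
            for i in range(20)
        ]
        out = multivariate_analysis(
            records, specs=[CovariateSpec("bad", (("sex", "female"),))]
        )
        assert out["bad"]["diagnostic"] is not None
        assert out["bad"]["fit"] is None


def record_with_total(pid, total_group, t, event):
    """A patient whose component combination lands in the requested group."""
    presets = {
        "low": dict(primary_site="breast", visceral="none", ecog=0,
                    prior_chemo=False, multiple_bone_mets=False),
        "intermediate": dict(primary_site="lung", visceral="nodular", ecog=0,
                             prior_chemo=False, multiple_bone_mets=False),
        "high": dict(primary_site="lung", visceral="disseminated", ecog=3,
                     prior_chemo=True, multiple_bone_mets=False),
    }
    return make_record(patient_id=pid, survival_months=t, event=event,
                       **presets[total_group])


class TestRiskGroupValidation:
    def test_identical_data_identical_rows_and_p_one(self):
        base = [(2.0, "died"), (5.0, "died"), (9.0, "censored"), (12.0, "died")]
        records = []
        for group in ("low", "intermediate", "high"):
            records += [
                record_with_total(f"{group}{i}", group, t, e)
                for i, (t, e) in enumerate(base)
            ]
        out = risk_group_validation(records)
        assert out["logrank_p"] == pytest.approx(1.0)
        medians = out["table"].median_months
        assert medians.nunique() == 1

    def test_absent_group_flagged(self):
        records = [record_with_total(f"h{i}", "high", float(i + 1), "died")
                   for i in range(6)]
        records += [record_with_total(f"l{i}", "low", float(i + 2), "died")
                    for i in range(6)]
        out = risk_group_validation(records)
        assert out["absent_groups"] == ["intermediate"]
        assert not math.isnan(out["logrank_p"])  # 2 groups still testable

    def test_replica_profile(self):
        df = simulate_cohort(CohortConfig(seed=31))
        res = KatagiriValidation.from_dataframe(df).fit()
        table = res.table5.set_index("group")
        # medians within sampling error of the calibrated 27 / 5.76 / 2.21
        assert abs(table.loc["intermediate", "median_months"] - 5.76) < 2.0
        assert abs(table.loc["high", "median_months"] - 2.21) < 1.0
        assert table.loc["low", "median_months"] > 12.0
        # survival percentages monotone non-increasing within each group
        cols = ["surv_3m", "surv_6m", "surv_12m", "surv_24m"]
        for group in table.index:
            vals = [v for v in table.loc[group, cols] if not math.isnan(v)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert res.logrank_p < 0.001
        assert table.n.sum() == res.n_scorable

    def test_km_curves_are_plot_ready(self):
        df = simulate_cohort(CohortConfig(seed=32))
        res = KatagiriValidation.from_dataframe(df).fit()
        km = res.km_curves
        assert set(km.group) == {"low", "intermediate", "high"}
        for _, g in km.groupby("group"):
            assert g.time.iloc[0] == 0.0 and g.survival.iloc[0] == 1.0
            assert (g.survival.diff().dropna() <= 1e-12).all()


class TestResultsObject:
    def test_report_written_with_all_artifacts(self, tmp_path):
        df = simulate_cohort(CohortConfig(seed=33))
        res = KatagiriValidation.from_dataframe(df).fit()
        paths = res.write(tmp_path)
        names = {p.name for p in paths}
        assert names == {
            "table2.csv", "table3.csv", "table4.csv", "table5.csv",
            "km_curves.csv", "report.json",
        }
        assert "log-rank" in res.summary()

    def test_score_frame_has_recommendations(self):
        df = simulate_cohort(CohortConfig(seed=34))
        res = KatagiriValidation.from_dataframe(df).fit()
        frame = res.score_frame()
        assert (frame.loc[frame.risk_group == "high", "recommendation"]
                == "single-fraction").all()
        assert (frame.loc[frame.risk_group == "low", "recommendation"]
                == "multi-fraction").all()
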