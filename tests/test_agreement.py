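import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipometry import (
    PairedSeries,
    bland_altman,
    classify_icc,
    icc,
    summarize_cohort,
    validity_report,
)
from adipometry.measurements import Cohort

from conftest import icc_anova_oracle, make_record


class TestIcc:
    def test_perfect_agreement_is_exactly_one(self):
        x = np.array([22.0, 25.5, 19.0, 31.2, 27.0])
        res = icc(PairedSeries(x, x.copy()))
        assert res.icc == 1.0
        assert res.classification == "good_excellent"

    def test_large_constant_offset_kills_absolute_agreement(self):
        # tiny subject variance + 20-point shift: brute-force oracle agrees
        crit = np.array([10.0, 10.1, 9.9, 10.05, 9.95])
        pred = crit + 20.0
        res = icc(PairedSeries(crit, pred))
        assert res.icc == pytest.approx(icc_anova_oracle(crit, pred), abs=1e-12)
        assert res.icc < 0.01

    def test_fixed_six_pair_vector_matches_anova_oracle(self):
        crit = np.array([22.1, 27.4, 19.8, 31.2, 24.5, 18.3])
        pred = np.array([20.3, 28.9, 18.2, 29.0, 26.1, 17.5])
        res = icc(PairedSeries(crit, pred))
        assert res.icc == pytest.approx(0.9477817804173562, abs=1e-10)

    def test_consistency_variant_ignores_constant_offset(self):
        crit = np.array([22.0, 25.5, 19.0, 31.2, 27.0])
        res = icc(PairedSeries(crit, crit + 5.0), variant="consistency")
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.variant == "consistency"

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        crit = rng.normal(25, 5, 30)
        pred = crit + rng.normal(1, 2, 30)
        res = icc(PairedSeries(crit, pred))
        assert res.ci_low <= res.icc <= res.ci_high

    def test_negative_lower_bound_is_not_truncated(self):
        # strong offset relative to subject spread drives the lower bound negative
        rng = np.random.default_rng(5)
        crit = rng.normal(25, 2, 12)
        pred = crit + 8 + rng.normal(0, 1, 12)
        res = icc(PairedSeries(crit, pred))
        assert res.ci_low < 0

    def test_matches_pingouin_absolute_and_consistency(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        n = 20
        crit = rng.normal(24, 6, n)
        pred = crit + rng.normal(3, 2.5, n)
        long = pd.DataFrame(
            {
                "subj": np.tile(np.arange(n), 2),
                "rater": np.repeat(["crit", "pred"], n),
                "y": np.concatenate([crit, pred]),
            }
        )
        ref = pg.intraclass_corr(long, targets="subj", raters="rater", ratings="y").set_index("Type")
        mine_a = icc(PairedSeries(crit, pred), "absolute_agreement")
        mine_c = icc(PairedSeries(crit, pred), "consistency")
        assert mine_a.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        assert mine_c.icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert mine_a.ci_low == pytest.approx(ref.loc["ICC(A,1)", "CI95"][0], abs=5e-3)
        assert mine_a.ci_high == pytest.approx(ref.loc["ICC(A,1)", "CI95"][1], abs=5e-3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100)
    def test_equals_anova_oracle_on_random_small_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        crit = rng.normal(25, 6, n)
        pred = crit + rng.normal(rng.uniform(-8, 8), rng.uniform(0.5, 4), n)
        res = icc(PairedSeries(crit, pred))
        assert res.icc == pytest.approx(icc_anova_oracle(crit, pred), abs=1e-8)

    def test_subject_relabelling_invariance(self):
        rng = np.random.default_rng(2)
        crit = rng.normal(25, 5, 15)
        pred = crit + rng.normal(2, 2, 15)
        perm = rng.permutation(15)
        a = icc(PairedSeries(crit, pred)).icc
        b = icc(PairedSeries(crit[perm], pred[perm])).icc
        assert a == pytest.approx(b, abs=1e-12)

    def test_absolute_icc_decreases_with_offset_magnitude(self):
        rng = np.random.default_rng(8)
        crit = rng.normal(25, 4, 60)
        values = [icc(PairedSeries(crit, crit + beta)).icc for beta in (0.5, 2, 5, 10, 15)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            icc(PairedSeries(np.array([1.0, 2.0]), np.array([1.0, 2.0])))

    def test_zero_total_variance_errors(self):
        x = np.full(5, 20.0)
        with pytest.raises(ValueError, match="variance"):
            icc(PairedSeries(x, x.copy()))


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.248, "poor"),
            (0.399, "poor"),
            (0.40, "moderate"),
            (0.741, "moderate"),
            (0.75, "moderate"),
            (0.751, "good_excellent"),
            (0.912, "good_excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_threshold_mapping(self, value, expected):
        assert classify_icc(value) == expected

    def test_icc_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.2)


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([20.0, 25.0, 30.0])
        res = bland_altman(PairedSeries(x, x.copy()))
        assert res.bias == 0.0
        assert res.sd_diff == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)
        assert res.outside_fraction == 0.0

    def test_hand_computed_differences(self):
        crit = np.array([1.0, 2.0, 3.0, 4.0, 5.0]) + 10
        pred = np.full(5, 10.0)
        res = bland_altman(PairedSeries(crit, pred))
        assert res.bias == pytest.approx(3.0, abs=1e-12)
        assert res.sd_diff == pytest.approx(1.5811388300841898, abs=1e-12)
        assert res.loa_low == pytest.approx(-0.09903210696501175, abs=1e-10)
        assert res.loa_high == pytest.approx(6.099032106965012, abs=1e-10)

    def test_overestimation_yields_negative_bias(self):
        crit = np.array([20.0, 22.0, 24.0])
        res = bland_altman(PairedSeries(crit, crit + 12.7))
        assert res.bias == pytest.approx(-12.7, abs=1e-12)

    def test_loa_identity_is_exact(self):
        rng = np.random.default_rng(1)
        pairs = PairedSeries(rng.normal(25, 5, 40), rng.normal(22, 5, 40))
        res = bland_altman(pairs)
        assert res.loa_low == res.bias - 1.96 * res.sd_diff
        assert res.loa_high == res.bias + 1.96 * res.sd_diff

    @given(st.floats(-20, 20))
    def test_translation_shifts_bias_exactly(self, c):
        rng = np.random.default_rng(9)
        crit = rng.normal(25, 5, 25)
        pred = crit + rng.normal(0, 2, 25)
        base = bland_altman(PairedSeries(crit, pred))
        shifted = bland_altman(PairedSeries(crit, pred + c))
        assert shifted.bias == pytest.approx(base.bias - c, abs=1e-9)
        assert shifted.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)

    def test_multiplier_is_configurable(self):
        rng = np.random.default_rng(4)
        pairs = PairedSeries(rng.normal(25, 5, 20), rng.normal(24, 5, 20))
        res = bland_altman(pairs, multiplier=2.5)
        assert res.loa_high - res.bias == pytest.approx(2.5 * res.sd_diff, abs=1e-12)

    def test_single_pair_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman(PairedSeries(np.array([1.0]), np.array([2.0])))


def _cohort_with_dexa_from(equation_value_fn, n=12):
    """Small two-sex cohort whose criterion is an exact copy of one equation."""
    records = []
    rng = np.random.default_rng(0)
    for i in range(n):
        sex = "F" if i % 2 == 0 else "M"
        folds = {
            "triceps": float(rng.uniform(6, 20)),
            "biceps": float(rng.uniform(4, 12)),
            "subscapular": float(rng.uniform(6, 16)),
            "suprailiac": float(rng.uniform(6, 18)),
            "supraspinale": float(rng.uniform(5, 12)),
            "abdominal": float(rng.uniform(8, 20)),
            "front_thigh": float(rng.uniform(10, 28)),
            "medial_calf": float(rng.uniform(6, 16)),
        }
        record = make_record(f"r{i}", sex=sex, skinfolds=folds, dexa_fp=None)
        records.append(make_record(f"r{i}", sex=sex, skinfolds=folds, dexa_fp=equation_value_fn(record)))
    return Cohort(tuple(records))


class TestValidityReport:
    def test_noiseless_reference_equation_row_is_perfect(self):
        from adipometry import durnin_rahaman_fp

        cohort = _cohort_with_dexa_from(durnin_rahaman_fp)
        report = validity_report(cohort, equations=("durnin_rahaman",))
        row = report.table[report.table.stratum == "all"].iloc[0]
        assert row["icc"] == 1.0
        assert row["bias"] == pytest.approx(0.0, abs=1e-12)

    def test_five_equations_three_strata_gives_15_rows(self, small_cohort):
        report = validity_report(small_cohort)
        assert len(report.table) == 15
        # deterministic row order: equation blocks, then all/F/M
        assert list(report.table["stratum"][:3]) == ["all", "F", "M"]

    def test_single_sex_cohort_reports_absent_stratum(self):
        records = tuple(make_record(f"f{i}", sex="F", dexa_fp=25 + i) for i in range(5))
        report = validity_report(Cohort(records), equations=("slaughter",))
        assert set(report.table["stratum"]) == {"all", "F"}
        assert any("slaughter/M" in note for note in report.notes)

    def test_missing_criterion_is_refused(self):
        records = tuple(make_record(f"f{i}", dexa_fp=None) for i in range(4))
        with pytest.raises(ValueError, match="criterion"):
            validity_report(Cohort(records))

    def test_listwise_exclusion_is_counted(self):
        complete = [make_record(f"c{i}", dexa_fp=25 + i) for i in range(5)]
        partial = make_record("p0", skinfolds={"triceps": 10.0, "medial_calf": 9.0}, dexa_fp=24.0)
        report = validity_report(Cohort((*complete, partial)), equations=("durnin_rahaman",))
        assert report.exclusions["durnin_rahaman"] == 1

    def test_coordinates_enable_plot_reconstruction(self, small_cohort):
        report = validity_report(small_cohort, equations=("slaughter",))
        coords = report.coordinates[("slaughter", "all")]
        assert set(coords.columns) == {"id", "mean", "difference", "bias", "loa_low", "loa_high"}
        assert len(coords) == len(small_cohort)


class TestSummarizeCohort:
    def test_single_record_mean_equals_median(self):
        cohort = Cohort((make_record("solo"),))
        table = summarize_cohort(cohort, strata=("all",))
        row = table[table.variable == "body_mass"].iloc[0]
        assert row["mean"] == row["median"] == pytest.approx(50.9)
        assert np.isnan(row["sd"])  # undefined for n = 1

    def test_constant_column_has_zero_spread(self):
        cohort = Cohort(tuple(make_record(f"r{i}") for i in range(4)))
        row = summarize_cohort(cohort, strata=("all",)).set_index("variable").loc["stature"]
        assert row["sd"] == 0.0
        assert row["q3"] - row["q1"] == 0.0

    def test_stratified_counts(self, small_cohort):
        table = summarize_cohort(small_cohort)
        by = table[table.variable == "age"].set_index("stratum")["n"]
        assert by["all"] == 6 and by["F"] == 3 and by["M"] == 3
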