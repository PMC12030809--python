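import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortinterp import (
    CohortConfig,
    OutputEstimate,
    TOSTConfig,
    anova_outputs,
    build_output_table,
    cohens_d_paired,
    generate_cohort,
    total_output,
    tost_paired,
)

from conftest import make_profile


class TestTotalOutput:
    def test_constant_one_integrates_to_1440(self):
        times = np.arange(0, 1441, 60, dtype=float)
        assert total_output(make_profile(np.ones(25), times)) == pytest.approx(1440.0)

    def test_linear_ramp_is_exact_triangle(self):
        times = np.array([0, 240, 1000, 1440], dtype=float)
        values = 10.0 * times / 1440.0
        assert total_output(make_profile(values, times)) == pytest.approx(7200.0)

    def test_missing_endpoint_rejected(self):
        times = np.arange(0, 1381, 60, dtype=float)  # stops at 23 h
        with pytest.raises(ValueError, match="endpoint"):
            total_output(make_profile(np.ones(len(times)), times))

    def test_additive_over_half_windows(self, serum_rest_profile):
        full = total_output(serum_rest_profile)
        first = total_output(serum_rest_profile, window=(0, 720))
        second = total_output(serum_rest_profile, window=(720, 1440))
        assert full == pytest.approx(first + second)

    def test_hour_rule_is_minute_rule_over_60(self, serum_rest_profile):
        assert total_output(serum_rest_profile, rule="trapezoid_hours") == pytest.approx(
            total_output(serum_rest_profile) / 60.0
        )

    def test_subsampling_changes_auc_only_slightly(self):
        """Q120 sub-sampling of the smooth synthetic serum profile moves the
        trapezoidal AUC by under 2% (quadrature error on a smooth curve)."""
        from cortinterp import build_scheme, downsample

        deviations = []
        for seed in range(20):
            cohort = generate_cohort(CohortConfig(n_subjects=1, seed=seed))
            serum = next(p for p in cohort if p.specimen == "serum")
            full = total_output(serum)
            sub = total_output(downsample(serum, build_scheme("Q120")))
            deviations.append(abs(sub - full) / full)
        assert np.mean(deviations) < 0.02


class TestCohensD:
    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cohens_d_paired([0.1, 0.1, 0.1])

    def test_zero_mean_gives_zero(self):
        assert cohens_d_paired([-1.0, 1.0]) == 0.0

    def test_hand_computed_example(self):
        assert cohens_d_paired([1.0, 2.0, 3.0]) == pytest.approx(2.0)


class TestTostPaired:
    def test_near_identical_outputs_are_equivalent(self):
        rng = np.random.default_rng(0)
        x = np.array([10.0, 11.0, 9.5, 12.0, 10.5, 11.5, 9.0, 10.2])
        y = x * np.exp(rng.normal(0, 0.01, 8))
        res = tost_paired(x, y)
        assert res.equivalent
        assert abs(res.estimate) < 0.02

    def test_half_log_shift_is_not_equivalent(self):
        rng = np.random.default_rng(1)
        x = np.array([10.0, 11.0, 9.5, 12.0, 10.5, 11.5, 9.0, 10.2])
        y = x * np.exp(0.5 + rng.normal(0, 0.05, 8))
        res = tost_paired(x, y)
        assert not res.equivalent
        assert res.estimate > 0.25

    def test_frozen_closed_form_oracle(self):
        """Fixed vectors checked against a paired-t oracle computed once
        with statsmodels (ttost_paired + tconfint_mean at alpha = 0.10)."""
        x = np.array([10.0, 11.0, 12.0, 13.0])
        y = np.array([10.5, 11.2, 12.4, 12.9])
        res = tost_paired(x, y)
        assert res.estimate == pytest.approx(0.022969111600, abs=1e-9)
        assert res.p_lower == pytest.approx(9.316260341524e-05, rel=1e-6)
        assert res.p_upper == pytest.approx(1.614315829993e-04, rel=1e-6)
        assert res.ci_lower == pytest.approx(-0.005284555946, abs=1e-9)
        assert res.ci_upper == pytest.approx(0.051222779147, abs=1e-9)
        assert res.cohens_d == pytest.approx(0.956595586773, abs=1e-9)
        assert res.equivalent

    def test_statsmodels_oracle_agreement(self):
        from statsmodels.stats.weightstats import DescrStatsW, ttost_paired

        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            x = rng.uniform(5, 15, n)
            y = x * np.exp(rng.normal(0, 0.1, n))
            res = tost_paired(x, y)
            d = np.log(y) - np.log(x)
            p, t1, t2 = ttost_paired(np.log(y), np.log(x), -0.25, 0.25)
            assert res.p_lower == pytest.approx(t1[1], rel=1e-9, abs=1e-12)
            assert res.p_upper == pytest.approx(t2[1], rel=1e-9, abs=1e-12)
            lo, hi = DescrStatsW(d).tconfint_mean(alpha=0.10)
            assert res.ci_lower == pytest.approx(lo, rel=1e-9)
            assert res.ci_upper == pytest.approx(hi, rel=1e-9)

    def test_non_positive_values_rejected_on_log_scale(self):
        with pytest.raises(ValueError, match="positive"):
            tost_paired([1.0, 0.0, 2.0], [1.0, 1.0, 2.0])

    def test_zero_spread_degenerates_by_sign(self):
        x = np.array([10.0, 20.0, 30.0])
        res = tost_paired(x, x * np.exp(0.1))  # constant log shift 0.1 < eps
        assert res.p_lower == 0.0 and res.p_upper == 0.0 and res.equivalent
        res2 = tost_paired(x, x * np.exp(0.4))  # constant shift beyond eps
        assert res2.p_upper == 1.0 and not res2.equivalent

    @settings(deadline=None, max_examples=50)
    @given(
        seed=st.integers(0, 100_000),
        shift=st.floats(-0.4, 0.4),
        spread=st.floats(0.01, 0.5),
    )
    def test_decision_iff_ci_inside_region(self, seed, shift, spread):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        x = rng.uniform(5, 15, n)
        y = x * np.exp(shift + rng.normal(0, spread, n))
        res = tost_paired(x, y)
        inside = -0.25 < res.ci_lower and res.ci_upper < 0.25
        assert res.equivalent == inside
        assert res.ci_lower <= res.estimate <= res.ci_upper


def _outputs(values_by_cell):
    out = []
    for (specimen, condition), values in values_by_cell.items():
        for i, v in enumerate(values):
            out.append(
                OutputEstimate(
                    subject_id=f"S{i + 1}",
                    condition=condition,
                    specimen=specimen,
                    scheme="Q60" if specimen == "serum" else "Q120",
                    auc=float(v),
                )
            )
    return out


class TestAnova:
    def test_all_equal_outputs_give_f_zero_p_one(self):
        cells = {
            (s, c): [100.0] * 4
            for s in ("serum", "saliva")
            for c in ("rest", "exercise")
        }
        table = anova_outputs(_outputs(cells)).set_index("factor")
        assert table.loc["C(specimen)", "F"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["C(specimen)", "p"] == pytest.approx(1.0)
        assert table.loc["C(condition)", "p"] == pytest.approx(1.0)

    def test_scale_invariance_of_f_and_p(self):
        rng = np.random.default_rng(0)
        cells = {
            (s, c): rng.uniform(90, 110, 5)
            for s in ("serum", "saliva")
            for c in ("rest", "exercise")
        }
        a = anova_outputs(_outputs(cells)).set_index("factor")
        doubled = {k: 2 * np.asarray(v) for k, v in cells.items()}
        b = anova_outputs(_outputs(doubled)).set_index("factor")
        for factor in ("C(specimen)", "C(condition)"):
            assert b.loc[factor, "F"] == pytest.approx(a.loc[factor, "F"])
            assert b.loc[factor, "p"] == pytest.approx(a.loc[factor, "p"])

    def test_missing_cell_rejected(self):
        cells = {
            ("serum", "rest"): [100.0] * 3,
            ("serum", "exercise"): [100.0] * 3,
            ("saliva", "rest"): [6.0] * 3,
        }
        with pytest.raises(ValueError, match="cell"):
            anova_outputs(_outputs(cells))

    def test_specimen_effect_dominates_on_synthetic_cohorts(self):
        """Serum output is ~17x salivary output by construction, so the
        specimen factor must be overwhelmingly significant at n = 8."""
        for seed in range(5):
            cohort = generate_cohort(CohortConfig(seed=seed))
            outputs = [
                OutputEstimate(p.subject_id, p.condition, p.specimen,
                               "Q60" if p.specimen == "serum" else "Q120",
                               total_output(p))
                for p in cohort
            ]
            table = anova_outputs(outputs).set_index("factor")
            assert table.loc["C(specimen)", "p"] < 0.001


class TestOutputTable:
    def test_layout_and_blank_ground_truth_degree_columns(self, default_cohort):
        from cortinterp import GROUND_TRUTH, valid_schemes_for, downsample

        outputs = []
        for p in default_cohort:
            for scheme in valid_schemes_for(p.specimen):
                obs = downsample(p, scheme)
                outputs.append(
                    OutputEstimate(p.subject_id, p.condition, p.specimen,
                                   scheme.name, total_output(obs))
                )
                if scheme.name != GROUND_TRUTH[p.specimen]:
                    for degree in (2, 3):
                        outputs.append(
                            OutputEstimate(p.subject_id, p.condition, p.specimen,
                                           scheme.name, total_output(obs) * 1.01,
                                           source="interpolated", degree=degree)
                        )
        table = build_output_table(outputs)
        serum = table[table.specimen == "serum"]
        saliva = table[table.specimen == "saliva"]
        assert len(serum) == 7 * 2
        assert len(saliva) == 5 * 2
        gt_rows = table[table.scheme.isin(["Q60"]) & (table.specimen == "serum")]
        assert gt_rows["deg2_mean"].isna().all()
        assert gt_rows["deg3_mean"].isna().all()
        # SE = sd/sqrt(n) over the 8 subjects
        cell = [o.auc for o in outputs
                if o.specimen == "serum" and o.condition == "rest"
                and o.scheme == "Q60" and o.source == "observed"]
        row = table[(table.specimen == "serum") & (table.condition == "rest")
                    & (table.scheme == "Q60")].iloc[0]
        assert row["obs_mean"] == pytest.approx(np.mean(cell))
        assert row["obs_se"] == pytest.approx(np.std(cell, ddof=1) / np.sqrt(8))

    def test_single_subject_se_is_empty(self):
        outputs = [
            OutputEstimate("S1", "rest", "serum", "Q60", 100.0),
        ]
        table = build_output_table(outputs)
        assert np.isnan(table.iloc[0]["obs_se"])
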