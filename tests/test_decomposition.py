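"""Overall and detailed decomposition: exactness, oracles, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from bmidecomp.core_records import Covariate, apply_exclusions
from bmidecomp.decomposition import (
    BootstrapError,
    GroupSummary,
    UnattributableError,
    bootstrap_ci,
    decompose,
    group_summary,
    overall_components,
    yun_detailed,
)
from bmidecomp.synthetic_cohort import generate_wave, make_scenario, population_truth
from bmidecomp.weighted_logit import (
    DesignSpec,
    LogitFit,
    build_design,
    fit_weighted_logit,
)

from conftest import BMI_NORMAL, BMI_UNDER, make_wave


def _fit_wave(wave, spec, outcome):
    X, y, w, cols = build_design(wave, spec, outcome)
    return fit_weighted_logit(X, y, w, columns=cols)


class TestGroupSummary:
    def test_means_and_intercept(self, binary_schema):
        spec = DesignSpec.from_schema(binary_schema)
        wave = make_wave(
            "2016",
            [{"bmi": BMI_UNDER, "x": "1", "weight": 2.0},
             {"bmi": BMI_NORMAL, "x": "0", "weight": 3.0}],
            binary_schema,
        )
        s = group_summary(wave, spec, "underweight")
        assert s.xbar[0] == 1.0                      # intercept column
        assert s.xbar[1] == pytest.approx(0.4)       # weighted share of x=1
        assert s.pbar == pytest.approx(0.4)
        assert ((s.xbar_full >= 0) & (s.xbar_full <= 1)).all()

    def test_equal_weights_match_unweighted(self, binary_schema):
        spec = DesignSpec.from_schema(binary_schema)
        wave = make_wave(
            "2016",
            [{"bmi": BMI_UNDER, "x": "1"}, {"bmi": BMI_NORMAL, "x": "0"},
             {"bmi": BMI_NORMAL, "x": "0"}],
            binary_schema,
        )
        s = group_summary(wave, spec, "underweight")
        assert s.xbar[1] == pytest.approx(1 / 3)
        assert s.pbar == pytest.approx(1 / 3)


class TestOverallComponents:
    def test_identical_fits_give_zero_coefficients_component(
        self, exact_two_cell_waves, binary_schema
    ):
        spec = DesignSpec.from_schema(binary_schema)
        wave_a, wave_b = exact_two_cell_waves
        fit = _fit_wave(wave_a, spec, "underweight")
        sa = group_summary(wave_a, spec, "underweight")
        sb = group_summary(wave_b, spec, "underweight")
        D, E, C = overall_components(fit, fit, sa, sb)
        assert C == 0.0

    def test_identical_waves_give_zero_gap(self, exact_two_cell_waves, binary_schema):
        spec = DesignSpec.from_schema(binary_schema)
        wave_a, _ = exact_two_cell_waves
        fit = _fit_wave(wave_a, spec, "underweight")
        s = group_summary(wave_a, spec, "underweight")
        D, E, C = overall_components(fit, fit, s, s)
        assert D == 0.0 and E == 0.0 and C == 0.0

    def test_two_cell_worked_example(self, exact_two_cell_waves, binary_schema):
        """Saturated fits on exact cell frequencies reproduce the enumeration
        oracle: (D, E, C) = (0.145, 0.075, 0.07)."""
        spec = DesignSpec.from_schema(binary_schema)
        wave_a, wave_b = exact_two_cell_waves
        fa = _fit_wave(wave_a, spec, "underweight")
        fb = _fit_wave(wave_b, spec, "underweight")
        sa = group_summary(wave_a, spec, "underweight")
        sb = group_summary(wave_b, spec, "underweight")
        D, E, C = overall_components(fa, fb, sa, sb)
        assert D == pytest.approx(0.145, abs=1e-8)
        assert E == pytest.approx(0.075, abs=1e-8)
        assert C == pytest.approx(0.07, abs=1e-8)

    def test_sample_average_equals_cell_enumeration(self, small_mixed_waves):
        """On a fully categorical design the sample-averaged counterfactual
        equals the weighted cell-enumeration value to 1e-10."""
        scenario, wave_a, wave_b = small_mixed_waves
        spec = scenario.spec
        fa = _fit_wave(wave_a, spec, scenario.outcome)
        sb = group_summary(wave_b, spec, scenario.outcome)
        from scipy.special import expit

        sample_avg = float(
            (sb.w @ expit(sb.X @ fa.params)) / sb.total_weight
        )
        cells = pd.DataFrame(sb.X, columns=list(sb.columns))
        cells["w"] = sb.w
        grouped = cells.groupby(list(sb.columns), as_index=False)["w"].sum()
        Xc = grouped[list(sb.columns)].to_numpy()
        wc = grouped["w"].to_numpy()
        cell_value = float((wc @ expit(Xc @ fa.params)) / wc.sum())
        assert sample_avg == pytest.approx(cell_value, abs=1e-10)


class TestYunDetailed:
    def _toy(self):
        cols = ("intercept", "x1", "x2")
        mk = lambda params: LogitFit(
            params=np.asarray(params, dtype=float), columns=cols, vcov=None,
            converged=True, n_iter=1, n=3, total_weight=1.0, loglik=0.0,
        )
        dummy = np.zeros((1, 3))
        mk_sum = lambda xbar: GroupSummary(
            year="t", X=dummy, X_full=dummy, y=np.zeros(1), w=np.ones(1),
            cluster_ids=np.array(["c"]), columns=cols, full_columns=cols,
            xbar=np.asarray(xbar, dtype=float), xbar_full=np.asarray(xbar, dtype=float),
            pbar=0.0, total_weight=1.0, n=1,
        )
        fa = mk([0.5, 1.0, -2.0])
        fb = mk([0.2, 0.4, -1.0])
        sa = mk_sum([1.0, 0.6, 0.3])
        sb = mk_sum([1.0, 0.5, 0.4])
        return fa, fb, sa, sb

    def test_three_column_toy_matches_hand_arithmetic(self):
        # s_E = (0, 0.1, 0.2) -> weights (0, 1/3, 2/3)
        # s_C = (0.3, 0.3, -0.4) -> weights (1.5, 1.5, -2.0)
        fa, fb, sa, sb = self._toy()
        detail = yun_detailed(fa, fb, sa, sb, E=0.06, C=0.05)
        np.testing.assert_allclose(detail["E"], [0.0, 0.02, 0.04], atol=1e-12)
        np.testing.assert_allclose(detail["C"], [0.075, 0.075, -0.10], atol=1e-12)

    def test_intercept_contributes_to_c_only(self):
        fa, fb, sa, sb = self._toy()
        detail = yun_detailed(fa, fb, sa, sb, E=0.06, C=0.05)
        assert detail.loc[detail.term == "intercept", "E"].iloc[0] == 0.0
        assert detail.loc[detail.term == "intercept", "C"].iloc[0] != 0.0

    def test_single_column_takes_full_component(
        self, exact_two_cell_waves, binary_schema
    ):
        spec = DesignSpec.from_schema(binary_schema)
        wave_a, wave_b = exact_two_cell_waves
        fa = _fit_wave(wave_a, spec, "underweight")
        fb = _fit_wave(wave_b, spec, "underweight")
        sa = group_summary(wave_a, spec, "underweight")
        sb = group_summary(wave_b, spec, "underweight")
        D, E, C = overall_components(fa, fb, sa, sb)
        detail = yun_detailed(fa, fb, sa, sb, E, C)
        # only x[1] has a composition change -> it carries all of E
        assert detail.loc[detail.term == "x[1]", "E"].iloc[0] == pytest.approx(E)

    def test_equal_shares_split_evenly(self):
        cols = ("intercept", "a", "b")
        fa = LogitFit(np.array([0.0, 1.0, 1.0]), cols, None, True, 1, 1, 1.0, 0.0)
        fb = LogitFit(np.array([0.0, 1.0, 1.0]), cols, None, True, 1, 1, 1.0, 0.0)
        dummy = np.zeros((1, 3))
        mk_sum = lambda xbar: GroupSummary(
            "t", dummy, dummy, np.zeros(1), np.ones(1), np.array(["c"]),
            cols, cols, np.asarray(xbar), np.asarray(xbar), 0.0, 1.0, 1,
        )
        detail = yun_detailed(
            fa, fb, mk_sum([1.0, 0.6, 0.6]), mk_sum([1.0, 0.4, 0.4]), E=0.08, C=0.0
        )
        np.testing.assert_allclose(detail["E"], [0.0, 0.04, 0.04], atol=1e-12)

    def test_unattributable_component_flagged(self):
        fa, fb, sa, sb = self._toy()
        # zero all coefficient gaps' shares: make xbar equal -> s_E all zero
        detail = yun_detailed(fa, fb, sa, sa, E=0.05, C=0.0)
        assert detail["E"].isna().all()
        with pytest.raises(UnattributableError):
            yun_detailed(fa, fb, sa, sa, E=0.05, C=0.0, strict=True)


class TestDecompose:
    def test_identical_waves_give_all_zero_result(self, small_mixed_waves):
        scenario, wave_a, _ = small_mixed_waves
        res = decompose(wave_a, wave_a, scenario.spec, scenario.outcome, ci=False)
        assert res.D == 0.0 and res.E == 0.0 and res.C == 0.0
        assert res.pct_E is None and res.pct_C is None  # suppressed, |D| ~ 0
        np.testing.assert_allclose(res.detail["E"], 0.0, atol=1e-12)

    def test_additivity_invariants(self, small_mixed_waves):
        scenario, wave_a, wave_b = small_mixed_waves
        res = decompose(wave_a, wave_b, scenario.spec, scenario.outcome, ci=False)
        assert abs(res.E + res.C - res.D) < 1e-10
        assert res.detail["E"].sum() == pytest.approx(res.E, abs=1e-10)
        assert res.detail["C"].sum() == pytest.approx(res.C, abs=1e-10)
        assert res.pct_E + res.pct_C == pytest.approx(100.0, abs=1e-6)

    def test_reference_recoding_leaves_components_unchanged(self, small_mixed_waves):
        scenario, wave_a, wave_b = small_mixed_waves
        spec = scenario.spec
        recoded = DesignSpec(
            covariates=tuple(
                Covariate(c.name, c.categories, c.categories[-1])
                if c.name in ("region", "education")
                else c
                for c in spec.covariates
            )
        )
        r1 = decompose(wave_a, wave_b, spec, scenario.outcome, ci=False)
        r2 = decompose(wave_a, wave_b, recoded, scenario.outcome, ci=False)
        assert r2.D == pytest.approx(r1.D, abs=1e-8)
        assert r2.E == pytest.approx(r1.E, abs=1e-8)
        assert r2.C == pytest.approx(r1.C, abs=1e-8)
        np.testing.assert_allclose(
            r2.detail["E"].to_numpy(), r1.detail["E"].to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose(
            r2.detail["C"].to_numpy(), r1.detail["C"].to_numpy(), atol=1e-6
        )

    def test_direction_antisymmetry(self, small_mixed_waves):
        """Swapping the waves negates D, and the swapped (E, C) still sum to
        the negated gap (values differ: the weighting convention flips)."""
        scenario, wave_a, wave_b = small_mixed_waves
        fwd = decompose(wave_a, wave_b, scenario.spec, scenario.outcome, ci=False)
        rev = decompose(wave_b, wave_a, scenario.spec, scenario.outcome, ci=False)
        assert rev.D == pytest.approx(-fwd.D, abs=1e-12)
        assert rev.E + rev.C == pytest.approx(-fwd.D, abs=1e-10)

    def test_index_conventions_agree_on_the_gap(self, small_mixed_waves):
        scenario, wave_a, wave_b = small_mixed_waves
        late = decompose(wave_a, wave_b, scenario.spec, scenario.outcome,
                         ci=False, index="late")
        early = decompose(wave_a, wave_b, scenario.spec, scenario.outcome,
                          ci=False, index="early")
        assert late.D == pytest.approx(early.D, abs=1e-12)
        assert abs(early.E + early.C - early.D) < 1e-10

    def test_coefficient_shift_only_attributes_everything_to_c(self):
        scenario = make_scenario("coefficient_shift_only")
        wave_a, _ = apply_exclusions(generate_wave(scenario, "a", 77))
        wave_b, _ = apply_exclusions(generate_wave(scenario, "b", 77))
        res = decompose(wave_a, wave_b, scenario.spec, scenario.outcome, ci=False)
        assert res.pct_C == pytest.approx(100.0, abs=10.0)


class TestBootstrap:
    def test_degenerate_waves_bracket_zero(self, small_mixed_waves):
        scenario, wave_a, _ = small_mixed_waves
        sub = wave_a.subset(np.arange(wave_a.n) < 1500)
        ci = bootstrap_ci(
            sub, sub, scenario.spec, scenario.outcome, reps=100, seed=5
        )
        for key in ("D", "E", "C"):
            lo, hi = ci[key]
            assert lo <= 0.0 <= hi

    def test_seeded_bootstrap_is_deterministic(self, small_mixed_waves):
        scenario, wave_a, wave_b = small_mixed_waves
        kw = dict(reps=100, seed=31)
        c1 = bootstrap_ci(wave_a, wave_b, scenario.spec, scenario.outcome, **kw)
        c2 = bootstrap_ci(wave_a, wave_b, scenario.spec, scenario.outcome, **kw)
        assert c1["D"] == c2["D"] and c1["E"] == c2["E"] and c1["C"] == c2["C"]
        np.testing.assert_array_equal(c1["E_k"], c2["E_k"])

    def test_point_estimates_inside_intervals(self, small_mixed_waves):
        scenario, wave_a, wave_b = small_mixed_waves
        res = decompose(
            wave_a, wave_b, scenario.spec, scenario.outcome, reps=150, seed=8
        )
        assert res.ci["D"][0] <= res.D <= res.ci["D"][1]
        assert res.ci["E"][0] <= res.E <= res.ci["E"][1]
        assert res.ci["C"][0] <= res.C <= res.ci["C"][1]

    def test_too_few_reps_rejected(self, small_mixed_waves):
        scenario, wave_a, wave_b = small_mixed_waves
        from bmidecomp.core_records import ConfigurationError

        with pytest.raises(ConfigurationError):
            bootstrap_ci(wave_a, wave_b, scenario.spec, scenario.outcome, reps=50)

    def test_null_coefficients_component_covered(self):
        """With truth C = 0 (composition shift only), the bootstrap C
        interval brackets zero in >= 90% of seeded runs."""
        scenario = make_scenario("composition_shift_only", n=5000)
        hits = 0
        runs = 10
        for s in range(runs):
            wave_a, _ = apply_exclusions(generate_wave(scenario, "a", 300 + s))
            wave_b, _ = apply_exclusions(generate_wave(scenario, "b", 300 + s))
            ci = bootstrap_ci(
                wave_a, wave_b, scenario.spec, scenario.outcome,
                reps=200, seed=s,
            )
            lo, hi = ci["C"]
            hits += lo <= 0.0 <= hi
        assert hits >= 0.9 * runs
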