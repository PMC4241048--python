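"""The core estimator: cell log-odds, missing-cell probabilities, arm
probabilities, effect scales, and the orchestrated fit."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

import imorsens as im
from imorsens.errors import DegenerateEffectError, InestimableCellError
from imorsens.sensitivity_model import estimate_observed_log_odds
from imorsens.trial_data import CellCounts, TrialTable

from conftest import random_table

INF = math.inf


def _estimates(table, **kwargs):
    return {
        k: estimate_observed_log_odds(c, cell_id=k, **kwargs)
        for k, c in table.cells.items()
        if c.n_obs > 0
    }


class TestObservedLogOdds:
    def test_worked_example_value(self):
        est = estimate_observed_log_odds(CellCounts(41, 24, 66), cell_id=(0, 1))
        assert round(est.log_odds, 3) == 0.536
        assert est.variance == pytest.approx(1 / 41 + 1 / 24, rel=1e-12)

    def test_symmetric_cell_is_zero(self):
        est = estimate_observed_log_odds(CellCounts(17, 17, 5))
        assert est.log_odds == 0.0

    def test_direct_arithmetic(self):
        est = estimate_observed_log_odds(CellCounts(230, 56, 460))
        assert est.log_odds == pytest.approx(math.log(230 / 56), rel=1e-14)
        assert est.variance == pytest.approx(1 / 230 + 1 / 56, rel=1e-14)

    @pytest.mark.parametrize("cell", [CellCounts(0, 10, 3), CellCounts(10, 0, 3)])
    def test_boundary_cell_errors_by_default(self, cell):
        with pytest.raises(InestimableCellError, match="boundary"):
            estimate_observed_log_odds(cell, cell_id=(0, 1))

    def test_continuity_correction_adds_half_to_both_counts(self):
        est = estimate_observed_log_odds(
            CellCounts(0, 10, 3), continuity_correction=True
        )
        assert est.log_odds == pytest.approx(math.log(0.5 / 10.5))
        assert est.variance == pytest.approx(1 / 0.5 + 1 / 10.5)

    def test_empty_observed_cell_errors(self):
        with pytest.raises(InestimableCellError):
            estimate_observed_log_odds(CellCounts(0, 0, 12))


class TestCellProbability:
    def test_worked_example_missing_cells(self):
        b1 = float(logit(41 / 65))
        assert round(100 * im.cell_probability(b1, 1.0, observed=False)) == 82
        b3 = float(logit(230 / 286))
        assert round(100 * im.cell_probability(b3, 1.0, observed=False)) == 92

    @pytest.mark.parametrize(
        "log_imor,expected", [(INF, 1.0), (-INF, 0.0)]
    )
    def test_infinite_limits_are_exact(self, log_imor, expected):
        assert im.cell_probability(0.7, log_imor, observed=False) == expected

    @given(st.floats(-5, 5))
    def test_zero_log_imor_matches_observed(self, log_odds):
        assert im.cell_probability(log_odds, 0.0, observed=False) == pytest.approx(
            im.cell_probability(log_odds, 123.0, observed=True)
        )

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            im.cell_probability(0.0, math.nan, observed=False)
        with pytest.raises(ValueError):
            im.cell_probability(math.inf, 0.0, observed=True)


class TestArmProbability:
    def test_worked_example_arm(self, iquit_treatment_table):
        params = im.SensitivityParameters.with_x(1, 1, 0, 0)
        p1 = im.arm_probability(
            iquit_treatment_table, 1, _estimates(iquit_treatment_table), params
        )
        assert round(p1, 2) == 0.85

    def test_complete_data_reduces_to_observed_proportion(self):
        cells = {
            (0, 1): CellCounts(30, 20, 0),
            (1, 1): CellCounts(10, 40, 0),
            (0, 0): CellCounts(25, 25, 0),
            (1, 0): CellCounts(5, 45, 0),
        }
        table = TrialTable(cells, has_x=True)
        p = im.arm_probability(table, 1, _estimates(table), im.SensitivityParameters.mar())
        assert p == pytest.approx(40 / 100, rel=1e-12)

    def test_matches_enumeration_over_cells(self):
        """Weighted cell enumeration oracle: explicit per-participant
        expectation over every (cell, response status) group."""
        rng = np.random.default_rng(5)
        table = random_table(rng)
        params = im.SensitivityParameters.with_x(*rng.normal(0, 1, size=4))
        ests = _estimates(table)
        for z in (0, 1):
            expected = 0.0
            for key in table.arm_keys(z):
                c = table.cells[key]
                p_obs = c.n_event_obs / c.n_obs
                q = float(expit(logit(p_obs) + params.for_cell(*key)))
                expected += c.n_obs * p_obs + c.n_miss * q
            expected /= table.arm_total(z)
            got = im.arm_probability(table, z, ests, params)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_empty_arm_errors(self, iquit_treatment_table):
        with pytest.raises(InestimableCellError, match="arm"):
            im.arm_probability(
                iquit_treatment_table,
                0,
                _estimates(iquit_treatment_table),
                im.SensitivityParameters.mar(),
            )

    def test_missing_only_cell_requires_infinite_log_imor(self):
        cells = {
            (0, 1): CellCounts(0, 0, 30),
            (1, 1): CellCounts(20, 10, 5),
            (0, 0): CellCounts(15, 15, 0),
            (1, 0): CellCounts(10, 20, 0),
        }
        table = TrialTable(cells, has_x=True)
        ests = _estimates(table)
        forced = im.SensitivityParameters.with_x(INF, 0, 0, 0)
        p = im.arm_probability(table, 1, ests, forced)
        # 30 forced events, 20 observed events, 5 missing at the observed
        # rate 20/30 in the (1, 1) cell
        assert p == pytest.approx((30 + 20 + 5 * (20 / 30)) / 65, rel=1e-12)
        with pytest.raises(InestimableCellError):
            im.arm_probability(table, 1, ests, im.SensitivityParameters.mar())


class TestInterventionEffect:
    @pytest.mark.parametrize("scale", list(im.EffectScale))
    def test_null_effect(self, scale):
        assert im.intervention_effect(0.3, 0.3, scale) == pytest.approx(0.0)

    def test_closed_forms(self):
        assert im.intervention_effect(
            0.25, 0.5, im.EffectScale.LOG_ODDS_RATIO
        ) == pytest.approx(math.log(1 / 3), rel=1e-12)
        assert im.intervention_effect(
            0.25, 0.5, im.EffectScale.RISK_DIFFERENCE
        ) == pytest.approx(-0.25, rel=1e-12)
        assert im.intervention_effect(
            0.25, 0.5, im.EffectScale.LOG_RELATIVE_RISK
        ) == pytest.approx(math.log(0.5), rel=1e-12)

    def test_boundary_errors(self):
        with pytest.raises(DegenerateEffectError):
            im.intervention_effect(1.0, 0.5, im.EffectScale.LOG_ODDS_RATIO)
        with pytest.raises(DegenerateEffectError):
            im.intervention_effect(0.2, 0.0, im.EffectScale.LOG_RELATIVE_RISK)
        # risk difference is defined on the closed interval
        assert im.intervention_effect(1.0, 0.0, im.EffectScale.RISK_DIFFERENCE) == 1.0


class TestFit:
    def test_no_x_mar_equals_complete_case(self, full_table):
        """Dropping the covariate and assuming MAR must reproduce the
        complete-case 2x2 analysis exactly (point and SE)."""
        res = im.fit(full_table, im.SensitivityParameters.without_x(0, 0))
        cc_est, cc_se = im.complete_case_log_odds_ratio(full_table)
        assert res.estimate == pytest.approx(cc_est, abs=1e-12)
        assert res.se == pytest.approx(cc_se, abs=1e-12)

    def test_no_x_mar_matches_logistic_regression(self, full_table):
        """Cross-check against an independent logistic regression of the
        observed outcomes on arm."""
        import statsmodels.api as sm

        collapsed = full_table.collapse_x()
        rows, y = [], []
        for z in (0, 1):
            c = collapsed.cells[(None, z)]
            rows += [[1.0, float(z)]] * c.n_obs
            y += [1] * c.n_event_obs + [0] * c.n_nonevent_obs
        model = sm.Logit(np.array(y), np.array(rows)).fit(disp=0)
        res = im.fit(full_table, im.SensitivityParameters.without_x(0, 0))
        assert res.estimate == pytest.approx(model.params[1], abs=1e-6)
        assert res.se == pytest.approx(model.bse[1], abs=1e-6)

    def test_no_missing_data_ignores_parameters(self):
        cells = {
            (0, 1): CellCounts(30, 20, 0),
            (1, 1): CellCounts(10, 40, 0),
            (0, 0): CellCounts(25, 25, 0),
            (1, 0): CellCounts(15, 35, 0),
        }
        table = TrialTable(cells, has_x=True)
        base = im.fit(table, im.SensitivityParameters.mar())
        for params in (
            im.SensitivityParameters.with_x(INF, -INF, 2.0, -3.0),
            im.SensitivityParameters.with_x(1, 1, 1, 1),
        ):
            other = im.fit(table, params)
            assert other.estimate == pytest.approx(base.estimate, abs=1e-12)
            assert other.se == pytest.approx(base.se, abs=1e-12)

    def test_all_plus_inf_equals_single_imputation_oracle(self):
        """Imputing every missing outcome as an event and tabulating must
        reproduce the fully-forced fit, point and SE."""
        rng = np.random.default_rng(17)
        table = random_table(rng)
        params = im.SensitivityParameters.with_x(INF, INF, INF, INF)
        res = im.fit(table, params)
        est, se = im.log_odds_ratio_2x2(im.single_impute(table, params))
        assert res.estimate == pytest.approx(est, abs=1e-12)
        assert res.se == pytest.approx(se, abs=1e-12)

    def test_wald_interval_brackets_point(self, full_table):
        res = im.fit(full_table, im.SensitivityParameters.mar(), ci_level=0.9)
        assert res.ci_lower < res.estimate < res.ci_upper
        half = res.estimate - res.ci_lower
        assert half == pytest.approx(res.ci_upper - res.estimate, rel=1e-12)


class TestModelProperties:
    @pytest.mark.parametrize("cell", [(0, 1), (1, 1)])
    def test_arm_probability_monotone_in_each_log_imor(self, full_table, cell):
        grid = [-INF, -2.0, 0.0, 1.5, INF]
        values = []
        for v in grid:
            base = {(0, 1): 0.3, (1, 1): -0.2, (0, 0): 0.0, (1, 0): 0.0}
            base[cell] = v
            res = im.fit(full_table, im.SensitivityParameters(base))
            values.append(res.p_treatment)
        assert all(a < b for a, b in zip(values, values[1:]))  # strict: n_miss > 0

    def test_large_finite_converges_to_symbolic_infinity(self, full_table):
        """Fits at +/-20 on the log scale are already indistinguishable
        from the symbolic limits."""
        m = 20.0
        for signs in [(1, 1, 1, 1), (-1, 1, -1, 1)]:
            inf_params = im.SensitivityParameters.with_x(*(s * INF for s in signs))
            big_params = im.SensitivityParameters.with_x(*(s * m for s in signs))
            res_inf = im.fit(full_table, inf_params)
            res_big = im.fit(full_table, big_params)
            assert res_big.estimate == pytest.approx(res_inf.estimate, abs=1e-6)
            assert res_big.se == pytest.approx(res_inf.se, abs=1e-6)

    def test_mar_with_x_equals_stratified_mar_analysis(self, full_table):
        """Log IMORs of zero give each cell its observed event rate, i.e.
        the MAR-given-(x, z) analysis."""
        res = im.fit(full_table, im.SensitivityParameters.mar())
        expected = {}
        for z in (0, 1):
            num = sum(
                full_table.cells[k].n_total
                * full_table.cells[k].n_event_obs
                / full_table.cells[k].n_obs
                for k in full_table.arm_keys(z)
            )
            expected[z] = num / full_table.arm_total(z)
        assert res.p_treatment == pytest.approx(expected[1], rel=1e-12)
        assert res.p_control == pytest.approx(expected[0], rel=1e-12)

    @pytest.mark.parametrize(
        "scale", [im.EffectScale.LOG_ODDS_RATIO, im.EffectScale.RISK_DIFFERENCE]
    )
    def test_arm_relabelling_negates_effect(self, full_table, scale):
        params = im.SensitivityParameters.with_x(0.5, -INF, 1.0, 2.0)
        res = im.fit(full_table, params, scale)
        swapped_cells = {
            (x, 1 - z): c for (x, z), c in full_table.cells.items()
        }
        swapped = im.fit(
            TrialTable(swapped_cells, has_x=True), params.swap_arms(), scale
        )
        assert swapped.estimate == pytest.approx(-res.estimate, abs=1e-12)
        assert swapped.se == pytest.approx(res.se, abs=1e-12)

    @given(
        st.tuples(*(st.floats(-2, 2) for _ in range(4))),
    )
    def test_scales_agree_in_sign(self, log_imors):
        cells = {
            (0, 1): CellCounts(41, 24, 66),
            (1, 1): CellCounts(230, 56, 460),
            (0, 0): CellCounts(50, 30, 40),
            (1, 0): CellCounts(180, 90, 300),
        }
        table = TrialTable(cells, has_x=True)
        params = im.SensitivityParameters.with_x(*log_imors)
        signs = {
            math.copysign(1.0, im.fit(table, params, scale).estimate)
            for scale in im.EffectScale
        }
        assert len(signs) == 1
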