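"""Kaplan-Meier, log-rank, and Cox regression.

lifelines serves as the independent oracle for the Cox fits and the
multi-group log-rank test; the classical score-test/log-rank identity
cross-checks the two implementations against each other.
"""

import numpy as np
import pandas as pd
import pytest

from splicestrat.errors import (
    ConvergenceError,
    DataError,
    DesignError,
    UsageError,
)
from splicestrat.survival import (
    CoxResult,
    collapse_stage,
    cox_fit,
    cox_score_test,
    forest_plot,
    forest_table,
    km_estimate,
    km_plot,
    logrank_test,
    significance_stars,
    make_design,
)


def simulate_cohort_data(rng, n=300, beta=np.log(2), censor_rate=0.3):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / np.exp(beta * x))
    c = rng.exponential(1.0 / censor_rate, n)
    return np.minimum(t, c), (t <= c).astype(int), x


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at 2 and 6, censoring at 4: S = (1 - 1/3) then * (1 - 1/1)
        km = km_estimate([2, 4, 6], [1, 0, 1])
        assert list(km.times) == [2, 6]
        assert km.surv == pytest.approx([2 / 3, 0.0])
        assert list(km.at_risk) == [3, 1]
        assert km.survival_at(1.9) == 1.0
        assert km.survival_at(4.5) == pytest.approx(2 / 3)

    def test_all_censored_is_flat_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        for _ in range(10):
            t = rng.exponential(size=40)
            km = km_estimate(t, np.ones_like(t))
            for u in km.times:
                assert km.survival_at(u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_tied_censoring_stays_at_risk(self):
        # censored at the event time counts in that risk set: d/n = 1/2
        km = km_estimate([5, 5], [1, 0])
        assert km.surv == pytest.approx([0.5])

    def test_empty_and_negative_rejected(self):
        with pytest.raises(UsageError):
            km_estimate([], [])
        with pytest.raises(DataError):
            km_estimate([-1.0], [1])


class TestLogrank:
    def test_hand_example(self):
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert res.statistic == pytest.approx(49 / 17, abs=1e-12)
        assert res.observed[0] == 2 and res.expected[0] == pytest.approx(5 / 6)

    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5, 6]
        res = logrank_test(t + t, [1] * 12, ["A"] * 6 + ["B"] * 6)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_symmetry(self, rng):
        time, event, x = simulate_cohort_data(rng, n=80)
        a = logrank_test(time, event, x)
        b = logrank_test(time, event, 1 - x)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_all_censored_warns_p_one(self):
        with pytest.warns(UserWarning, match="no usable events"):
            res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])
        assert res.p_value == 1.0

    def test_three_groups_matches_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        n = 120
        g = rng.integers(0, 3, n)
        t = rng.exponential(1.0 / np.exp(0.3 * g))
        c = rng.exponential(2.0, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        ours = logrank_test(time, event, g)
        ref = multivariate_logrank_test(time, g, event)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.df == 2


class TestCox:
    def test_matches_lifelines_continuous_and_binary(self, rng):
        from lifelines import CoxPHFitter

        n = 250
        X = pd.DataFrame(
            {"binary": rng.integers(0, 2, n).astype(float), "cont": rng.normal(size=n)}
        )
        eta = 0.6 * X["binary"] - 0.4 * X["cont"]
        t = rng.exponential(1.0 / np.exp(eta))
        c = rng.exponential(2.0, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        fit = cox_fit(time, event, X)
        df = X.assign(T=time, E=event)
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.coefs.values, ref.params_.values, atol=1e-5)
        assert np.allclose(
            fit.summary["se"].values, ref.standard_errors_.values, atol=1e-5
        )

    def test_efron_handles_ties_like_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        x = rng.integers(0, 2, n).astype(float)
        # heavy ties: discrete event times
        t = np.ceil(rng.exponential(3.0 / np.exp(0.7 * x)))
        event = rng.random(n) < 0.8
        fit = cox_fit(t, event.astype(int), pd.DataFrame({"x": x}), ties="efron")
        ref = CoxPHFitter().fit(
            pd.DataFrame({"T": t, "E": event.astype(int), "x": x}), "T", "E"
        )
        assert fit.coefs["x"] == pytest.approx(ref.params_["x"], abs=1e-5)

    def test_breslow_equals_efron_without_ties(self, rng):
        time, event, x = simulate_cohort_data(rng, n=120)
        X = pd.DataFrame({"x": x})
        assert cox_fit(time, event, X, ties="efron").coefs["x"] == pytest.approx(
            cox_fit(time, event, X, ties="breslow").coefs["x"], abs=1e-10
        )

    def test_covariate_scaling_equivariance(self, rng):
        n = 200
        z = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * z))
        event = np.ones(n, dtype=int)
        b1 = cox_fit(t, event, pd.DataFrame({"z": z})).coefs["z"]
        b10 = cox_fit(t, event, pd.DataFrame({"z": 10 * z})).coefs["z"]
        assert b10 == pytest.approx(b1 / 10, rel=1e-6)

    def test_score_at_solution_near_zero(self, rng):
        time, event, x = simulate_cohort_data(rng)
        fit = cox_fit(time, event, pd.DataFrame({"x": x}))
        assert fit.converged and fit.score_norm < 1e-6

    def test_constant_column_rejected(self, rng):
        time, event, _ = simulate_cohort_data(rng, n=30)
        with pytest.raises(DesignError, match="constant"):
            cox_fit(time, event, pd.DataFrame({"zeros": np.zeros(30)}))

    def test_complete_separation_detected(self):
        # x=1 fails first: partial likelihood is monotone in beta
        with pytest.raises(ConvergenceError, match="separation|diverged"):
            cox_fit([1.0, 2.0], [1, 1], pd.DataFrame({"x": [1.0, 0.0]}))

    def test_no_events_rejected(self):
        with pytest.raises(UsageError):
            cox_fit([1.0, 2.0], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))

    def test_score_test_equals_logrank(self, rng):
        for _ in range(5):
            time, event, x = simulate_cohort_data(rng, n=60)
            chi2, _ = cox_score_test(time, event, x.reshape(-1, 1))
            ref = logrank_test(time, event, x).statistic
            assert chi2 == pytest.approx(ref, abs=1e-8)


class TestDesignHelpers:
    def test_collapse_stage(self):
        s = pd.Series(
            ["Stage I", "Stage II", "Stage III", "Stage IVB", "stage ia", None]
        )
        out = collapse_stage(s)
        assert list(out[:5]) == ["early", "early", "advanced", "advanced", "early"]
        assert pd.isna(out[5])

    def test_make_design_one_hot_and_complete_case(self):
        df = pd.DataFrame(
            {
                "age": [50, 60, None, 70],
                "race": ["AA", "EA", "EA", "AA"],
            }
        )
        design = make_design(df, continuous=["age"], categorical={"race": "EA"})
        assert list(design.columns) == ["age", "race[AA]"]
        assert len(design) == 3  # complete-case drop
        assert list(design["race[AA]"]) == [1.0, 0.0, 1.0]

    def test_missing_reference_level_rejected(self):
        df = pd.DataFrame({"race": ["AA", "EA"]})
        with pytest.raises(DesignError):
            make_design(df, categorical={"race": "XX"})


class TestForestTable:
    def make_result(self, p=0.0322):
        summary = pd.DataFrame(
            {
                "covariate": ["group[low]"],
                "coef": [np.log(1.65)],
                "se": [0.234],
                "hr": [1.65],
                "ci_low": [1.04],
                "ci_high": [2.61],
                "p": [p],
            }
        )
        return CoxResult(
            summary=summary, ties="efron", n=100, n_events=40,
            converged=True, n_iter=5, log_likelihood=-100.0, score_norm=1e-10,
        )

    def test_single_row_one_star(self):
        # HR 1.65, CI 1.04-2.61, p = 0.0322 formats as one significant star
        table = forest_table(self.make_result())
        row = table.iloc[0]
        assert (row["hr"], row["ci_low"], row["ci_high"]) == (1.65, 1.04, 2.61)
        assert row["stars"] == "*"

    def test_nonsignificant_row_no_stars(self):
        assert forest_table(self.make_result(p=0.2)).iloc[0]["stars"] == ""

    def test_reference_row(self):
        table = forest_table(self.make_result(), reference_rows=[("group", "high")])
        ref = table[table["reference"]].iloc[0]
        assert ref["hr"] == 1.0 and np.isnan(ref["ci_low"]) and ref["stars"] == ""

    def test_non_converged_refused(self):
        res = self.make_result()
        res.converged = False
        with pytest.raises(UsageError, match="non-converged"):
            forest_table(res)

    @pytest.mark.parametrize(
        "p,stars",
        [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****"), (0.06, "")],
    )
    def test_star_tiers(self, p, stars):
        assert significance_stars(p) == stars


def test_plot_smoke(tmp_path, rng):
    time, event, x = simulate_cohort_data(rng, n=40)
    curves = {
        "x=0": km_estimate(time[x == 0], event[x == 0]),
        "x=1": km_estimate(time[x == 1], event[x == 1]),
    }
    km_path = tmp_path / "km.png"
    km_plot(curves, km_path, title="toy")
    fit = cox_fit(time, event, pd.DataFrame({"x": x}))
    forest_path = tmp_path / "forest.png"
    forest_plot(forest_table(fit), forest_path)
    assert km_path.stat().st_size > 0 and forest_path.stat().st_size > 0
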