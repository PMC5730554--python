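import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter

from riskrecal.gndd import (
    ConfigurationError,
    DataError,
    DegenerateDataError,
    assign_deciles,
    calibration_summary,
    format_p,
    gnd_chi_squared,
    gndd_test,
    km_at,
)


def toy_cohort(times, events, risks=None):
    n = len(times)
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": 50.0, "bmi": 24.0, "sbp": 140.0, "heart_rate": 70.0,
        "cholesterol": 6.0, "ex_smoker": 0, "smoker": 0,
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "population": "toy",
    })
    return df


class TestKaplanMeier:
    def test_hand_product_limit_no_censoring(self):
        """10 subjects, 3 events before t: S = (9/10)(8/9)(7/8) = 0.7 and
        Greenwood variance equals the binomial 0.7*0.3/10 = 0.021."""
        times = [1, 2, 3] + [20] * 7
        events = [1, 1, 1] + [1] * 7
        surv, var = km_at(times, events, t=10.0)
        assert surv == pytest.approx(0.7)
        assert var == pytest.approx(0.021)

    def test_before_first_event(self):
        surv, var = km_at([5, 6, 7], [1, 1, 1], t=1.0)
        assert (surv, var) == (1.0, 0.0)

    def test_hand_example_with_censoring(self):
        """Censor at 1, event at 2 with 2 at risk, one survivor: S(3) = 0.5."""
        surv, _ = km_at([1, 2, 3], [0, 1, 0], t=3.0)
        assert surv == pytest.approx(0.5)

    def test_empty_input(self):
        with pytest.raises(DataError):
            km_at([], [], t=1.0)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_censor_free_equals_empirical_fraction(self, data):
        """Without censoring, the product-limit estimate collapses to the
        empirical survival fraction and Greenwood to binomial variance."""
        n = data.draw(st.integers(5, 40))
        times = data.draw(
            st.lists(st.integers(1, 20), min_size=n, max_size=n).map(
                lambda xs: np.asarray(xs, float)
            )
        )
        t = data.draw(st.floats(0.5, 21.0))
        surv, var = km_at(times, np.ones(n, dtype=int), t)
        frac = float((times > t).mean())
        assert surv == pytest.approx(frac, abs=1e-12)
        assert var == pytest.approx(frac * (1 - frac) / n, abs=1e-12)

    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_lifelines_with_censoring(self, data):
        """Independent cross-check of the survival curve against the
        lifelines Kaplan-Meier implementation on censored samples."""
        n = data.draw(st.integers(5, 40))
        times = np.asarray(data.draw(
            st.lists(st.integers(1, 15), min_size=n, max_size=n)), float)
        events = np.asarray(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)), int)
        t = 8.0
        surv, _ = km_at(times, events, t)
        kmf = KaplanMeierFitter().fit(times, events)
        assert surv == pytest.approx(
            float(kmf.predict(t)), abs=1e-9
        )


class TestDecileAssignment:
    def test_equal_groups(self):
        labels = assign_deciles(np.random.default_rng(0).random(100), 10)
        assert np.bincount(labels).tolist() == [10] * 10

    def test_identical_risks_stay_balanced(self):
        labels = assign_deciles(np.full(50, 0.3), 5)
        assert np.bincount(labels).tolist() == [10] * 5

    def test_quantile_boundaries(self):
        """Risks 1..20 into quartiles: boundaries at 5/10/15."""
        labels = assign_deciles(np.arange(1, 21), 4)
        for g in range(4):
            assert (np.flatnonzero(labels == g) == np.arange(5 * g, 5 * g + 5)).all()

    def test_ordering_by_risk(self):
        rng = np.random.default_rng(1)
        risks = rng.random(200)
        labels = assign_deciles(risks, 10)
        means = [risks[labels == g].mean() for g in range(10)]
        assert (np.diff(means) > 0).all()

    @pytest.mark.parametrize("n, D", [(5, 10), (10, 1)])
    def test_bad_configuration(self, n, D):
        with pytest.raises(ConfigurationError):
            assign_deciles(np.ones(n), D)


class TestGNDStatistic:
    def test_two_group_hand_arithmetic(self):
        """(0.30-0.20)^2/0.021 + (0.50-0.60)^2/0.025 = 0.87619 on 1 df."""
        chi2, df, p = gnd_chi_squared([0.30, 0.50], [0.20, 0.60], [0.021, 0.025])
        assert chi2 == pytest.approx(0.01 / 0.021 + 0.01 / 0.025)
        assert df == 1
        assert p == pytest.approx(0.349, abs=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            gnd_chi_squared([0.3, 0.5], [0.3, 0.5], [0.02, 0.0])


class TestGNDDTest:
    def perfect_cohort(self):
        """Two risk strata whose predicted risk equals the exact observed
        event fraction (no censoring)."""
        times, events, risks = [], [], []
        for frac, n in ((0.2, 100), (0.4, 100)):
            k = int(frac * n)
            times += [5.0] * k + [25.0] * (n - k)
            events += [1] * k + [0] * (n - k)
            risks += [frac] * n
        return toy_cohort(times, events), np.asarray(risks)

    def test_perfect_calibration_gives_zero_chi2(self):
        cohort, risks = self.perfect_cohort()
        res = gndd_test(cohort, risks, horizon=25.0, D=2, min_events=5)
        assert res.chi_squared == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.degrees_of_freedom == 1

    def test_mean_identities(self, ne_cohort, ne_fit):
        from riskrecal import predict_risk

        risks = predict_risk(ne_fit, ne_cohort)
        res = gndd_test(ne_cohort, risks)
        assert res.mean_expected == pytest.approx(float(np.mean(risks)), abs=1e-12)
        w = res.rows["n"] / res.rows["n"].sum()
        assert res.mean_observed == pytest.approx(
            float((w * res.rows["observed_risk"]).sum()), abs=1e-12
        )
        assert res.rows["mean_predicted"].is_monotonic_increasing

    def test_row_permutation_invariance(self, ne_cohort, ne_fit):
        """Reordering subjects (with their risks) leaves the statistic
        untouched: grouping depends only on the risk ranking."""
        from riskrecal import predict_risk

        risks = predict_risk(ne_fit, ne_cohort)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(ne_cohort))
        res1 = gndd_test(ne_cohort, risks)
        res2 = gndd_test(ne_cohort.iloc[perm].reset_index(drop=True), risks[perm])
        assert res2.chi_squared == pytest.approx(res1.chi_squared, rel=1e-9)
        assert res2.p_value == pytest.approx(res1.p_value, rel=1e-9)

    def test_sparse_groups_are_merged(self):
        """A stratum with a single event cannot stand alone: it is merged
        into its higher-risk neighbour, reducing the degrees of freedom."""
        times, events, risks = [], [], []
        rng = np.random.default_rng(5)
        for g, (frac, n) in enumerate(((0.01, 100), (0.3, 100), (0.5, 100))):
            k = max(1, int(frac * n))
            times += [float(rng.uniform(1, 20)) for _ in range(k)] + [25.0] * (n - k)
            events += [1] * k + [0] * (n - k)
            risks += list(0.1 * g + rng.uniform(0, 0.05, n))
        res = gndd_test(toy_cohort(times, events), np.asarray(risks),
                        horizon=25.0, D=3, min_events=5)
        assert len(res.rows) == 2
        assert res.degrees_of_freedom == 1
        assert (res.rows["events"] >= 5).all()

    def test_misaligned_risks(self, ne_cohort):
        with pytest.raises(DataError):
            gndd_test(ne_cohort, np.ones(10))

    def test_power_against_transported_wrong_s0(self, ne_cohort, ne_fit):
        """A three-fold understated baseline risk is rejected outright."""
        from riskrecal import predict_risk
        from riskrecal.cox import CoxComponents

        wrong = CoxComponents(
            coefficients=ne_fit.coefficients, means=ne_fit.means,
            s0=ne_fit.s0 ** (1 / 3), horizon=ne_fit.horizon,
            source_label="wrong-s0",
        )
        res = gndd_test(ne_cohort, predict_risk(wrong, ne_cohort))
        assert res.p_value < 1e-6


class TestSummary:
    def test_all_groups_equal_gives_unit_ratio(self):
        cohort, risks = TestGNDDTest().perfect_cohort()
        res = gndd_test(cohort, np.full(len(cohort), 0.3), D=2, min_events=5)
        assert res.decile_ratio == pytest.approx(1.0)

    def test_summary_fields(self, ne_cohort, ne_fit):
        from riskrecal import predict_risk

        res = gndd_test(ne_cohort, predict_risk(ne_fit, ne_cohort))
        row = calibration_summary(res, model="SELF", population="NE")
        assert row["decile_ratio"] == pytest.approx(
            row["decile_10"] / row["decile_1"]
        )
        assert row["p_value"] == res.p_value

    @pytest.mark.parametrize(
        "p, rendered", [(0.72961, "0.7296"), (9.9e-5, "<0.0001"), (0.0178, "0.0178")]
    )
    def test_p_value_rendering(self, p, rendered):
        assert format_p(p) == rendered
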