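"""The statistic suite, external-validation criteria, split and ARD report.

Every statistic is checked against an independently coded brute-force
implementation (explicit Python loops over the defining sums).
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import r2_score

from iltox.metrics import (
    ARD_BIN_LABELS,
    MetricSet,
    PredictionSet,
    aard_pct,
    adjusted_r_squared,
    ard_histogram,
    ard_pct,
    compute_metrics,
    r_squared,
    rmse,
    slopes_and_r0,
    split_train_test,
    tropsha_check,
    validation_report,
)

# ---------------------------------------------------------------- oracles


def oracle_r2(y_exp, y_cal):
    ym = sum(y_exp) / len(y_exp)
    sst = sum((e - ym) ** 2 for e in y_exp)
    sse = sum((c - e) ** 2 for c, e in zip(y_cal, y_exp))
    return (sst - sse) / sst


def oracle_aard(y_exp, y_cal):
    return 100.0 * sum(abs((c - e) / e) for c, e in zip(y_cal, y_exp)) / len(y_exp)


def oracle_rmse(y_exp, y_cal):
    return (sum((c - e) ** 2 for c, e in zip(y_cal, y_exp)) / len(y_exp)) ** 0.5


def oracle_slopes_r0(y_exp, y_cal):
    """Through-origin regressions done longhand."""
    sec = sum(e * c for e, c in zip(y_exp, y_cal))
    k = sec / sum(c * c for c in y_cal)
    kp = sec / sum(e * e for e in y_exp)
    cm = sum(y_cal) / len(y_cal)
    em = sum(y_exp) / len(y_exp)
    r0 = 1 - sum((c - kp * e) ** 2 for c, e in zip(y_cal, y_exp)) \
        / sum((c - cm) ** 2 for c in y_cal)
    r0p = 1 - sum((e - k * c) ** 2 for c, e in zip(y_cal, y_exp)) \
        / sum((e - em) ** 2 for e in y_exp)
    return k, kp, r0, r0p


def random_ps(rng, n=None):
    n = n or int(rng.integers(10, 101))
    y_exp = rng.uniform(0.5, 6.0, n)
    y_cal = y_exp + rng.normal(scale=0.3, size=n)
    return PredictionSet(y_exp, y_cal)


# ---------------------------------------------------------------- units


class TestRSquared:
    def test_perfect_predictions(self, rng):
        ps = PredictionSet(rng.uniform(1, 5, 10), np.zeros(10))
        ps.y_cal = ps.y_exp.copy()
        assert r_squared(ps) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self, rng):
        y = rng.uniform(1, 5, 10)
        ps = PredictionSet(y, np.full(10, y.mean()))
        assert r_squared(ps) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_and_sklearn(self, rng):
        ps = random_ps(rng, 10)
        got = r_squared(ps)
        assert got == pytest.approx(oracle_r2(ps.y_exp, ps.y_cal), rel=1e-12)
        assert got == pytest.approx(r2_score(ps.y_exp, ps.y_cal), rel=1e-10)


class TestAdjustedR2:
    def test_zero_predictors_leave_r2_unchanged(self):
        assert adjusted_r_squared(0.85, 50, 0) == pytest.approx(0.85)

    def test_perfect_fit_stays_one(self):
        assert adjusted_r_squared(1.0, 30, 11) == pytest.approx(1.0)

    def test_hand_worked_value(self):
        # 1 - (1-0.9)*99/88
        assert adjusted_r_squared(0.9, 100, 11) == pytest.approx(1 - 0.1 * 99 / 88)

    def test_degenerate_dof_raises(self):
        with pytest.raises(ValueError):
            adjusted_r_squared(0.9, 10, 9)


class TestDeviationMetrics:
    def test_five_percent_overshoot(self, rng):
        y = rng.uniform(1, 5, 20)
        assert aard_pct(PredictionSet(y, 1.05 * y)) == pytest.approx(5.0)

    def test_perfect_predictions_zero(self, rng):
        y = rng.uniform(1, 5, 20)
        assert aard_pct(PredictionSet(y, y.copy())) == 0.0
        assert rmse(PredictionSet(y, y.copy())) == 0.0

    def test_constant_error_rmse(self, rng):
        y = rng.uniform(1, 5, 20)
        assert rmse(PredictionSet(y, y - 0.7)) == pytest.approx(0.7)

    def test_ard_scalars(self):
        assert ard_pct(1.03, 1.0) == pytest.approx(3.0)
        assert ard_pct(0.9, 1.0) == pytest.approx(10.0)

    def test_ard_vector_consistent_with_aard(self, rng):
        ps = random_ps(rng)
        ards = ard_pct(ps.y_cal, ps.y_exp)
        assert aard_pct(ps) == pytest.approx(np.mean(ards), rel=1e-12)

    def test_near_zero_experimental_values_excluded(self, caplog):
        ps = PredictionSet(np.array([2.0, 1e-15, 4.0]),
                           np.array([2.2, 5.0, 4.4]))
        with caplog.at_level("INFO"):
            val = aard_pct(ps)
        assert val == pytest.approx(oracle_aard([2.0, 4.0], [2.2, 4.4]))


class TestSlopesAndR0:
    def test_identity_predictions(self, rng):
        y = rng.uniform(1, 5, 15)
        k, kp, r0, r0p = slopes_and_r0(PredictionSet(y, y.copy()))
        assert (k, kp) == (pytest.approx(1.0), pytest.approx(1.0))
        assert (r0, r0p) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_doubled_predictions_hand_algebra(self, rng):
        y = rng.uniform(1, 5, 15)
        k, kp, _, _ = slopes_and_r0(PredictionSet(y, 2 * y))
        assert k == pytest.approx(0.5)
        assert kp == pytest.approx(2.0)

    def test_matches_through_origin_oracle(self, rng):
        ps = random_ps(rng)
        got = slopes_and_r0(ps)
        exp = oracle_slopes_r0(ps.y_exp.tolist(), ps.y_cal.tolist())
        np.testing.assert_allclose(got, exp, rtol=1e-10)

    def test_as_printed_mode_collapses_to_slope_functions(self, rng):
        # the literal closed forms scale a variable by its own slope
        ps = random_ps(rng)
        k, kp, r0, r0p = slopes_and_r0(ps, mode="as_printed")
        c = ps.y_cal
        lit = 1 - ((c - k * c) ** 2).sum() / ((c - c.mean()) ** 2).sum()
        assert r0 == pytest.approx(lit, rel=1e-12)


class TestTropsha:
    def test_perfect_predictions_pass(self, rng):
        y = rng.uniform(1, 5, 20)
        m = compute_metrics(PredictionSet(y, y.copy()))
        res = tropsha_check(m.r2, m.k, m.k_prime, m.r0_sq, m.r0_prime_sq)
        assert res.overall

    def test_low_r2_fails_first_criterion(self):
        res = tropsha_check(0.6, 1.0, 1.0, 0.99, 0.99)
        assert not res.passes["r2_above_0.7"]
        assert not res.overall

    def test_reported_mlr_test_set_statistics_all_pass(self):
        # printed external-validation quantities of the linear model's test set
        res = tropsha_check(r2=0.914, k=0.9876, k_prime=1.0058,
                            r0_sq=0.9975, r0_prime_sq=0.9996)
        assert res.overall
        assert res.quantities["(r2-r0_sq)/r2"] < 0.1
        assert res.quantities["|r0_sq-r0_prime_sq|"] < 0.3

    def test_improving_predictions_never_flips_pass_to_fail(self, rng):
        # move y_cal toward y_exp along the segment; a passing set stays passing
        for trial in range(50):
            ps = random_ps(rng, 30)
            m = compute_metrics(ps)
            if not tropsha_check(m.r2, m.k, m.k_prime, m.r0_sq,
                                 m.r0_prime_sq).overall:
                continue
            for t in np.linspace(0.1, 1.0, 10):
                mid = PredictionSet(ps.y_exp,
                                    ps.y_cal + t * (ps.y_exp - ps.y_cal))
                mm = compute_metrics(mid)
                assert tropsha_check(mm.r2, mm.k, mm.k_prime, mm.r0_sq,
                                     mm.r0_prime_sq).overall


class TestARDHistogram:
    def test_all_perfect_in_first_range(self, rng):
        y = rng.uniform(1, 5, 12)
        h = ard_histogram(PredictionSet(y, y.copy()))
        assert h["percent"].tolist() == [100.0, 0.0, 0.0, 0.0]

    def test_constructed_quartiles(self):
        y_exp = np.ones(4)
        y_cal = np.array([1.005, 1.03, 1.07, 1.12])  # ARD 0.5 / 3 / 7 / 12 %
        h = ard_histogram(PredictionSet(y_exp, y_cal))
        assert h["count"].tolist() == [1, 1, 1, 1]
        assert h["percent"].tolist() == [25.0, 25.0, 25.0, 25.0]
        assert list(h["range"]) == list(ARD_BIN_LABELS)

    def test_percentages_sum_to_100(self, rng):
        for _ in range(20):
            h = ard_histogram(random_ps(rng))
            assert h["percent"].sum() == pytest.approx(100.0, abs=0.05)
            assert h["count"].sum() == h["count"].sum()  # integers, no drops


class TestSplit:
    def test_160_samples_split_128_32(self):
        df = pd.DataFrame({"x": np.arange(160.0)})
        train, test = split_train_test(df, 0.8, seed=4)
        assert (len(train), len(test)) == (128, 32)
        assert set(train.index).isdisjoint(test.index)
        assert len(set(train.index) | set(test.index)) == 160

    def test_same_seed_same_split(self):
        df = pd.DataFrame({"x": np.arange(50.0)})
        t1, _ = split_train_test(df, 0.8, seed=9)
        t2, _ = split_train_test(df, 0.8, seed=9)
        assert t1.index.tolist() == t2.index.tolist()
        t3, _ = split_train_test(df, 0.8, seed=10)
        assert t1.index.tolist() != t3.index.tolist()

    def test_fraction_one_empty_test_warns(self):
        df = pd.DataFrame({"x": np.arange(5.0)})
        with pytest.warns(UserWarning, match="empty"):
            train, test = split_train_test(df, 1.0, seed=0)
        assert len(train) == 5 and len(test) == 0

    def test_ceil_rounding(self):
        df = pd.DataFrame({"x": np.arange(7.0)})
        train, test = split_train_test(df, 0.8, seed=0)
        assert (len(train), len(test)) == (6, 1)  # ceil(5.6) = 6


class _IdentityModel:
    n_terms = 1

    def predict(self, frame):
        return frame["logEC50"].to_numpy() * 1.02


class TestValidationReport:
    def test_report_structure_and_totals(self, rng):
        df = pd.DataFrame({"logEC50": rng.uniform(1, 5, 40)})
        train, test = split_train_test(df, 0.8, seed=1)
        rep = validation_report(_IdentityModel(), train, test)
        assert rep["n"] == {"train": 32, "test": 8, "total": 40}
        # union metrics equal metrics of the concatenated prediction sets
        y = np.concatenate([train["logEC50"], test["logEC50"]])
        ps = PredictionSet(y, 1.02 * y)
        assert rep["metrics"]["total"]["r2"] == pytest.approx(r_squared(ps))
        assert rep["metrics"]["total"]["aard_pct"] == pytest.approx(2.0)
        assert rep["tropsha_test"]["overall"] is True

    def test_report_json_round_trips(self, rng, tmp_path):
        import json
        df = pd.DataFrame({"logEC50": rng.uniform(1, 5, 20)})
        train, test = split_train_test(df, 0.8, seed=1)
        rep = validation_report(_IdentityModel(), train, test)
        path = tmp_path / "r.json"
        path.write_text(json.dumps(rep))
        assert json.loads(path.read_text()) == json.loads(json.dumps(rep))


class TestOracleSweep:
    def test_full_suite_matches_bruteforce_on_random_sets(self, rng):
        """Every statistic vs its longhand oracle on 200 random sets."""
        for _ in range(200):
            ps = random_ps(rng)
            assert r_squared(ps) == pytest.approx(
                oracle_r2(ps.y_exp, ps.y_cal), rel=1e-10)
            assert aard_pct(ps) == pytest.approx(
                oracle_aard(ps.y_exp, ps.y_cal), rel=1e-10)
            assert rmse(ps) == pytest.approx(
                oracle_rmse(ps.y_exp, ps.y_cal), rel=1e-10)
            np.testing.assert_allclose(
                slopes_and_r0(ps), oracle_slopes_r0(ps.y_exp.tolist(),
                                                    ps.y_cal.tolist()),
                rtol=1e-10)
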