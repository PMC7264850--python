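"""Cline curve families: shapes, limits, likelihoods, standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hzclines import (
    ClineModel,
    FrequencyBinTable,
    TraitBinTable,
    delta_p,
    evaluate,
    loglik_frequency,
    loglik_trait,
    standardize_trait,
)


class TestEvaluate:
    def test_midpoint_is_mean_of_asymptotes(self):
        m = ClineModel("I", center=500.0, width=1500.0, pmin=0.2, pmax=0.8)
        assert evaluate(m, 500.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        m = ClineModel("I", center=0.0, width=2000.0, pmin=0.0, pmax=1.0)
        # Phi(1000) = 1 / (1 + e^-2)
        assert evaluate(m, 1000.0) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-12)

    def test_model_ii_far_attachment_reduces_to_model_i(self):
        mi = ClineModel("I", center=0.0, width=1000.0, pmin=0.0, pmax=1.0)
        mii = ClineModel(
            "II", center=0.0, width=1000.0, pmin=0.0, pmax=1.0,
            delta_l=10_000.0, tau_l=0.5, delta_r=10_000.0, tau_r=0.5,
        )
        d = np.linspace(-5000.0, 5000.0, 501)
        assert np.max(np.abs(evaluate(mii, d) - evaluate(mi, d))) < 1e-6

    def test_null_model_is_straight_line(self):
        m = ClineModel("null", pmin=0.1, pmax=0.9, d_min=-1000.0, d_max=1000.0)
        assert evaluate(m, -1000.0) == pytest.approx(0.1)
        assert evaluate(m, 0.0) == pytest.approx(0.5)
        assert evaluate(m, 1000.0) == pytest.approx(0.9)

    def test_decreasing_cline_allowed(self):
        m = ClineModel("I", center=0.0, width=1000.0, pmin=0.71, pmax=0.41)
        d = np.linspace(-4000.0, 4000.0, 100)
        assert np.all(np.diff(evaluate(m, d)) <= 0)

    def test_non_finite_distance_rejected(self, model_i):
        with pytest.raises(ValueError):
            evaluate(model_i, np.nan)


@pytest.mark.parametrize("delta,tau", [(200.0, 0.3), (500.0, 1.0), (0.0, 0.7), (1500.0, 0.05)])
def test_tail_continuity_at_attachment(delta, tau):
    m = ClineModel("III", center=0.0, width=1000.0, pmin=0.0, pmax=1.0,
                   delta_l=delta, tau_l=tau, delta_r=2 * delta + 1, tau_r=tau)
    for a in (-delta, 2 * delta + 1):
        lo, hi = evaluate(m, a - 1e-9), evaluate(m, a + 1e-9)
        assert abs(hi - lo) < 1e-6


def test_tau_one_gives_c1_join():
    m = ClineModel("II", center=0.0, width=1000.0, pmin=0.0, pmax=1.0,
                   delta_l=300.0, tau_l=1.0)
    a = -300.0
    h = 1e-4
    left = (evaluate(m, a) - evaluate(m, a - h)) / h
    right = (evaluate(m, a + h) - evaluate(m, a)) / h
    assert abs(left - right) < 1e-6


@pytest.mark.parametrize("model_type,kwargs", [
    ("I", {}),
    ("II", {"delta_l": 400.0, "tau_l": 0.2}),
    ("III", {"delta_l": 400.0, "tau_l": 0.2, "delta_r": 900.0, "tau_r": 0.8}),
])
def test_monotone_and_in_range(model_type, kwargs):
    m = ClineModel(model_type, center=100.0, width=1800.0, pmin=0.05, pmax=0.95, **kwargs)
    d = np.linspace(-20_000.0, 20_000.0, 2001)
    v = evaluate(m, d)
    assert np.all(np.diff(v) >= -1e-12)
    assert np.all((v >= 0.05 - 1e-12) & (v <= 0.95 + 1e-12))


def test_smaller_tau_means_longer_tails():
    base = dict(center=0.0, width=1000.0, pmin=0.0, pmax=1.0, delta_l=500.0, delta_r=500.0)
    mi = ClineModel("I", **{k: v for k, v in base.items() if not k.startswith("delta")})
    slow = ClineModel("II", tau_l=0.1, **base)
    fast = ClineModel("II", tau_l=0.9, **base)
    d = -4000.0  # deep in the western tail
    dev_slow = abs(evaluate(slow, d) - evaluate(mi, d))
    dev_fast = abs(evaluate(fast, d) - evaluate(mi, d))
    assert dev_slow > dev_fast


class TestDeltaP:
    def test_values(self):
        m = ClineModel("I", center=0, width=1, pmin=0.02, pmax=0.99)
        assert delta_p(m) == pytest.approx(0.97)
        m2 = ClineModel("I", center=0, width=1, pmin=0.71, pmax=0.41)
        assert delta_p(m2) == pytest.approx(0.30)

    def test_flat_cline(self):
        m = ClineModel("I", center=0, width=1, pmin=0.5, pmax=0.5)
        assert delta_p(m) == 0.0


class TestLoglikFrequency:
    def test_hand_value(self):
        t = FrequencyBinTable([0.0], [10], [5])
        m = ClineModel("I", center=0.0, width=1000.0, pmin=0.5, pmax=0.5)
        assert loglik_frequency(m, t) == pytest.approx(10 * np.log(0.5), abs=1e-12)

    def test_mle_at_observed_frequencies(self):
        t = FrequencyBinTable([-1000.0, 1000.0], [20, 20], [4, 16])
        # flat models predicting each observed frequency beat any other flat model
        at_obs = ClineModel("I", center=0.0, width=2000.0, pmin=0.2, pmax=0.8)
        worse = ClineModel("I", center=0.0, width=2000.0, pmin=0.4, pmax=0.6)
        assert loglik_frequency(at_obs, t) > loglik_frequency(worse, t)

    def test_additive_over_bins(self, model_i):
        t1 = FrequencyBinTable([-500.0], [30], [7])
        t2 = FrequencyBinTable([800.0], [30], [25])
        both = FrequencyBinTable([-500.0, 800.0], [30, 30], [7, 25])
        assert loglik_frequency(model_i, both) == pytest.approx(
            loglik_frequency(model_i, t1) + loglik_frequency(model_i, t2), abs=1e-10
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            FrequencyBinTable([], [], [])


class TestLoglikTrait:
    def test_exact_fit_leaves_only_constants(self, model_i):
        d = np.array([-2000.0, 0.0, 2000.0])
        mu = np.asarray(evaluate(model_i, d))
        t = TraitBinTable(d, [5, 5, 5], mu, [0.01, 0.01, 0.01])
        expected = 3 * float(-0.5 * np.log(2 * np.pi * 0.01 / 5))
        assert loglik_trait(model_i, t) == pytest.approx(expected, abs=1e-10)

    def test_matches_gaussian_density_oracle(self, model_i):
        from scipy.stats import norm

        d = np.array([-1500.0, 200.0, 3000.0])
        means = np.array([0.2, 0.55, 0.8])
        var = np.array([0.02, 0.05, 0.01])
        n = np.array([4, 9, 6])
        t = TraitBinTable(d, n, means, var)
        mu = np.asarray(evaluate(model_i, d))
        oracle = float(np.sum(norm.logpdf(means, mu, np.sqrt(var / n))))
        assert loglik_trait(model_i, t) == pytest.approx(oracle, abs=1e-9)

    def test_doubling_n_doubles_quadratic_penalty(self, model_i):
        d = np.array([-1000.0, 1000.0])
        means = np.array([0.3, 0.7])
        var = np.array([0.04, 0.04])
        t1 = TraitBinTable(d, [5, 5], means, var)
        t2 = TraitBinTable(d, [10, 10], means, var)
        mu = np.asarray(evaluate(model_i, d))
        quad1 = loglik_trait(model_i, t1) - float(np.sum(-0.5 * np.log(2 * np.pi * var / 5)))
        quad2 = loglik_trait(model_i, t2) - float(np.sum(-0.5 * np.log(2 * np.pi * var / 10)))
        assert quad2 == pytest.approx(2 * quad1, abs=1e-9)

    def test_zero_variance_without_fallback_errors(self, model_i):
        t = TraitBinTable([0.0, 100.0], [3, 3], [0.5, 0.6], [0.0, 0.0])
        with pytest.raises(ValueError):
            loglik_trait(model_i, t, pooled_fallback=False)


class TestStandardize:
    def test_minmax_endpoints(self):
        vals, scaler = standardize_trait([1.0, 2.0, 3.0])
        assert vals == pytest.approx([0.0, 0.5, 1.0])
        assert scaler.inverse(vals) == pytest.approx([1.0, 2.0, 3.0])

    def test_log_transform(self):
        vals, scaler = standardize_trait([1.0, np.e, np.e**2], transform="log")
        assert vals == pytest.approx([0.0, 0.5, 1.0], abs=1e-12)
        assert scaler.inverse(vals) == pytest.approx([1.0, np.e, np.e**2])

    def test_sqrt_round_trip(self):
        raw = np.array([0.0, 1.0, 4.0, 9.0])
        vals, scaler = standardize_trait(raw, transform="sqrt")
        assert np.asarray(scaler.inverse(vals)) == pytest.approx(raw, abs=1e-12)

    def test_domain_violation_names_offender(self):
        with pytest.raises(ValueError, match="treeB"):
            standardize_trait([1.0, -2.0], transform="log", ids=["treeA", "treeB"])

    def test_constant_input_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            vals, scaler = standardize_trait([2.0, 2.0, 2.0])
        assert np.all(vals == 0.5)
        assert scaler.constant


@settings(derandomize=True, max_examples=50)
@given(
    delta=st.floats(0.0, 3000.0),
    tau=st.floats(0.01, 1.0),
    width=st.floats(10.0, 5000.0),
)
def test_tail_range_property(delta, tau, width):
    """Phi stays inside (0,1) for any valid tail parameterization."""
    m = ClineModel("II", center=0.0, width=width, pmin=0.0, pmax=1.0,
                   delta_l=delta, tau_l=tau)
    d = np.linspace(-1e5, 1e5, 401)
    v = np.asarray(evaluate(m, d))
    assert np.all(v >= 0.0) and np.all(v <= 1.0)
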