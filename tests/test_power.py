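"""Closed-form power, sample-size and item-count functions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from cronpower import (
    Design,
    DesignSpec,
    DomainError,
    InfeasibleDesignError,
    alpha_from_rho,
    items_required,
    power_alpha_test,
    power_between_within,
    power_prepost,
    power_rho_parameterized,
    power_two_sample,
    rho_from_alpha,
    samplesize_between_within,
    samplesize_prepost,
    samplesize_two_sample,
    theoretical_power,
    z_pair,
)


def test_z_pair_values():
    assert z_pair(0.05, 0.5) == pytest.approx(1.959964, abs=1e-6)
    assert z_pair(0.05, 0.8) == pytest.approx(2.801585, abs=1e-6)


@given(a=st.floats(0.001, 0.2), p=st.floats(0.01, 0.99))
@settings(derandomize=True, max_examples=100)
def test_z_pair_quantile_antisymmetry(a, p):
    assert z_pair(a, p) + z_pair(a, 1 - p) == pytest.approx(
        2 * norm.ppf(1 - a / 2), abs=1e-9
    )


@pytest.mark.parametrize("bad", [(0.0, 0.5), (1.0, 0.5), (0.05, 0.0), (0.05, 1.0)])
def test_z_pair_boundary_errors(bad):
    with pytest.raises(DomainError):
        z_pair(*bad)


class TestAlphaTestPower:
    def test_fisher_z_known_value(self):
        assert power_alpha_test(0.5, 30) == pytest.approx(0.826, abs=1e-3)

    def test_zero_alpha_leaves_one_tail(self):
        assert power_alpha_test(0.0, 50) == pytest.approx(0.025, abs=1e-10)

    def test_monotone_in_alpha_and_n(self):
        vals = [power_alpha_test(a, 30) for a in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(vals) > 0)
        vals = [power_alpha_test(0.4, n) for n in range(5, 200, 5)]
        assert np.all(np.diff(vals) > 0)

    def test_monte_carlo_oracle(self):
        # brute-force check: Fisher-z test applied to bivariate normal samples
        # with correlation 0.5 at N=30 should reject at about the closed-form rate
        rng = np.random.default_rng(11)
        n, reps, rho = 30, 4000, 0.5
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z_crit = norm.ppf(0.975)
        rej = 0
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            r = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
            if abs(np.sqrt(n - 3) * np.arctanh(r)) > z_crit:
                rej += 1
        p_hat = rej / reps
        se = np.sqrt(p_hat * (1 - p_hat) / reps)
        assert power_alpha_test(rho, n) == pytest.approx(p_hat, abs=4 * se)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            power_alpha_test(1.0, 30)  # z-transform diverges
        with pytest.raises(DomainError):
            power_alpha_test(0.5, 3)


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (power_prepost, (0.4, 0.5, 30), 0.341),
        (power_prepost, (0.4, 0.9, 30), 0.996),
        (power_between_within, (0.4, 0.5, 30), 0.194),
        (power_between_within, (0.4, 0.9, 30), 0.908),
        (power_two_sample, (0.7, 0.5, 50), 0.697),
        (power_two_sample, (0.5, 0.9, 100), 0.918),
    ],
)
def test_power_spot_values(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize("fn", [power_prepost, power_between_within, power_two_sample])
def test_null_effect_power_is_half_alpha(fn):
    # the opposite rejection tail is dropped by convention
    for c_alpha, n, a in [(0.3, 20, 0.05), (0.8, 100, 0.01)]:
        assert fn(0.0, c_alpha, n, a) == pytest.approx(a / 2, abs=1e-12)
        assert fn(0.0, c_alpha, n, a, both_tails=True) == pytest.approx(a, abs=1e-12)


@pytest.mark.parametrize("fn", [power_prepost, power_between_within, power_two_sample])
def test_power_monotone_in_all_arguments(fn):
    alphas = np.linspace(0.05, 0.95, 19)
    assert np.all(np.diff([fn(0.4, a, 30) for a in alphas]) > 0)
    assert np.all(np.diff([fn(0.4, 0.6, n) for n in range(2, 200, 7)]) > 0)
    assert np.all(np.diff([fn(d, 0.6, 30) for d in np.linspace(0.05, 2.0, 30)]) > 0)


def test_two_sample_allows_perfect_alpha_prepost_does_not():
    # error-free items: classical two-sample normal power
    d, n = 0.7, 50
    expected = norm.cdf(d * np.sqrt(n / 2) - norm.ppf(0.975))
    assert power_two_sample(d, 1.0, n) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(DomainError):
        power_prepost(d, 1.0, n)
    with pytest.raises(DomainError):
        power_between_within(d, 1.0, n)


class TestSampleSize:
    def test_prepost_hand_value(self):
        res = samplesize_prepost(0.4, 0.5, 0.05, 0.8)
        assert res.n_continuous == pytest.approx(2 * 1 * 2.801585**2 / 0.16, rel=1e-6)
        assert res.n == 99

    def test_between_within_is_double_prepost(self):
        pp = samplesize_prepost(0.4, 0.5, 0.05, 0.8)
        bw = samplesize_between_within(0.4, 0.5, 0.05, 0.8)
        assert bw.n_continuous == pytest.approx(2 * pp.n_continuous, rel=1e-12)
        assert bw.n == 197

    def test_two_sample_hand_value_and_classical_limit(self):
        res = samplesize_two_sample(0.7, 0.5, 0.05, 0.8)
        assert res.n_continuous == pytest.approx(2 * 2.801585**2 / (0.5 * 0.49), rel=1e-6)
        assert res.n == 65
        at_one = samplesize_two_sample(0.7, 1.0, 0.05, 0.8)
        assert at_one.n_continuous == pytest.approx(2 * z_pair(0.05, 0.8) ** 2 / 0.49, rel=1e-12)

    @pytest.mark.parametrize(
        "ss_fn, p_fn",
        [
            (samplesize_prepost, power_prepost),
            (samplesize_between_within, power_between_within),
            (samplesize_two_sample, power_two_sample),
        ],
    )
    def test_power_duality(self, ss_fn, p_fn):
        # plugging the continuous N back into the power function recovers the target
        for d in (0.2, 0.5, 1.0):
            for ca in (0.3, 0.6, 0.9):
                for phi in (0.5, 0.8, 0.95):
                    n_cont = ss_fn(d, ca, 0.05, phi).n_continuous
                    assert p_fn(d, ca, n_cont) == pytest.approx(phi, abs=1e-10)

    def test_monotone_decreasing_in_alpha_and_effect(self):
        ns = [samplesize_prepost(0.4, ca).n_continuous for ca in (0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(ns) < 0)
        ns = [samplesize_prepost(d, 0.5).n_continuous for d in (0.2, 0.4, 0.8)]
        assert np.all(np.diff(ns) < 0)

    def test_zero_effect_rejected(self):
        for fn in (samplesize_prepost, samplesize_between_within, samplesize_two_sample):
            with pytest.raises(DomainError):
                fn(0.0, 0.5)


class TestItemsRequired:
    def test_prepost_consistent_with_samplesize_at_single_item(self):
        # at N equal to the k=1 sample size, about one item suffices
        res = items_required("prepost", 0.5, 99, 0.4, 0.05, 0.8)
        assert res.k_continuous == pytest.approx(0.991, abs=1e-3)
        assert res.k == 1

    def test_prepost_inversion_of_rho_power(self):
        rho, n, d, phi = 0.3, 40, 0.5, 0.8
        k_cont = items_required("prepost", rho, n, d, 0.05, phi).k_continuous
        assert power_rho_parameterized("prepost", d, rho, k_cont, n) == pytest.approx(
            phi, abs=1e-9
        )

    def test_two_sample_inversion_and_infeasibility(self):
        rho, n, d, phi = 0.4, 120, 0.5, 0.8
        k_cont = items_required("ts", rho, n, d, 0.05, phi).k_continuous
        assert power_rho_parameterized("ts", d, rho, k_cont, n) == pytest.approx(phi, abs=1e-9)
        with pytest.raises(InfeasibleDesignError):
            items_required("ts", 0.5, 10, 0.4, 0.05, 0.8)

    def test_between_within_surfaces_both_factors(self):
        rho, n, d, phi = 0.4, 200, 0.5, 0.8
        res = items_required("bw", rho, n, d, 0.05, phi)
        # default: self-consistent inversion of the interaction power function
        assert power_rho_parameterized("bw", d, rho, res.k_continuous, n) == pytest.approx(
            phi, abs=1e-9
        )
        # the published variant carries half the numerator and is also reported
        assert res.k_continuous_printed == pytest.approx(res.k_continuous / 2, rel=1e-12)
        printed = items_required("bw", rho, n, d, 0.05, phi, formula="printed")
        assert printed.k_continuous == pytest.approx(res.k_continuous_printed, rel=1e-12)

    def test_alpha_design_rejected(self):
        with pytest.raises(DomainError):
            items_required("alpha", 0.5, 30, 0.4)


@pytest.mark.parametrize("design", ["prepost", "bw", "ts"])
def test_rho_parameterization_matches_alpha_parameterization(design):
    fn = {
        "prepost": power_prepost,
        "bw": power_between_within,
        "ts": power_two_sample,
    }[design]
    for rho in (0.1, 0.3, 0.6, 0.9):
        for k in (1, 2, 5, 10):
            c_alpha = alpha_from_rho(rho, k)
            assert power_rho_parameterized(design, 0.5, rho, k, 40) == pytest.approx(
                fn(0.5, c_alpha, 40), abs=1e-12
            )


def test_k_independence_for_equal_alpha():
    # instruments with different item counts but equal alpha have equal power
    c_alpha = 0.75
    vals = {
        k: power_rho_parameterized("ts", 0.5, rho_from_alpha(c_alpha, k), k, 60)
        for k in (1, 3, 8, 20)
    }
    assert max(vals.values()) - min(vals.values()) < 1e-12


def test_per_group_total_consistency():
    # interaction power at per-group N equals paired power at total N with sqrt(2) scaling
    for d in (0.3, 0.6):
        for ca in (0.4, 0.8):
            for n in (20, 50):
                assert power_between_within(d, ca, n) == pytest.approx(
                    power_prepost(d / np.sqrt(2), ca, n), abs=1e-12
                )


def test_theoretical_power_dispatch_and_spec_validation():
    spec = DesignSpec(design=Design.PRE_POST, delta_std=0.4, n=30, c_alpha=0.5)
    assert theoretical_power(spec).power == pytest.approx(power_prepost(0.4, 0.5, 30))
    with pytest.raises(DomainError):
        DesignSpec(design=Design.ALPHA_TEST, delta_std=0.0, n=3, c_alpha=0.5)
    with pytest.raises(DomainError):
        DesignSpec(design=Design.PRE_POST, delta_std=0.4, n=30, c_alpha=1.5)
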