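"""Unit and property tests for the generative model core."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import norm

from glampi.model import (
    GlampiParams,
    TrialSet,
    calculate_inbound,
    dataset_nll,
    desktop_encoded_distance,
    encode_angle,
    encode_distances,
    leak_factor,
    predict_inbound,
    produce_inbound,
    trial_nll,
)

LOG_2PI = math.log(2 * math.pi)


def ode_encoded_distance(l, T, k, beta):
    """Independent oracle: numerically integrate the leaky integrator."""
    v = l / T
    sol = solve_ivp(lambda t, y: -beta * y + k * v, (0, T), [0.0], rtol=1e-11, atol=1e-13)
    return sol.y[0, -1]


class TestEncoding:
    def test_zero_leak_is_identity(self):
        l1p, l2p = encode_distances(2.0, 3.0, 2.5, 4.0, k=1.0, beta=0.0)
        assert l1p == pytest.approx(2.0, abs=1e-12)
        assert l2p == pytest.approx(3.0, abs=1e-12)

    def test_single_leg_matches_ode_oracle(self):
        # 3 m walked in 4 s at beta = 0.1 encodes to ~2.4726 m
        expected = ode_encoded_distance(3.0, 4.0, 1.0, 0.1)
        assert expected == pytest.approx(2.4726, abs=1e-4)
        _, l2p = encode_distances(0.0, 3.0, 1.0, 4.0, k=1.0, beta=0.1)
        assert l2p == pytest.approx(expected, abs=1e-6)

    def test_first_leg_keeps_decaying_during_second(self):
        # the ODE run through both legs gives the extra exp(-beta*T2) factor
        l1p, _ = encode_distances(3.0, 3.0, 4.0, 4.0, k=1.0, beta=0.1)
        assert l1p == pytest.approx(2.4726 * math.exp(-0.4), abs=1e-4)
        one_leg = ode_encoded_distance(3.0, 4.0, 1.0, 0.1)
        sol = solve_ivp(lambda t, y: -0.1 * y, (0, 4.0), [one_leg], rtol=1e-11, atol=1e-13)
        assert l1p == pytest.approx(sol.y[0, -1], abs=1e-6)

    def test_continuous_at_zero_leak(self):
        for beta in (-1e-9, 1e-9):
            val = leak_factor(beta, 5.0)
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_negative_leak_represents_growth(self):
        _, l2p = encode_distances(0.0, 3.0, 1.0, 4.0, k=1.0, beta=-0.1)
        assert l2p > 3.0

    def test_desktop_integrator_equivalence(self):
        # at constant speed v the time-domain encoder with leak beta equals
        # the distance-domain integrator with rate beta/v, exactly
        for beta in (-0.2, 0.05, 0.4):
            for v in (0.5, 1.25):
                for l in (1.0, 3.5):
                    _, l2p = encode_distances(0.0, l, 1.0, l / v, k=1.1, beta=beta)
                    assert l2p == pytest.approx(desktop_encoded_distance(l, beta / v, 1.1), abs=1e-12)


class TestCalculation:
    def test_right_isosceles(self):
        h, alpha = calculate_inbound(1.0, 1.0, np.pi / 2)
        assert h == pytest.approx(math.sqrt(2), abs=1e-12)
        assert alpha == pytest.approx(3 * np.pi / 4, abs=1e-12)

    def test_vector_addition_oracle(self):
        # independent check via explicit 2-D leg addition
        l1p, l2p, th = 2.0, 1.0, 2 * np.pi / 3
        h, alpha = calculate_inbound(l1p, l2p, th)
        ret = -np.array([l1p + l2p * np.cos(th), l2p * np.sin(th)])
        assert h == pytest.approx(np.hypot(*ret), abs=1e-12)
        assert h == pytest.approx(math.sqrt(3), abs=1e-9)
        assert alpha == pytest.approx(np.pi / 2, abs=1e-9)

    def test_gain_encoding_monotone(self):
        th = np.pi / 2
        assert encode_angle(th, 1.0) == th
        assert encode_angle(th, 1.2) == pytest.approx(0.6 * np.pi)
        gains = [0.8, 1.0, 1.3]
        assert sorted(encode_angle(th, g) for g in gains) == [encode_angle(th, g) for g in gains]

    def test_degenerate_closed_path_rejected(self):
        with pytest.raises(ValueError):
            calculate_inbound(1.0, 1.0, np.pi)

    def test_asin_argument_clamped(self):
        # float error can push the ratio just past 1; must not yield NaN
        h, alpha = calculate_inbound(1.0, 1e-14, np.pi / 2)
        assert np.isfinite(alpha)

    def test_obtuse_branch_flagged_and_overturns(self):
        # when the encoded return vertex goes obtuse the literal asin form
        # returns a large turn where exact geometry returns a small one --
        # the mechanism by which angular over-encoding produces over-turning
        l1p, l2p, th = 2.0, 1.0, np.deg2rad(174)
        h, alpha, amb = calculate_inbound(l1p, l2p, th, return_flag=True)
        assert bool(amb)
        ret = -np.array([l1p + l2p * np.cos(th), l2p * np.sin(th)])
        exact = (np.arctan2(ret[1], ret[0]) - th) % (2 * np.pi)
        assert alpha > np.pi / 2 > exact
        _, _, amb_acute = calculate_inbound(1.0, 1.0, np.pi / 2, return_flag=True)
        assert not bool(amb_acute)


class TestProduction:
    def test_veridical_production(self):
        assert produce_inbound(2.0, 1.5, g3=1.0, m3=1.0, lbar=9.0, thbar=9.0) == (2.0, 1.5)

    def test_full_regression_to_mean(self):
        l3p, th3p = produce_inbound(2.0, 1.5, g3=0.0, m3=0.0, lbar=2.5, thbar=1.0)
        assert (l3p, th3p) == (2.5, 1.0)

    def test_linear_blend(self):
        _, th3p = produce_inbound(2.0, 2.0, g3=0.5, m3=1.0, lbar=2.0, thbar=1.0)
        assert th3p == pytest.approx(1.5)


def _random_trialset(rng, n, params, oob_frac=0.0):
    l1 = rng.uniform(1.5, 3.5, n)
    l2 = rng.uniform(1.5, 3.5, n)
    th2 = rng.uniform(0.8, 2.2, n)
    T1 = l1 / rng.uniform(0.5, 1.2, n)
    T2 = l2 / rng.uniform(0.5, 1.2, n)
    hc = np.sqrt(l1**2 + l2**2 + 2 * l1 * l2 * np.cos(th2))
    lbar, thbar = float(hc.mean()), 2.0
    l3p, th3p = predict_inbound(params, l1, l2, th2, T1, T2, lbar, thbar)
    l3 = l3p + params.sigma * rng.standard_normal(n)
    th3 = th3p + params.nu * rng.standard_normal(n)
    oob = rng.random(n) < oob_frac
    l3 = np.where(oob, np.nan, l3)
    return TrialSet(l1=l1, l2=l2, theta2=th2, T1=T1, T2=T2, theta3=th3, l3=l3, oob=oob, lbar=lbar, thbar=thbar)


class TestLikelihood:
    def test_mode_density(self):
        assert trial_nll(2.0, 1.5, 2.0, 1.5, sigma=1.0, nu=1.0) == pytest.approx(LOG_2PI, abs=1e-12)

    def test_oob_contributes_angle_only(self):
        assert trial_nll(np.nan, 1.5, 99.0, 1.5, sigma=1.0, nu=1.0, oob=True) == pytest.approx(0.5 * LOG_2PI, abs=1e-12)

    def test_matches_gaussian_density_oracle(self, rng):
        params = GlampiParams(k=1.2, g2=1.1, beta=0.1, g3=0.8, m3=0.9, sigma=0.3, nu=0.4)
        ts = _random_trialset(rng, 40, params, oob_frac=0.3)
        l3p, th3p = predict_inbound(params, ts.l1, ts.l2, ts.theta2, ts.T1, ts.T2, ts.lbar, ts.thbar)
        oracle = -norm.logpdf(ts.theta3, th3p, params.nu).sum()
        complete = ~ts.oob
        oracle += -norm.logpdf(ts.l3[complete], l3p[complete], params.sigma).sum()
        assert dataset_nll(ts, params) == pytest.approx(oracle, abs=1e-10)

    def test_perfect_trials_and_additivity(self):
        params = GlampiParams(sigma=1.0, nu=1.0)
        one = _random_trialset(np.random.default_rng(0), 1, GlampiParams(sigma=0, nu=0))
        n = 6
        ts = TrialSet(
            l1=np.repeat(one.l1, n), l2=np.repeat(one.l2, n), theta2=np.repeat(one.theta2, n),
            T1=np.repeat(one.T1, n), T2=np.repeat(one.T2, n), theta3=np.repeat(one.theta3, n),
            l3=np.repeat(one.l3, n), oob=np.zeros(n, bool), lbar=one.lbar, thbar=one.thbar,
        )
        assert dataset_nll(ts, params) == pytest.approx(n * LOG_2PI, abs=1e-10)
        half = TrialSet(
            l1=ts.l1[:3], l2=ts.l2[:3], theta2=ts.theta2[:3], T1=ts.T1[:3], T2=ts.T2[:3],
            theta3=ts.theta3[:3], l3=ts.l3[:3], oob=ts.oob[:3], lbar=ts.lbar, thbar=ts.thbar,
        )
        assert dataset_nll(ts, params) == pytest.approx(2 * dataset_nll(half, params), abs=1e-10)

    def test_zero_noise_sd_is_fit_reject_signal(self):
        ts = _random_trialset(np.random.default_rng(1), 5, GlampiParams(sigma=0.2, nu=0.2))
        assert dataset_nll(ts, GlampiParams(sigma=0.0, nu=0.3)) == math.inf

    def test_truth_beats_perturbations_at_scale(self):
        # large-sample consistency: the generating parameters score no worse
        # than any single-coordinate +0.5 perturbation
        truth = GlampiParams(k=1.2, g2=1.1, beta=0.1, g3=0.8, m3=0.9, sigma=0.3, nu=0.35)
        ts = _random_trialset(np.random.default_rng(7), 10_000, truth)
        base = dataset_nll(ts, truth)
        for name in ("k", "g2", "beta", "g3", "m3", "sigma", "nu"):
            perturbed = truth.replace(**{name: getattr(truth, name) + 0.5})
            assert base <= dataset_nll(ts, perturbed)

    def test_empty_set_rejected(self):
        ts = _random_trialset(np.random.default_rng(2), 3, GlampiParams(sigma=0.2, nu=0.2))
        empty = TrialSet(
            l1=ts.l1[:0], l2=ts.l2[:0], theta2=ts.theta2[:0], T1=ts.T1[:0], T2=ts.T2[:0],
            theta3=ts.theta3[:0], l3=ts.l3[:0], oob=ts.oob[:0], lbar=ts.lbar, thbar=ts.thbar,
        )
        with pytest.raises(ValueError):
            dataset_nll(empty, GlampiParams(sigma=1, nu=1))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        GlampiParams(sigma=-0.1)
    with pytest.raises(ValueError):
        GlampiParams(k=math.nan)


def test_params_json_roundtrip():
    p = GlampiParams(k=1.2, g2=1.1, beta=0.05, g3=0.8, m3=0.9, sigma=0.3, nu=0.4)
    assert GlampiParams.from_json(p.to_json()) == p
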