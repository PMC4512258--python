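"""Sampler unit tests: conditionals, hyper-parameter defaults, determinism,
and agreement with the exact delta-enumeration posterior."""
import numpy as np
import pytest

from braim.gibbs import (
    GibbsState,
    default_lambda,
    delta_probability,
    run_gibbs,
    sample_beta,
    sample_delta,
    sample_sigma2,
    sample_z,
    transcript_rng,
)
from braim.types import HyperParams, ResponseSet

from _oracle import batch_mcse, exact_posterior


def make_response(y, err_var, tid="t1"):
    y = np.asarray(y, dtype=float)
    return ResponseSet(
        transcript_id=tid,
        y_scaled=y,
        err_var_scaled=np.asarray(err_var, dtype=float),
        scale_sd=1.0,
    )


@pytest.mark.parametrize(
    "nu,var,expected",
    [(2.5, 1.0, 0.04), (5.0, 1.0, 0.12), (2.5, 0.0, 0.0)],
)
def test_default_lambda(nu, var, expected):
    assert default_lambda(nu, var) == pytest.approx(expected)


def test_default_lambda_rejects_small_nu():
    with pytest.raises(ValueError):
        default_lambda(2.0)


def test_hyperparams_default_lambda_is_004():
    assert HyperParams().lam == pytest.approx(0.04)


def test_sample_z_moments_match_conditional():
    """n=1, err_var=1, s2=1, Xb=0, y=2 -> posterior N(1, 0.5)."""
    resp = make_response([2.0], [1.0])
    X = np.array([[1.0]])
    state = GibbsState(z=np.zeros(1), beta=np.zeros(1), sigma2=1.0, delta=np.zeros(1, dtype=int))
    rng = np.random.default_rng(0)
    draws = np.array([sample_z(state, resp, X, rng)[0] for _ in range(20000)])
    assert draws.mean() == pytest.approx(1.0, abs=0.02)
    assert draws.var() == pytest.approx(0.5, rel=0.05)


def test_sample_z_zero_error_pins_to_data():
    resp = make_response([2.0, -1.0], [1e-12, 1e-12])
    X = np.ones((2, 1))
    state = GibbsState(z=np.zeros(2), beta=np.zeros(1), sigma2=1.0, delta=np.zeros(1, dtype=int))
    z = sample_z(state, resp, X, np.random.default_rng(0))
    assert z == pytest.approx([2.0, -1.0], abs=1e-4)


def test_sample_beta_moments_match_conditional():
    """n=2 ones column, z=(1,1), s2=1, prior var 1 -> N(2/3, 1/3)."""
    X = np.ones((2, 1))
    hyper = HyperParams(tau=1.0, c_mult=1.0)
    state = GibbsState(z=np.ones(2), beta=np.zeros(1), sigma2=1.0, delta=np.zeros(1, dtype=int))
    rng = np.random.default_rng(0)
    draws = np.array([sample_beta(state, X, hyper, rng)[0] for _ in range(20000)])
    assert draws.mean() == pytest.approx(2.0 / 3.0, abs=0.02)
    assert draws.var() == pytest.approx(1.0 / 3.0, rel=0.05)


def test_sample_beta_zero_z_centers_at_zero():
    X = np.ones((4, 1))
    hyper = HyperParams()
    state = GibbsState(z=np.zeros(4), beta=np.zeros(1), sigma2=1.0, delta=np.zeros(1, dtype=int))
    rng = np.random.default_rng(0)
    draws = np.array([sample_beta(state, X, hyper, rng)[0] for _ in range(5000)])
    assert abs(draws.mean()) < 0.01


def test_sample_sigma2_shape_and_scale():
    """n=2, p=1, nu=2.5 -> IG shape 2.75; with z=Xb and b=0 the scale is
    nu*lam/2 = 0.05, so E[1/s2] = shape/scale."""
    X = np.ones((2, 1))
    hyper = HyperParams(nu=2.5, lam=0.04)
    state = GibbsState(z=np.zeros(2), beta=np.zeros(1), sigma2=1.0, delta=np.zeros(1, dtype=int))
    rng = np.random.default_rng(0)
    draws = np.array([sample_sigma2(state, X, hyper, rng) for _ in range(40000)])
    assert np.all(draws > 0)
    assert np.mean(1.0 / draws) == pytest.approx(2.75 / 0.05, rel=0.03)


def test_delta_probability_examples():
    # c=1 degenerates the mixture: posterior = prior
    hyper = HyperParams(tau=0.1, c_mult=1.0, prior_p=0.3)
    assert delta_probability(np.zeros(2), 1.0, hyper) == pytest.approx([0.3, 0.3])
    # at beta=0 the density ratio equals c
    hyper = HyperParams(tau=0.1, c_mult=4.25, prior_p=0.1)
    expected = 0.1 / (0.1 + 4.25 * 0.9)
    assert delta_probability(np.zeros(1), 1.0, hyper)[0] == pytest.approx(expected, rel=1e-9)
    # far in the tail the slab dominates
    assert delta_probability(np.array([50.0]), 1.0, hyper)[0] > 1.0 - 1e-6


def test_sample_delta_prior_recovery():
    hyper = HyperParams(tau=0.1, c_mult=1.0, prior_p=0.25)
    state = GibbsState(z=np.zeros(1), beta=np.zeros(3), sigma2=1.0, delta=np.zeros(3, dtype=int))
    rng = np.random.default_rng(0)
    draws = np.array([sample_delta(state, hyper, rng) for _ in range(20000)])
    assert draws.mean() == pytest.approx(0.25, abs=0.02)


def test_run_gibbs_deterministic_under_seed():
    rng = np.random.default_rng(3)
    y = rng.standard_normal(6)
    resp = make_response(y, np.full(6, 0.1))
    X = np.column_stack([np.ones(6), [1, -1, 1, -1, 1, -1]])
    hyper = HyperParams(n_iter=500, burn_in=100, seed=11)
    f1 = run_gibbs(resp, X, hyper, column_labels=("parental", "cross"))
    f2 = run_gibbs(resp, X, hyper, column_labels=("parental", "cross"))
    assert np.array_equal(f1.pp, f2.pp)
    assert np.array_equal(f1.post_beta, f2.post_beta)
    assert np.array_equal(f1.post_sigma2, f2.post_sigma2)


def test_run_gibbs_dimension_mismatch():
    resp = make_response([1.0, 2.0], [0.1, 0.1])
    with pytest.raises(ValueError):
        run_gibbs(resp, np.ones((3, 1)), HyperParams(n_iter=10, burn_in=1), column_labels=("parental",))


def test_transcript_rng_order_invariant():
    a1 = transcript_rng(5, "txA").standard_normal(3)
    _ = transcript_rng(5, "txB").standard_normal(3)
    a2 = transcript_rng(5, "txA").standard_normal(3)
    assert np.array_equal(a1, a2)


@pytest.mark.parametrize(
    "n,p,seed",
    [(4, 1, 0), (6, 2, 1), (5, 2, 2)],
)
def test_run_gibbs_matches_exact_enumeration_oracle(n, p, seed):
    """PP and beta moments agree with brute-force delta enumeration
    (conjugate normal-inverse-gamma marginals) within 3 MC standard errors
    in the zero-measurement-error limit."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.choice([-1.0, 1.0], n) for _ in range(p - 1)])
    beta_true = np.array([1.0] + [0.3] * (p - 1))
    y = X @ beta_true + 0.8 * rng.standard_normal(n)
    resp = make_response(y, np.full(n, 1e-8))
    hyper = HyperParams(tau=0.3, c_mult=4.25, prior_p=0.2, n_iter=30000, burn_in=2000, seed=seed)
    fit = run_gibbs(resp, X, hyper, column_labels=tuple(f"e{i}" for i in range(p)))
    exact = exact_posterior(y, X, hyper)

    for i in range(p):
        mcse_pp = batch_mcse(fit.post_delta[:, i])
        assert fit.pp[i] == pytest.approx(exact["pp"][i], abs=max(3 * mcse_pp, 0.005))
        mcse_b = batch_mcse(fit.post_beta[:, i])
        assert fit.beta_mean[i] == pytest.approx(exact["beta_mean"][i], abs=max(3 * mcse_b, 0.005))
        assert fit.beta_sd[i] == pytest.approx(exact["beta_sd"][i], rel=0.1)
    assert fit.sigma2_mean == pytest.approx(exact["sigma2_mean"], rel=0.15)


def test_run_gibbs_conjugate_limit_delta_all_ones():
    """With err_var -> 0 and the prior forcing delta = 1, the beta
    posterior matches the standard conjugate regression posterior."""
    rng = np.random.default_rng(4)
    n = 6
    X = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], n)])
    y = X @ np.array([1.2, -0.5]) + 0.5 * rng.standard_normal(n)
    resp = make_response(y, np.full(n, 1e-8))
    hyper = HyperParams(
        tau=0.5, c_mult=2.0, prior_p=1 - 1e-12, n_iter=30000, burn_in=2000, seed=4
    )
    fit = run_gibbs(resp, X, hyper, column_labels=("a", "b"))
    # closed form: delta fixed at (1,1)
    d2 = (hyper.tau * hyper.c_mult) ** 2
    M_inv = np.linalg.inv(X.T @ X + np.eye(2) / d2)
    mu = M_inv @ X.T @ y
    a, b = hyper.nu / 2, hyper.nu * hyper.lam / 2
    q = y @ np.linalg.solve(np.eye(n) + d2 * (X @ X.T), y)
    e_sig2 = (b + q / 2) / (a + n / 2 - 1)
    cov = e_sig2 * M_inv
    for i in range(2):
        mcse = batch_mcse(fit.post_beta[:, i])
        assert fit.beta_mean[i] == pytest.approx(mu[i], abs=max(3 * mcse, 0.01))
        assert fit.beta_sd[i] == pytest.approx(np.sqrt(cov[i, i]), rel=0.1)
    assert np.all(fit.pp > 0.999)


def test_sigma2_chain_positive_and_pp_in_unit_interval():
    rng = np.random.default_rng(9)
    y = rng.standard_normal(8)
    resp = make_response(y, np.full(8, 0.2))
    X = np.column_stack([np.ones(8), rng.choice([-1.0, 1.0], 8)])
    fit = run_gibbs(
        resp, X, HyperParams(n_iter=2000, burn_in=200, seed=9), column_labels=("a", "b")
    )
    assert np.all(fit.post_sigma2 > 0)
    assert np.all((fit.pp >= 0) & (fit.pp <= 1))
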