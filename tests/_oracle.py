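"""Exact posterior by delta-enumeration, independent of the Gibbs sampler.

In the zero-measurement-error limit the latent z equals the observed
response and, for a fixed inclusion vector delta, the model is conjugate
normal-inverse-gamma: the marginal likelihood of y, the posterior mean of
beta and the posterior mean of sigma^2 are all closed-form.  Enumerating
all 2^p delta configurations and weighting by marginal likelihood times
prior gives the exact posterior inclusion probabilities and beta moments.
"""
from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import gammaln


def exact_posterior(y: np.ndarray, X: np.ndarray, hyper) -> dict:
    """Exact PP, E[beta], sd[beta] and E[sigma2] for err_var -> 0."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    a = hyper.nu / 2.0
    b = hyper.nu * hyper.lam / 2.0

    log_w = []
    means = []
    covs = []
    sig2s = []
    deltas = list(product([0, 1], repeat=p))
    for delta in deltas:
        d2 = (hyper.tau * hyper.c_mult ** np.array(delta)) ** 2
        V = np.eye(n) + X @ np.diag(d2) @ X.T
        sign, logdet = np.linalg.slogdet(V)
        assert sign > 0
        q = float(y @ np.linalg.solve(V, y))
        log_m = (
            gammaln(a + n / 2.0)
            - gammaln(a)
            + a * np.log(b)
            - (n / 2.0) * np.log(2.0 * np.pi)
            - 0.5 * logdet
            - (a + n / 2.0) * np.log(b + q / 2.0)
        )
        log_prior = float(
            np.sum(np.where(np.array(delta) == 1, np.log(hyper.prior_p), np.log(1.0 - hyper.prior_p)))
        )
        log_w.append(log_m + log_prior)

        M_inv = np.linalg.inv(X.T @ X + np.diag(1.0 / d2))
        mu = M_inv @ X.T @ y
        e_sig2 = (b + q / 2.0) / (a + n / 2.0 - 1.0)
        means.append(mu)
        covs.append(e_sig2 * M_inv)
        sig2s.append(e_sig2)

    log_w = np.array(log_w)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()

    deltas_arr = np.array(deltas)
    pp = w @ deltas_arr
    beta_mean = w @ np.array(means)
    # law of total variance over delta configurations
    second = sum(
        wk * (np.diag(ck) + mk**2) for wk, ck, mk in zip(w, covs, means)
    )
    beta_var = second - beta_mean**2
    return {
        "pp": pp,
        "beta_mean": beta_mean,
        "beta_sd": np.sqrt(np.maximum(beta_var, 0.0)),
        "sigma2_mean": float(w @ np.array(sig2s)),
        "weights": w,
        "deltas": deltas_arr,
    }


def batch_mcse(draws: np.ndarray, n_batches: int = 30) -> float:
    """Batch-means Monte-Carlo standard error of a chain's mean."""
    draws = np.asarray(draws, dtype=float)
    m = draws.size // n_batches
    batches = draws[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
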