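"""Independent dense-grid quadrature oracles for the site models.

These integrate the exact same posterior densities as the production
engine, but by brute-force nested numerical integration: the gamma
random effect of each individual is integrated on a fine trapezoid grid
(not Gauss-Hermite), and the remaining parameters on dense tensor grids.
Used to validate posterior means and log marginal likelihoods.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

LOG2PI = float(np.log(2.0 * np.pi))


def _log_trapz(log_f: np.ndarray, dx: float, axis: int = -1) -> np.ndarray:
    """log of the trapezoid integral of exp(log_f) along axis."""
    n = log_f.shape[axis]
    w = np.full(n, dx)
    w[0] = w[-1] = dx / 2.0
    shape = [1] * log_f.ndim
    shape[axis] = n
    return logsumexp(log_f + np.log(w).reshape(shape), axis=axis)


def _site_loglik(y: float, n: float, eta: np.ndarray) -> np.ndarray:
    logc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return logc + y * eta - n * np.logaddexp(0.0, eta)


def _log_marg_table(
    y: float, n: float, mu_grid: np.ndarray, sigma_grid: np.ndarray,
    gamma_half: float = 14.0, n_gamma: int = 1401,
) -> np.ndarray:
    """log m(mu, sigma) = log Int lik(mu+g) N(g|0, sigma^2) dg, trapezoid.

    Returns array (len(mu_grid), len(sigma_grid)). The gamma integral is
    a single likelihood-matrix x prior-kernel product per individual.
    """
    g = np.linspace(-gamma_half, gamma_half, n_gamma)
    dg = g[1] - g[0]
    w_trap = np.full(n_gamma, dg)
    w_trap[0] = w_trap[-1] = dg / 2.0
    ll = _site_loglik(y, n, mu_grid[:, None] + g[None, :])  # (mu, g)
    row_max = ll.max(axis=1, keepdims=True)
    lik = np.exp(ll - row_max)
    s2 = np.maximum(sigma_grid, 1e-6) ** 2
    kern = (
        np.exp(-(g[:, None] ** 2) / (2 * s2[None, :]))
        / np.sqrt(2 * np.pi * s2)[None, :]
        * w_trap[:, None]
    )  # (g, sigma)
    # renormalize columns: for sigma below the grid resolution the raw
    # trapezoid sum misrepresents the near-delta kernel; normalizing keeps
    # the discrete gamma-average exact in the sigma -> 0 limit too
    kern /= kern.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore"):
        return row_max + np.log(lik @ kern)


def _halfnormal_logpdf(sigma: np.ndarray, scale: float) -> np.ndarray:
    return np.log(2.0) - 0.5 * LOG2PI - np.log(scale) - sigma**2 / (2 * scale**2)


def _normal_logpdf(x: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * LOG2PI - np.log(sd) - x**2 / (2 * sd**2)


def grid_posterior_m0(
    y: np.ndarray, n: np.ndarray,
    beta0_sd: float = 3.0, sigma_scale: float = 1.0,
    n_beta: int = 321, beta_half: float = 8.0,
    n_sigma: int = 161, sigma_max: float = 4.0,
) -> dict:
    """Grid posterior for eta_i = beta0 + gamma_i (the M0 / no-status model).

    Returns log marginal likelihood and the beta0 posterior mean.
    """
    b = np.linspace(-beta_half, beta_half, n_beta)
    s = np.linspace(0.0, sigma_max, n_sigma)
    db, ds = b[1] - b[0], s[1] - s[0]
    total = np.zeros((n_beta, n_sigma))
    for yi, ni in zip(y, n):
        total += _log_marg_table(float(yi), float(ni), b, s)
    total += _normal_logpdf(b, beta0_sd)[:, None]
    total += _halfnormal_logpdf(s, sigma_scale)[None, :]
    log_z = float(_log_trapz(_log_trapz(total, ds, axis=1), db, axis=0))
    log_pb = _log_trapz(total, ds, axis=1)  # marginal over sigma
    pb = np.exp(log_pb - logsumexp(log_pb))
    pb /= np.trapezoid(pb, b)
    beta_mean = float(np.trapezoid(pb * b, b))
    return {"log_marginal": log_z, "beta0_mean": beta_mean, "beta0_grid": b, "beta0_density": pb}


def grid_posterior_m1(
    y: np.ndarray, n: np.ndarray, affected: np.ndarray,
    beta0_sd: float = 3.0, delta_sd: float = 1.0, sigma_scale: float = 1.0,
    n_u: int = 321, u_half: float = 8.0,
    n_sigma: int = 161, sigma_max: float = 4.0,
) -> dict:
    """Grid posterior for eta_i = beta0 + delta*x_i + gamma_i (x = +-1/2).

    Integrates over (u, v, sigma) with u = beta0 + delta/2 (affected
    linear predictor), v = beta0 - delta/2; the change of variables has
    unit Jacobian, so priors are evaluated at beta0 = (u+v)/2 and
    delta = u - v.
    """
    u = np.linspace(-u_half, u_half, n_u)
    s = np.linspace(0.0, sigma_max, n_sigma)
    du, ds = u[1] - u[0], s[1] - s[0]
    A = np.zeros((n_u, n_sigma))  # affected individuals, predictor u
    B = np.zeros((n_u, n_sigma))  # unaffected, predictor v (same grid)
    for yi, ni, aff in zip(y, n, affected):
        t = _log_marg_table(float(yi), float(ni), u, s)
        if aff:
            A += t
        else:
            B += t
    beta0 = (u[:, None] + u[None, :]) / 2.0  # (u, v)
    delta = u[:, None] - u[None, :]
    log_prior = _normal_logpdf(beta0, beta0_sd) + _normal_logpdf(delta, delta_sd)
    total = (
        A[:, None, :] + B[None, :, :]
        + log_prior[:, :, None]
        + _halfnormal_logpdf(s, sigma_scale)[None, None, :]
    )
    log_z = float(_log_trapz(_log_trapz(_log_trapz(total, ds, axis=2), du, axis=1), du, axis=0))
    return {"log_marginal": log_z}


def grid_posterior_status_random(
    y: np.ndarray, n: np.ndarray, affected: np.ndarray,
    beta0_sd: float = 3.0, sigma_gamma_scale: float = 1.0, sigma_status_scale: float = 1.0,
    n_beta: int = 241, beta_half: float = 8.0,
    n_sigma: int = 81, sigma_max: float = 4.0,
) -> dict:
    """Grid posterior for the quantification model on 2-individual sites.

    With exactly one affected and one unaffected individual, the status
    random effect b_{s(i)} and gamma_i collapse to a single per-individual
    normal effect with variance sigma_s^2 + sigma_g^2, which factorizes
    the integral per individual. Valid only for such sites.
    """
    assert affected.sum() == 1 and (~affected.astype(bool)).sum() == 1
    b = np.linspace(-beta_half, beta_half, n_beta)
    sg = np.linspace(0.0, sigma_max, n_sigma)
    ss = np.linspace(0.0, sigma_max, n_sigma)
    db = b[1] - b[0]
    dsg = sg[1] - sg[0]
    # effective per-individual sd over the (sg, ss) grid
    eff = np.sqrt(sg[:, None] ** 2 + ss[None, :] ** 2).ravel()
    total = np.zeros((n_beta, eff.size))
    for yi, ni in zip(y, n):
        total += _log_marg_table(float(yi), float(ni), b, eff)
    total = total.reshape(n_beta, sg.size, ss.size)
    total += _normal_logpdf(b, beta0_sd)[:, None, None]
    total += _halfnormal_logpdf(sg, sigma_gamma_scale)[None, :, None]
    total += _halfnormal_logpdf(ss, sigma_status_scale)[None, None, :]
    inner = _log_trapz(_log_trapz(total, dsg, axis=2), dsg, axis=1)
    log_z = float(_log_trapz(inner, db, axis=0))
    pb = np.exp(inner - logsumexp(inner))
    pb /= np.trapezoid(pb, b)
    beta_mean = float(np.trapezoid(pb * b, b))
    return {"log_marginal": log_z, "beta0_mean": beta_mean}
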