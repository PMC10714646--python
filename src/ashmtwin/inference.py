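"""Posterior and marginal-likelihood engine for binomial logit mixed models.

The allelic-imbalance model at one SNP is

    y_i ~ Binomial(n_i, sigmoid(eta_i))
    eta_i = beta0 [+ delta * x_i] [+ b_{s(i)}] + gamma_i

with ``y_i`` the alternative-allele read count of heterozygous individual
``i``, ``beta0`` the allelic-imbalance intercept on the logit scale,
optionally a status effect (either effect-coded with a proper normal
prior on ``delta``, used for Bayes-factor model comparison, or as a
2-level mean-zero random effect ``b_s``, used for quantification), and a
per-individual random effect ``gamma_i``.

Priors (all proper, so marginal likelihoods are finite):

    beta0 ~ Normal(0, 3^2)         delta ~ Normal(0, 1)
    b_s   ~ Normal(0, sigma_s^2)   gamma_i ~ Normal(0, sigma_g^2)
    sigma_s, sigma_g ~ Half-Normal(1)

Inference strategy (a Laplace + quadrature backend):

1. The per-individual random effects are integrated out of the
   likelihood by adaptive Gauss-Hermite quadrature (nodes centered at
   each individual's conditional mode), leaving an unconstrained
   parameter vector of at most six dimensions:
   (beta0, [delta], [w_levels], [log sigma_s], log sigma_g), where the
   status levels use the non-centered scaling b_l = sigma_s * w_l.
2. The posterior mode of this marginal posterior is found by
   quasi-Newton optimization, and a Laplace Gaussian approximation is
   built from the numerical Hessian at the mode.
3. :func:`fit_model` refines the Laplace approximation by
   self-normalized importance sampling with a defensive mixture of
   multivariate-t proposals (the Laplace component plus a
   moment-matched one), yielding posterior draws of beta0 and the log
   marginal likelihood via the average importance weight — the route
   used for Bayes factors.
4. :func:`posterior_quadrature` instead integrates the same posterior
   deterministically on adaptively sized tensor grids (for the
   status-random-effect model, via an exact factorization over the
   per-status linear predictors), the route used for site-level
   posterior summaries and credible intervals.

All randomness is controlled by the settings seed; identical inputs and
seeds reproduce identical results, and the quadrature route is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp
from scipy.special import roots_hermite

__all__ = [
    "Priors",
    "InferenceSettings",
    "BinomialLogitModel",
    "FitResult",
    "QuadratureResult",
    "fit_model",
    "posterior_quadrature",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_LOG_SIGMA_BOUNDS = (-8.0, 3.0)
_GH_NODES, _GH_WEIGHTS = roots_hermite(15)
_GH_LOGW = np.log(_GH_WEIGHTS)


@dataclass(frozen=True)
class Priors:
    beta0_sd: float = 3.0
    delta_sd: float = 1.0
    sigma_gamma_scale: float = 1.0  # half-normal scale of the per-individual SD
    sigma_status_scale: float = 1.0  # half-normal scale of the status-level SD

    def scaled(self, factor: float) -> "Priors":
        """Widen/narrow every prior scale by ``factor`` (sensitivity runs)."""
        return Priors(
            self.beta0_sd * factor,
            self.delta_sd * factor,
            self.sigma_gamma_scale * factor,
            self.sigma_status_scale * factor,
        )


@dataclass(frozen=True)
class InferenceSettings:
    n_draws: int = 4000
    proposal_df: float = 5.0
    proposal_scale: float = 1.3
    n_adapt: int = 1  # moment-matching refinements of the t proposal
    seed: int = 0
    importance_refine: bool = True  # False -> pure Laplace (faster, cruder)


@dataclass
class FitResult:
    log_marginal: float
    log_marginal_laplace: float
    theta_map: np.ndarray
    param_names: list[str]
    beta0_draws: np.ndarray
    weights: np.ndarray  # normalized importance weights
    ess: float
    draws: np.ndarray | None = None
    sigma_gamma_draws: np.ndarray | None = None
    sigma_status_draws: np.ndarray | None = None

    def beta0_mean(self) -> float:
        return float(np.sum(self.weights * self.beta0_draws))

    def beta0_quantiles(self, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        return weighted_quantile(self.beta0_draws, self.weights, np.asarray(qs))

    def sigma_mean(self, which: str = "gamma") -> float:
        d = self.sigma_gamma_draws if which == "gamma" else self.sigma_status_draws
        if d is None:
            return float("nan")
        return float(np.sum(self.weights * d))


def weighted_quantile(x: np.ndarray, w: np.ndarray, qs: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum /= ws.sum()
    return np.interp(qs, cum, xs)


class BinomialLogitModel:
    """One site's model instance: marginal posterior over the fixed block.

    All latent effects are integrated out of the likelihood inside
    :meth:`log_post`: the per-individual gamma effects by adaptive
    Gauss-Hermite quadrature, and (when a status random effect is
    present) the level effects b_l = sigma_s * w_l by a second, nested
    adaptive Gauss-Hermite layer — the levels factorize given the
    scales. The explicit parameters are only
    (beta0, [delta], [log sigma_s], log sigma_g), a low-dimensional,
    funnel-free space on which Laplace + importance sampling is accurate.
    """

    def __init__(
        self,
        y: np.ndarray,
        n: np.ndarray,
        x_delta: np.ndarray | None = None,
        status_level: np.ndarray | None = None,
        priors: Priors | None = None,
    ):
        self.y = np.asarray(y, float)
        self.n = np.asarray(n, float)
        if self.y.size < 1 or (self.n < 1).any():
            raise ValueError("each individual needs at least one read")
        if (self.y < 0).any() or (self.y > self.n).any():
            raise ValueError("alt counts must lie in [0, n]")
        self.x = None if x_delta is None else np.asarray(x_delta, float)
        self.level = None if status_level is None else np.asarray(status_level, int)
        self.n_levels = 0 if self.level is None else int(self.level.max()) + 1
        self.priors = priors or Priors()
        self.I = self.y.size
        self._logC = gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)

        names = ["beta0"]
        if self.x is not None:
            names.append("delta")
        if self.n_levels:
            names.append("log_sigma_s")
        names.append("log_sigma_g")
        self.param_names = names
        self.dim = len(names)
        self._i_delta = 1 if self.x is not None else None
        self._i_ls = self.dim - 2 if self.n_levels else None
        self._i_lg = self.dim - 1

    # -- marginal likelihood of one parameter point (vectorized) ---------

    def _mu(self, theta: np.ndarray) -> np.ndarray:
        """Linear predictor without latent effects; shape (..., I)."""
        beta0 = theta[..., 0]
        mu = np.broadcast_to(beta0[..., None], theta.shape[:-1] + (self.I,)).copy()
        if self.x is not None:
            mu += theta[..., self._i_delta, None] * self.x
        return mu

    def _gamma_marginal(self, mu, s2, y, n, want_derivs: bool = False):
        """Adaptive GH integral over gamma for each (…, individual) cell.

        Returns log m (and its first/second mu-derivatives if asked),
        where m(mu) = Int Binom(y | n, sigmoid(mu+g)) N(g | 0, s2) dg,
        excluding the binomial coefficient.
        """
        g = np.zeros(np.broadcast_shapes(mu.shape, s2.shape, y.shape))
        mu = np.broadcast_to(mu, g.shape)
        # Newton for the conditional mode (integrand strictly log-concave)
        for _ in range(30):
            p = expit(mu + g)
            f1 = y - n * p - g / s2
            f2 = -n * p * (1 - p) - 1.0 / s2
            step = np.clip(f1 / f2, -5.0, 5.0)
            g = g - step
            if np.max(np.abs(f1)) < 1e-10:
                break
        p = expit(mu + g)
        f2 = -n * p * (1 - p) - 1.0 / s2
        shat = 1.0 / np.sqrt(-f2)
        nodes = g[..., None] + np.sqrt(2.0) * shat[..., None] * _GH_NODES
        eta = mu[..., None] + nodes
        vals = (
            y[..., None] * eta
            - n[..., None] * np.logaddexp(0.0, eta)
            - nodes**2 / (2.0 * s2[..., None])
            - 0.5 * np.log(2.0 * np.pi * s2[..., None])
            + _GH_NODES**2 + _GH_LOGW
        )
        log_m = 0.5 * np.log(2.0) + np.log(shat) + logsumexp(vals, axis=-1)
        if not want_derivs:
            return log_m
        # node-weighted posterior moments give d log m / d mu and its slope
        pw = np.exp(vals - log_m[..., None] + 0.5 * np.log(2.0) + np.log(shat)[..., None])
        pw /= pw.sum(axis=-1, keepdims=True)
        pn = expit(eta)
        r = y[..., None] - n[..., None] * pn
        d1 = np.sum(pw * r, axis=-1)
        d2 = np.sum(pw * (r**2 - n[..., None] * pn * (1 - pn)), axis=-1) - d1**2
        # log m is log-concave in mu, so d2 <= 0 exactly; clamp the
        # floating-point cancellation that can push it slightly positive
        d2 = np.minimum(d2, -1e-12)
        return log_m, d1, d2

    def _loglik_marginal(self, mu: np.ndarray, sigma_g: np.ndarray, sigma_s=None) -> np.ndarray:
        """log p(y | theta) with gamma (and level effects) integrated out."""
        s2 = np.maximum(sigma_g[..., None] ** 2, 1e-12)
        if not self.n_levels:
            log_m = self._gamma_marginal(mu, s2, self.y, self.n)
            return np.sum(self._logC + log_m, axis=-1)

        ss = sigma_s[..., None]  # broadcast over individuals of a level
        total = np.sum(self._logC) + np.zeros(mu.shape[:-1])
        for l in range(self.n_levels):
            idx = np.flatnonzero(self.level == l)
            y_l, n_l = self.y[idx], self.n[idx]
            mu_l = mu[..., idx]
            # adaptive GH over the level effect w ~ N(0,1), b = sigma_s * w:
            # Newton on H(w) = sum_i log m_i(mu_i + sigma_s w) - w^2/2
            w = np.zeros(mu.shape[:-1])
            for _ in range(8):
                _, d1, d2 = self._gamma_marginal(
                    mu_l + ss * w[..., None], s2, y_l, n_l, want_derivs=True
                )
                h1 = ss[..., 0] * d1.sum(axis=-1) - w
                h2 = ss[..., 0] ** 2 * d2.sum(axis=-1) - 1.0
                w = w - np.clip(h1 / h2, -4.0, 4.0)
                if np.max(np.abs(h1)) < 1e-8:
                    break
            _, d1, d2 = self._gamma_marginal(
                mu_l + ss * w[..., None], s2, y_l, n_l, want_derivs=True
            )
            h2 = ss[..., 0] ** 2 * d2.sum(axis=-1) - 1.0
            sw = 1.0 / np.sqrt(-h2)
            w_nodes = w[..., None] + np.sqrt(2.0) * sw[..., None] * _GH_NODES
            # H at the nodes: (..., K) after summing the level's individuals
            log_m = self._gamma_marginal(
                mu_l[..., None, :] + ss[..., None] * w_nodes[..., None],
                s2[..., None, :], y_l, n_l,
            ).sum(axis=-1)
            h_vals = (
                log_m - w_nodes**2 / 2.0 - 0.5 * _LOG2PI
                + _GH_NODES**2 + _GH_LOGW
            )
            total = total + 0.5 * np.log(2.0) + np.log(sw) + logsumexp(h_vals, axis=-1)
        return total

    def log_post(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior with all latent effects integrated out.

        ``theta`` may be (dim,) or (M, dim).
        """
        theta = np.asarray(theta, float)
        mu = self._mu(theta)
        sigma_g = np.exp(theta[..., self._i_lg])
        sigma_s = np.exp(theta[..., self._i_ls]) if self.n_levels else None
        lp = self._loglik_marginal(mu, sigma_g, sigma_s)
        pr = self.priors
        beta0 = theta[..., 0]
        lp = lp - 0.5 * _LOG2PI - np.log(pr.beta0_sd) - beta0**2 / (2 * pr.beta0_sd**2)
        if self.x is not None:
            delta = theta[..., self._i_delta]
            lp = lp - 0.5 * _LOG2PI - np.log(pr.delta_sd) - delta**2 / (2 * pr.delta_sd**2)
        if self.n_levels:
            log_ss = theta[..., self._i_ls]
            lp = lp + self._halfnormal_logpdf(sigma_s, log_ss, pr.sigma_status_scale)
        log_sg = theta[..., self._i_lg]
        lp = lp + self._halfnormal_logpdf(sigma_g, log_sg, pr.sigma_gamma_scale)
        return lp

    @staticmethod
    def _halfnormal_logpdf(sigma, log_sigma, scale):
        # density in sigma plus the log-sigma Jacobian
        return (
            np.log(2.0) - 0.5 * _LOG2PI - np.log(scale)
            - sigma**2 / (2.0 * scale**2) + log_sigma
        )

    # -- fitting ---------------------------------------------------------

    def _initial_theta(self) -> np.ndarray:
        theta = np.zeros(self.dim)
        frac = np.clip(self.y.sum() / self.n.sum(), 0.02, 0.98)
        theta[0] = np.log(frac / (1 - frac))
        theta[self._i_lg] = np.log(0.3)
        if self.n_levels:
            theta[self._i_ls] = np.log(0.3)
        return theta

    def find_map(self) -> np.ndarray:
        bounds = [(None, None)] * self.dim
        bounds[self._i_lg] = _LOG_SIGMA_BOUNDS
        if self.n_levels:
            bounds[self._i_ls] = _LOG_SIGMA_BOUNDS
        res = optimize.minimize(
            lambda t: -self.log_post(t),
            self._initial_theta(),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-13},
        )
        return res.x

    def neg_hessian(self, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
        """Numerical negative Hessian of log_post at theta (central diffs)."""
        d = self.dim
        steps = h * np.maximum(1.0, np.abs(theta))
        f0 = float(self.log_post(theta))
        H = np.empty((d, d))
        fp = np.empty(d)
        fm = np.empty(d)
        for j in range(d):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += steps[j]
            tm[j] -= steps[j]
            fp[j] = self.log_post(tp)
            fm[j] = self.log_post(tm)
            H[j, j] = (fp[j] - 2 * f0 + fm[j]) / steps[j] ** 2
        for j in range(d):
            for k in range(j + 1, d):
                t = theta.copy()
                t[j] += steps[j]
                t[k] += steps[k]
                fpp = float(self.log_post(t))
                H[j, k] = H[k, j] = (
                    fpp - fp[j] - fp[k] + f0
                ) / (steps[j] * steps[k])
        A = -H
        w, V = np.linalg.eigh(A)
        if w.min() < 1e-6:
            w = np.clip(w, 1e-2, None)
            A = (V * w) @ V.T
        return A

    def sigma_draws(self, draws: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        sg = np.exp(draws[:, self._i_lg])
        ss = np.exp(draws[:, self._i_ls]) if self.n_levels else None
        return sg, ss


def _mvt_logpdf(dev: np.ndarray, chol: np.ndarray, df: float) -> np.ndarray:
    d = dev.shape[-1]
    sol = np.linalg.solve(chol, dev.T).T
    maha = np.sum(sol**2, axis=-1)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return (
        gammaln((df + d) / 2) - gammaln(df / 2)
        - 0.5 * d * np.log(df * np.pi) - 0.5 * logdet
        - 0.5 * (df + d) * np.log1p(maha / df)
    )


def fit_model(model: BinomialLogitModel, settings: InferenceSettings | None = None) -> FitResult:
    """MAP + Laplace + importance-sampling fit of one site model."""
    settings = settings or InferenceSettings()
    theta_map = model.find_map()
    A = model.neg_hessian(theta_map)
    _, logdet_A = np.linalg.slogdet(A)
    lj_map = float(model.log_post(theta_map))
    log_z_laplace = lj_map + 0.5 * model.dim * _LOG2PI - 0.5 * logdet_A

    rng = np.random.default_rng(settings.seed)
    if not settings.importance_refine:
        cov = np.linalg.inv(A)
        draws = rng.multivariate_normal(theta_map, cov, size=settings.n_draws)
        w = np.full(settings.n_draws, 1.0 / settings.n_draws)
        sg, ss = model.sigma_draws(draws)
        return FitResult(
            log_z_laplace, log_z_laplace, theta_map, model.param_names,
            draws[:, 0], w, float(settings.n_draws), draws, sg, ss,
        )

    df = settings.proposal_df
    cov0 = np.linalg.inv(A) * settings.proposal_scale**2
    chol0 = np.linalg.cholesky(cov0)

    def _draw_t(center, chol, n):
        z = rng.standard_normal((n, model.dim))
        u = rng.chisquare(df, size=n) / df
        return center + (z @ chol.T) / np.sqrt(u)[:, None]

    # pilot: moment-match a second proposal component, with truncated
    # importance weights so a few extreme weights cannot derail the moments
    center1, chol1 = theta_map, chol0
    n_pilot = max(500, settings.n_draws // 2)
    for _ in range(max(0, settings.n_adapt)):
        draws = _draw_t(center1, chol1, n_pilot)
        log_w = model.log_post(draws) - _mvt_logpdf(draws - center1, chol1, df)
        log_w = np.minimum(
            log_w, logsumexp(log_w) - np.log(n_pilot) + 0.5 * np.log(n_pilot)
        )
        w = np.exp(log_w - logsumexp(log_w))
        if 1.0 / np.sum(w**2) < 3 * model.dim:
            chol1 = chol1 * 1.4  # too few effective points to trust moments
            continue
        center1 = w @ draws
        dev = draws - center1
        cov1 = (dev * w[:, None]).T @ dev * settings.proposal_scale**2
        cov1 += 1e-8 * np.eye(model.dim)
        chol1 = np.linalg.cholesky(cov1)

    # final stage: defensive 50/50 mixture of the Laplace component and
    # the adapted component, so a poor adaptation cannot lose the mass
    # the Laplace approximation does cover
    n_half = settings.n_draws // 2
    draws = np.vstack(
        [_draw_t(theta_map, chol0, n_half), _draw_t(center1, chol1, settings.n_draws - n_half)]
    )
    log_q = np.logaddexp(
        _mvt_logpdf(draws - theta_map, chol0, df),
        _mvt_logpdf(draws - center1, chol1, df),
    ) - np.log(2.0)
    log_w = model.log_post(draws) - log_q
    log_z = float(logsumexp(log_w) - np.log(draws.shape[0]))
    w = np.exp(log_w - logsumexp(log_w))
    ess = float(1.0 / np.sum(w**2))
    sg, ss = model.sigma_draws(draws)
    return FitResult(
        log_z, log_z_laplace, theta_map, model.param_names, draws[:, 0], w, ess, draws, sg, ss
    )


@dataclass
class QuadratureResult:
    """Deterministic tensor-grid posterior summary of one site model.

    The beta0 marginal density is obtained by integrating the
    latent-marginalized posterior over the remaining scale (and effect)
    dimensions on an adaptively sized grid anchored at the Laplace
    approximation. All quantities are deterministic functions of the
    data and priors.
    """

    log_marginal: float
    beta0_grid: np.ndarray
    beta0_density: np.ndarray  # normalized w.r.t. trapezoid integration
    beta0_mean: float
    prob_le_zero: float
    sigma_gamma_mean: float
    sigma_status_mean: float
    theta_map: np.ndarray

    def beta0_quantiles(self, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        b, f = self.beta0_grid, self.beta0_density
        cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2 * np.diff(b))])
        cdf /= cdf[-1]
        return np.interp(np.asarray(qs), cdf, b)

    def tail_pvalue(self) -> float:
        p = self.prob_le_zero
        return min(1.0, 2.0 * min(p, 1.0 - p))

    def sample_beta0(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Posterior draws of beta0 by inverse-CDF sampling of the grid."""
        b, f = self.beta0_grid, self.beta0_density
        cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2 * np.diff(b))])
        cdf /= cdf[-1]
        return np.interp(rng.random(n), cdf, b)


def _log_trapz_axis(log_f: np.ndarray, grid: np.ndarray, axis: int) -> np.ndarray:
    dx = grid[1] - grid[0]
    w = np.full(grid.size, dx)
    w[0] = w[-1] = dx / 2.0
    shape = [1] * log_f.ndim
    shape[axis] = grid.size
    return logsumexp(log_f + np.log(w).reshape(shape), axis=axis)


def _status_quadrature(
    model: BinomialLogitModel,
    theta_map: np.ndarray,
    sd: np.ndarray,
    n_beta: int,
    n_sigma: int,
) -> QuadratureResult:
    """Grid posterior for the status-random-effect model, computed by
    conditioning on the per-status linear predictors.

    With u_s = beta0 + b_s the likelihood factorizes over individuals
    given (u_aff, u_un, sigma_g); each u_s has prior N(beta0, sigma_s^2),
    so the u integrals are Gaussian convolutions of the per-status
    profile likelihoods, evaluated as matrix products over a fine u
    grid. Exact in the sigma_s -> 0 limit via kernel renormalization.
    """
    grids_ls = []
    for j in (model._i_ls, model._i_lg):
        lo = max(theta_map[j] - max(6.0 * sd[j], 2.0), _LOG_SIGMA_BOUNDS[0])
        hi = min(theta_map[j] + max(4.0 * sd[j], 1.5), _LOG_SIGMA_BOUNDS[1])
        grids_ls.append(np.linspace(lo, hi, n_sigma))
    ls_grid, lg_grid = grids_ls
    ss = np.exp(ls_grid)
    sg = np.exp(lg_grid)

    u = np.arange(-18.0, 18.0 + 1e-9, 0.08)
    # per-status profile log-likelihood tables over (u, sigma_g)
    tables = []
    for l in range(model.n_levels):
        idx = np.flatnonzero(model.level == l)
        log_m = model._gamma_marginal(
            u[:, None, None], np.maximum(sg[None, :, None] ** 2, 1e-12),
            model.y[idx], model.n[idx],
        ).sum(axis=-1)  # (u, sigma_g)
        tables.append(log_m + model._logC[idx].sum())
    du = u[1] - u[0]
    w_trap = np.full(u.size, du)
    w_trap[0] = w_trap[-1] = du / 2.0
    pr = model.priors
    b_half = max(7.0 * sd[0], 0.75)
    for _ in range(4):
        # keep the beta0 grid inside the u table's support
        lo = max(theta_map[0] - b_half, u[0] + 1.0)
        hi = min(theta_map[0] + b_half, u[-1] - 1.0)
        b = np.linspace(lo, hi, n_beta)
        # Gaussian convolution kernels N(u | beta0, sigma_s^2) with trapezoid
        # weights, renormalized per column (exact point mass as sigma_s -> 0)
        dev = u[:, None, None] - b[None, :, None]  # (u, beta0, sigma_s)
        log_k = -(dev**2) / (2.0 * np.maximum(ss[None, None, :], 1e-8) ** 2)
        # per-column max subtraction keeps narrow kernels from underflowing
        kern = np.exp(log_k - log_k.max(axis=0, keepdims=True))
        kern *= w_trap[:, None, None]
        kern /= kern.sum(axis=0, keepdims=True)
        kern = kern.reshape(u.size, -1)  # (u, beta0*sigma_s)

        total = np.zeros((n_beta, n_sigma, n_sigma))  # (beta0, sigma_s, sigma_g)
        with np.errstate(divide="ignore"):
            for t in tables:
                mx = t.max(axis=0, keepdims=True)  # per sigma_g column
                conv = np.log(np.exp(t - mx).T @ kern) + mx.T  # (sigma_g, beta0*sigma_s)
                total += conv.reshape(n_sigma, n_beta, n_sigma).transpose(1, 2, 0)
        total += (
            -0.5 * _LOG2PI - np.log(pr.beta0_sd) - b**2 / (2 * pr.beta0_sd**2)
        )[:, None, None]
        total += model._halfnormal_logpdf(ss, ls_grid, pr.sigma_status_scale)[None, :, None]
        total += model._halfnormal_logpdf(sg, lg_grid, pr.sigma_gamma_scale)[None, None, :]

        log_b = _log_trapz_axis(_log_trapz_axis(total, lg_grid, 2), ls_grid, 1)
        log_z = float(_log_trapz_axis(log_b, b, 0))
        dens = np.exp(log_b - log_b.max())
        if max(dens[0], dens[-1]) < 1e-8 * dens.max():
            break
        b_half *= 1.6  # visible mass at the beta0 boundary: widen and retry
    dens = dens / np.trapezoid(dens, b)
    mean = float(np.trapezoid(dens * b, b))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(b))])
    cdf /= cdf[-1]

    def _scale_mean(axis, grid):
        log_m = total
        for ax in (2, 1, 0):
            if ax != axis:
                gr = (b, ls_grid, lg_grid)[ax]
                log_m = _log_trapz_axis(log_m, gr, ax)
        d = np.exp(log_m - log_m.max())
        d /= np.trapezoid(d, grid)
        return float(np.trapezoid(d * np.exp(grid), grid))

    return QuadratureResult(
        log_marginal=log_z,
        beta0_grid=b,
        beta0_density=dens,
        beta0_mean=mean,
        prob_le_zero=float(np.interp(0.0, b, cdf)),
        sigma_gamma_mean=_scale_mean(2, lg_grid),
        sigma_status_mean=_scale_mean(1, ls_grid),
        theta_map=theta_map,
    )


def posterior_quadrature(
    model: BinomialLogitModel,
    n_beta: int = 61,
    n_sigma: int = 15,
    max_widen: int = 2,
) -> QuadratureResult:
    """Tensor-grid quadrature posterior for (beta0, [delta], scales).

    Grid ranges are sized from the Laplace standard deviations at the
    posterior mode and widened automatically while visible density mass
    touches the beta0 boundary. Status-random-effect models dispatch to
    the factorized convolution path.
    """
    theta_map = model.find_map()
    A = model.neg_hessian(theta_map)
    sd = np.sqrt(np.diag(np.linalg.inv(A)))
    if model.n_levels:
        return _status_quadrature(model, theta_map, sd, n_beta, n_sigma)

    half = max(7.0 * sd[0], 0.75)
    for _ in range(max_widen + 1):
        grids = []
        for j in range(model.dim):
            if j == 0:
                g = np.linspace(theta_map[0] - half, theta_map[0] + half, n_beta)
            elif j == model._i_delta:
                w = max(7.0 * sd[j], 0.75)
                g = np.linspace(theta_map[j] - w, theta_map[j] + w, n_beta)
            else:  # log sigma dimensions
                lo = max(theta_map[j] - max(6.0 * sd[j], 2.0), _LOG_SIGMA_BOUNDS[0])
                hi = min(theta_map[j] + max(4.0 * sd[j], 1.5), _LOG_SIGMA_BOUNDS[1])
                g = np.linspace(lo, hi, n_sigma)
            grids.append(g)
        mesh = np.meshgrid(*grids, indexing="ij")
        theta = np.stack([m.ravel() for m in mesh], axis=-1)
        log_f = model.log_post(theta).reshape([g.size for g in grids])
        # integrate out everything but beta0 (and the Jacobians are unit:
        # the grid is over the unconstrained parameterization itself)
        log_b = log_f
        for axis in range(model.dim - 1, 0, -1):
            log_b = _log_trapz_axis(log_b, grids[axis], axis)
        log_z = float(_log_trapz_axis(log_b, grids[0], 0))
        dens = np.exp(log_b - log_b.max())
        edge = max(dens[0], dens[-1]) / dens.max()
        if edge < 1e-8:
            break
        half *= 1.6  # visible mass at the boundary: widen and retry
    b = grids[0]
    dens = dens / np.trapezoid(dens, b)
    mean = float(np.trapezoid(dens * b, b))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(b))])
    cdf /= cdf[-1]
    prob_le_zero = float(np.interp(0.0, b, cdf))

    # posterior means of the scales from their own 1-D marginals
    def _scale_mean(axis):
        log_m = log_f
        for ax in range(model.dim - 1, -1, -1):
            if ax != axis:
                log_m = _log_trapz_axis(log_m, grids[ax], ax)
        d = np.exp(log_m - log_m.max())
        d /= np.trapezoid(d, grids[axis])
        return float(np.trapezoid(d * np.exp(grids[axis]), grids[axis]))

    sigma_g_mean = _scale_mean(model._i_lg)
    sigma_s_mean = _scale_mean(model._i_ls) if model.n_levels else float("nan")
    return QuadratureResult(
        log_marginal=log_z,
        beta0_grid=b,
        beta0_density=dens,
        beta0_mean=mean,
        prob_le_zero=prob_le_zero,
        sigma_gamma_mean=sigma_g_mean,
        sigma_status_mean=sigma_s_mean,
        theta_map=theta_map,
    )
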