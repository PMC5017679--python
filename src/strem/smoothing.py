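"""Bayesian smoothing models extending the FMP track-count estimator.

Counts ``X`` are negative-binomially distributed around ``mu = e * a`` where
``e`` is the known survey offset (``(2/pi) * E[L] * sum(M*D)``) and ``a`` is
the latent density on the reference habitat.  ``log a = b + z`` with ``z``
either a yearly AR1 process (temporal model) or a separable AR1-in-time x
Matern-in-space Gaussian field evaluated at the survey sites
(spatio-temporal model).

Inference is INLA-style: for fixed hyperparameters the latent Gaussian field
is integrated out with a Laplace approximation (the NB log-likelihood is
log-concave in ``z``, so the inner Newton optimisation is well behaved), and
the resulting approximate marginal posterior of the hyperparameters is
explored with an affine-invariant ensemble sampler (emcee).  Latent draws
are then sampled from the Gaussian conditional at each retained
hyperparameter draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import gammaln, kv, gamma as gamma_fn

import emcee

__all__ = [
    "nb_logpmf",
    "matern_covariance",
    "simulate_latent",
    "PriorPreset",
    "DEFAULT_PRIOR",
    "RELAXED_PRIOR",
    "get_prior",
    "PosteriorFit",
    "fit_temporal",
    "fit_spatiotemporal",
    "predict_density_field",
    "matern_krige",
]


# --------------------------------------------------------------------------
# Distributions
# --------------------------------------------------------------------------

def nb_logpmf(x, mu, r):
    """Negative-binomial log-pmf with mean ``mu`` and size ``r``.

    Variance is ``mu + mu**2 / r``; the success probability of the classical
    parameterization is ``p = r / (r + mu)``.  ``r -> inf`` recovers Poisson.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(mu <= 0) or np.any(r <= 0) or np.any(x < 0):
        raise ValueError("require mu > 0, r > 0, x >= 0")
    return (gammaln(x + r) - gammaln(r) - gammaln(x + 1)
            + r * np.log(r / (r + mu)) + x * np.log(mu / (r + mu)))


def matern_covariance(d, sigma2, kappa, nu=1.0):
    """Matern covariance ``C(d) = sigma2 * 2^(1-nu)/Gamma(nu) (kappa d)^nu K_nu(kappa d)``.

    ``kappa`` is the inverse spatial scale (1/km); ``C(0) = sigma2``.
    """
    d = np.asarray(d, dtype=float)
    if sigma2 <= 0 or kappa <= 0 or nu <= 0:
        raise ValueError("sigma2, kappa, nu must be positive")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    u = kappa * d
    out = np.empty_like(u)
    zero = u == 0
    uu = np.where(zero, 1.0, u)
    out = sigma2 * (2.0 ** (1 - nu) / gamma_fn(nu)) * uu ** nu * kv(nu, uu)
    out = np.where(zero, sigma2, out)
    return out if out.ndim else float(out)


def simulate_latent(n_years, phi, sigma2, rng, sites=None, kappa=None, nu=1.0):
    """Draw the latent state process from its prior.

    Temporal (``sites is None``): returns ``z`` of shape ``(n_years,)`` with
    ``z_1 ~ N(0, sigma2/(1-phi^2))`` and ``z_t = phi z_{t-1} + eps_t``,
    ``eps_t ~ N(0, sigma2)``.

    Spatio-temporal: returns shape ``(n_years, n_sites)`` with innovations
    spatially correlated by a Matern covariance with variance ``sigma2`` and
    inverse scale ``kappa`` (stationary over time).
    """
    if not (abs(phi) < 1 and sigma2 >= 0):
        raise ValueError("require |phi| < 1 and sigma2 >= 0")
    if sites is None:
        z = np.empty(n_years)
        z[0] = rng.normal(0.0, np.sqrt(sigma2 / (1 - phi ** 2)))
        eps = rng.normal(0.0, np.sqrt(sigma2), size=n_years - 1)
        for t in range(1, n_years):
            z[t] = phi * z[t - 1] + eps[t - 1]
        return z
    sites = np.asarray(sites, dtype=float)
    S = len(sites)
    D = np.hypot(sites[:, None, 0] - sites[None, :, 0],
                 sites[:, None, 1] - sites[None, :, 1])
    K = matern_covariance(D, sigma2, kappa, nu) + 1e-10 * sigma2 * np.eye(S)
    L = np.linalg.cholesky(K)
    Z = np.empty((n_years, S))
    Z[0] = L @ rng.standard_normal(S) / np.sqrt(1 - phi ** 2)
    for t in range(1, n_years):
        Z[t] = phi * Z[t - 1] + L @ rng.standard_normal(S)
    return Z


# --------------------------------------------------------------------------
# Priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorPreset:
    """Hyperpriors on the transformed latent-model parameters.

    theta1 = log precision of the AR1 innovations (sigma2 = exp(-theta1));
    theta2 = log((1+phi)/(1-phi)).  ``theta1`` is either
    ``("normal", mean, precision)`` or ``("loggamma", shape, rate)`` (the
    latter places a Gamma(shape, rate) prior on the precision itself).
    """

    name: str
    theta1: tuple = ("normal", 0.0, 1.0)
    theta2: tuple = ("normal", 1.0, 1.0)
    b_mean: float = 0.0
    b_sd: float = 10.0
    logr_mean: float = 0.0
    logr_sd: float = 1.5
    logkappa_mean: float = float(np.log(0.01))  # prior median range 100 km
    logkappa_sd: float = 1.5

    def logpdf(self, b, theta1, theta2, logr, logkappa=None) -> float:
        lp = -0.5 * ((b - self.b_mean) / self.b_sd) ** 2
        lp += -0.5 * ((logr - self.logr_mean) / self.logr_sd) ** 2
        kind = self.theta1[0]
        if kind == "normal":
            _, m, tau = self.theta1
            lp += -0.5 * tau * (theta1 - m) ** 2
        elif kind == "loggamma":
            _, shape, rate = self.theta1
            lp += shape * theta1 - rate * np.exp(min(theta1, 500.0))
        else:  # pragma: no cover - config error
            raise ValueError(f"unknown theta1 prior kind {kind!r}")
        _, m2, tau2 = self.theta2
        lp += -0.5 * tau2 * (theta2 - m2) ** 2
        if logkappa is not None:
            lp += -0.5 * ((logkappa - self.logkappa_mean) / self.logkappa_sd) ** 2
        return float(lp)


#: Tight-shrinkage preset emulating an over-smoothing engine default (T1):
#: diffuse Gamma(1, 5e-5) on the innovation precision favours tiny sigma2.
DEFAULT_PRIOR = PriorPreset(name="default",
                            theta1=("loggamma", 1.0, 5e-5),
                            theta2=("normal", 0.0, 0.15))

#: Relaxed preset (T2): Gaussian(0, prec 1) on theta1, Gaussian(1, prec 1)
#: on theta2 -- provides much less smoothing.
RELAXED_PRIOR = PriorPreset(name="relaxed",
                            theta1=("normal", 0.0, 1.0),
                            theta2=("normal", 1.0, 1.0))

_PRESETS = {"default": DEFAULT_PRIOR, "relaxed": RELAXED_PRIOR,
            "T1": DEFAULT_PRIOR, "T2": RELAXED_PRIOR}


def get_prior(name_or_preset) -> PriorPreset:
    if isinstance(name_or_preset, PriorPreset):
        return name_or_preset
    try:
        return _PRESETS[name_or_preset]
    except KeyError:
        raise ValueError(f"unknown prior preset {name_or_preset!r}") from None


def _unpack(eta):
    b, theta1, theta2, logr = eta[:4]
    sigma2 = float(np.exp(-theta1))
    phi = float(np.tanh(theta2 / 2.0))
    r = float(np.exp(logr))
    kappa = float(np.exp(eta[4])) if len(eta) > 4 else None
    return b, phi, sigma2, r, kappa


# --------------------------------------------------------------------------
# Laplace approximation of the latent field
# --------------------------------------------------------------------------

def _ar1_precision(T, phi):
    """Tridiagonal AR1 precision with unit innovation variance; det = 1-phi^2."""
    Q = np.zeros((T, T))
    idx = np.arange(T)
    Q[idx, idx] = 1.0 + phi ** 2
    Q[0, 0] = Q[-1, -1] = 1.0
    Q[idx[:-1], idx[:-1] + 1] = -phi
    Q[idx[:-1] + 1, idx[:-1]] = -phi
    return Q


def _nb_grad_hess(x, mu, r):
    # d/dz of NB loglik with mu = e*exp(b+z): g = x - (x+r) mu/(r+mu)
    g = x - (x + r) * mu / (r + mu)
    w = (x + r) * r * mu / (r + mu) ** 2  # = -d2/dz2, always > 0
    return g, w


def _laplace(x, e, obs_idx, n_latent, b, r, Q, half_logdet_Q, z0=None):
    """Newton-maximize p(x|z) p(z) over z; return Laplace log-marginal pieces.

    Returns (logmarg, zhat, L) where L is the lower Cholesky factor of
    (Q + W); logmarg approximates log p(x | hyperparameters) up to the
    constant -n/2 log(2 pi) terms which cancel across hyperparameters.
    """
    z = np.zeros(n_latent) if z0 is None else z0.copy()

    def parts(z):
        lin = np.clip(b + z[obs_idx], -300, 300)
        mu = e * np.exp(lin)
        ll = float(np.sum(nb_logpmf(x, mu, r)))
        return mu, ll

    mu, ll = parts(z)
    f = ll - 0.5 * z @ Q @ z
    for _ in range(100):
        g_obs, w_obs = _nb_grad_hess(x, mu, r)
        g = np.zeros(n_latent)
        w = np.zeros(n_latent)
        np.add.at(g, obs_idx, g_obs)
        np.add.at(w, obs_idx, w_obs)
        grad = g - Q @ z
        if np.max(np.abs(grad)) < 1e-6:
            break
        A = Q.copy()
        A[np.diag_indices_from(A)] += w
        try:
            c, low = linalg.cho_factor(A, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf, z, None
        step = linalg.cho_solve((c, low), grad, check_finite=False)
        # damped update
        lam = 1.0
        for _ in range(30):
            z_new = z + lam * step
            mu_new, ll_new = parts(z_new)
            f_new = ll_new - 0.5 * z_new @ Q @ z_new
            if f_new >= f - 1e-12:
                break
            lam *= 0.5
        if f_new < f - 1e-9:  # no progress
            break
        z, mu, ll, f = z_new, mu_new, ll_new, f_new
    # final curvature at the mode
    _, w_obs = _nb_grad_hess(x, mu, r)
    w = np.zeros(n_latent)
    np.add.at(w, obs_idx, w_obs)
    A = Q.copy()
    A[np.diag_indices_from(A)] += w
    try:
        c, low = linalg.cho_factor(A, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf, z, None
    L = np.tril(c)
    logmarg = f + half_logdet_Q - float(np.sum(np.log(np.diag(L))))
    return logmarg, z, L


# --------------------------------------------------------------------------
# Posterior container
# --------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    """Joint posterior over hyperparameters and the latent density field."""

    kind: str                      # "temporal" | "spatiotemporal"
    prior: str
    years: np.ndarray
    eta_draws: np.ndarray          # (n_draws, n_eta)
    z_draws: np.ndarray            # (n_draws, n_latent)
    sites: np.ndarray | None
    offsets: np.ndarray
    counts: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    failed: bool = False

    @property
    def n_draws(self) -> int:
        return len(self.eta_draws)

    @property
    def param_draws(self) -> dict:
        b = self.eta_draws[:, 0]
        sigma2 = np.exp(-self.eta_draws[:, 1])
        phi = np.tanh(self.eta_draws[:, 2] / 2.0)
        r = np.exp(self.eta_draws[:, 3])
        out = {"b": b, "phi": phi, "sigma2": sigma2, "r": r}
        if self.eta_draws.shape[1] > 4:
            out["kappa"] = np.exp(self.eta_draws[:, 4])
        return out

    def density_draws(self) -> np.ndarray:
        """Posterior draws of the reference-habitat density ``a``.

        Shape ``(n_draws, T)`` for the temporal model and
        ``(n_draws, T, S)`` for the spatio-temporal model.
        """
        a = np.exp(self.eta_draws[:, [0]] + self.z_draws)
        if self.kind == "spatiotemporal":
            T, S = len(self.years), len(self.sites)
            return a.reshape(self.n_draws, T, S)
        return a


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _run_ensemble(logprob, eta0, n_walkers, n_steps, n_burn, rng):
    ndim = len(eta0)
    n_walkers = max(n_walkers, 2 * ndim + 2)
    p0 = eta0[None, :] + 0.15 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, logprob)
    seed = int(rng.integers(2 ** 31 - 1))
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    logp = sampler.get_log_prob(discard=n_burn, flat=True)
    acc = float(np.mean(sampler.acceptance_fraction))
    return chain, logp, acc


def _fit_core(x, e, obs_idx, n_latent, q_builder, eta0, prior_logpdf, rng,
              n_walkers, n_steps, n_burn, n_draws):
    x = np.asarray(x, dtype=float)
    e = np.asarray(e, dtype=float)
    warm = {"z": None}
    newton_failures = [0]

    def logprob(eta):
        lp = prior_logpdf(eta)
        if not np.isfinite(lp):
            return -np.inf
        b, phi, sigma2, r, kappa = _unpack(eta)
        if not np.isfinite(sigma2) or sigma2 <= 0 or sigma2 > 1e6 or r > 1e8:
            return -np.inf
        built = q_builder(eta)
        if built is None:
            return -np.inf
        Q, half_logdet_Q = built
        lm, zhat, L = _laplace(x, e, obs_idx, n_latent, b, r, Q,
                               half_logdet_Q, z0=warm["z"])
        if L is None or not np.isfinite(lm):
            newton_failures[0] += 1
            return -np.inf
        warm["z"] = zhat
        return lp + lm

    chain, logp, acc = _run_ensemble(logprob, eta0, n_walkers, n_steps,
                                     n_burn, rng)
    finite = np.isfinite(logp)
    failed = not finite.any() or acc < 0.02
    if not finite.any():
        eta_draws = np.tile(eta0, (n_draws, 1))
        z_draws = np.zeros((n_draws, n_latent))
        return eta_draws, z_draws, {"acceptance_fraction": acc,
                                    "newton_failures": newton_failures[0],
                                    "max_logprob": float("-inf")}, True
    chain, logp = chain[finite], logp[finite]
    pick = rng.choice(len(chain), size=n_draws, replace=True)
    eta_draws = chain[pick]
    z_draws = np.empty((n_draws, n_latent))
    cache = {}
    for i, eta in enumerate(eta_draws):
        key = eta.tobytes()
        if key not in cache:
            b, phi, sigma2, r, kappa = _unpack(eta)
            Q, half_logdet_Q = q_builder(eta)
            _, zhat, L = _laplace(x, e, obs_idx, n_latent, b, r, Q,
                                  half_logdet_Q, z0=warm["z"])
            cache[key] = (zhat, L)
        zhat, L = cache[key]
        if L is None:
            z_draws[i] = zhat
            continue
        xi = rng.standard_normal(n_latent)
        z_draws[i] = zhat + linalg.solve_triangular(L, xi, trans="T", lower=True)
    diag = {"acceptance_fraction": acc,
            "newton_failures": newton_failures[0],
            "max_logprob": float(np.max(logp))}
    failed = failed or not np.all(np.isfinite(z_draws))
    return eta_draws, z_draws, diag, failed


def fit_temporal(counts, offsets, prior="relaxed", rng=None, years=None,
                 n_walkers=12, n_steps=400, n_burn=200, n_draws=300
                 ) -> PosteriorFit:
    """Fit the yearly AR1 negative-binomial state-space model.

    Parameters
    ----------
    counts : (T,) yearly total crossing counts.
    offsets : (T,) yearly offsets ``e_t = (2/pi) E[L] sum_i M_it D_it``.
    prior : "default" (over-smoothing T1 preset), "relaxed" (T2 preset) or a
        :class:`PriorPreset`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(counts, dtype=float)
    e = np.asarray(offsets, dtype=float)
    T = len(x)
    if T < 3:
        raise ValueError("need at least 3 years")
    if np.any(e <= 0):
        raise ValueError("offsets must be positive")
    preset = get_prior(prior)
    years = np.arange(1, T + 1) if years is None else np.asarray(years)

    def q_builder(eta):
        b, phi, sigma2, r, _ = _unpack(eta)
        Q = _ar1_precision(T, phi) / sigma2
        half_logdet = 0.5 * (np.log1p(-phi ** 2) - T * np.log(sigma2))
        return Q, half_logdet

    def prior_logpdf(eta):
        return preset.logpdf(eta[0], eta[1], eta[2], eta[3])

    b0 = float(np.log((x.sum() + 0.5) / e.sum()))
    eta0 = np.array([b0, 0.0, 0.5, 0.0])
    eta_draws, z_draws, diag, failed = _fit_core(
        x, e, np.arange(T), T, q_builder, eta0, prior_logpdf, rng,
        n_walkers, n_steps, n_burn, n_draws)
    return PosteriorFit(kind="temporal", prior=preset.name, years=years,
                        eta_draws=eta_draws, z_draws=z_draws, sites=None,
                        offsets=e, counts=x, diagnostics=diag, failed=failed)


def _site_distances(sites):
    sites = np.asarray(sites, dtype=float)
    return np.hypot(sites[:, None, 0] - sites[None, :, 0],
                    sites[:, None, 1] - sites[None, :, 1])


def fit_spatiotemporal(counts, offsets, site_idx, year_idx, sites, n_years,
                       prior="relaxed", rng=None, years=None, nu=1.0,
                       n_walkers=12, n_steps=200, n_burn=100, n_draws=200
                       ) -> PosteriorFit:
    """Fit the separable space-time NB model at a fixed set of sites.

    The latent field ``z`` lives on the full ``n_years x n_sites`` lattice
    (year-major flattening); observations reference it through
    ``(site_idx, year_idx)``.  The spatial innovation covariance is an exact
    Matern (smoothness ``nu = 1``) on the site set; duplicate sites are
    jittered and flagged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(counts, dtype=float)
    e = np.asarray(offsets, dtype=float)
    sites = np.asarray(sites, dtype=float)
    S, T = len(sites), int(n_years)
    if S < 2 or T < 2:
        raise ValueError("need >= 2 sites and >= 2 years")
    preset = get_prior(prior)
    years = np.arange(1, T + 1) if years is None else np.asarray(years)
    obs_idx = np.asarray(year_idx, dtype=np.int64) * S + np.asarray(site_idx, dtype=np.int64)

    D = _site_distances(sites)
    off_diag = D[~np.eye(S, dtype=bool)]
    jitter_flag = bool(off_diag.size and off_diag.min() == 0.0)
    jitter = 1e-6 if jitter_flag else 1e-8

    def q_builder(eta):
        b, phi, sigma2, r, kappa = _unpack(eta)
        if kappa is None or kappa <= 0 or kappa > 1e3:
            return None
        Kc = matern_covariance(D, 1.0, kappa, nu) + jitter * np.eye(S)
        try:
            cK, lowK = linalg.cho_factor(Kc, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_Kc = 2.0 * float(np.sum(np.log(np.diag(cK))))
        K_inv = linalg.cho_solve((cK, lowK), np.eye(S), check_finite=False)
        Q = np.kron(_ar1_precision(T, phi), K_inv) / sigma2
        half_logdet = 0.5 * (S * np.log1p(-phi ** 2) - T * logdet_Kc
                             - T * S * np.log(sigma2))
        return Q, half_logdet

    def prior_logpdf(eta):
        return preset.logpdf(eta[0], eta[1], eta[2], eta[3], eta[4])

    b0 = float(np.log((x.sum() + 0.5) / e.sum()))
    med_d = float(np.median(off_diag)) if off_diag.size else 100.0
    eta0 = np.array([b0, 0.0, 0.5, 0.0, np.log(2.0 / max(med_d, 1e-6))])
    eta_draws, z_draws, diag, failed = _fit_core(
        x, e, obs_idx, T * S, q_builder, eta0, prior_logpdf, rng,
        n_walkers, n_steps, n_burn, n_draws)
    diag["duplicate_sites_jittered"] = jitter_flag
    return PosteriorFit(kind="spatiotemporal", prior=preset.name, years=years,
                        eta_draws=eta_draws, z_draws=z_draws, sites=sites,
                        offsets=e, counts=x, diagnostics=diag, failed=failed)


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------

def matern_krige(sites, points, kappa, nu=1.0, jitter=1e-8):
    """Simple-kriging weights and conditional variances on the correlation scale.

    Returns ``(W, schur_diag)`` with ``W`` of shape (n_points, n_sites) such
    that the conditional mean is ``W @ z`` and the conditional variance of a
    unit-variance field is ``schur_diag`` (multiply by the field's marginal
    variance).
    """
    sites = np.asarray(sites, dtype=float)
    points = np.asarray(points, dtype=float)
    S = len(sites)
    Kss = matern_covariance(_site_distances(sites), 1.0, kappa, nu) + jitter * np.eye(S)
    d_ps = np.hypot(points[:, None, 0] - sites[None, :, 0],
                    points[:, None, 1] - sites[None, :, 1])
    Kps = matern_covariance(d_ps, 1.0, kappa, nu)
    c, low = linalg.cho_factor(Kss, lower=True)
    W = linalg.cho_solve((c, low), Kps.T).T
    schur = 1.0 - np.einsum("ps,ps->p", W, Kps)
    return W, np.maximum(schur, 0.0)


def predict_density_field(fit: PosteriorFit, points, year, rng=None):
    """Posterior draws of the density ``a(s, t)`` at new points for one year.

    For the spatio-temporal model, conditioning on the fitted lattice reduces
    (by the separable Kronecker structure) to spatial kriging within the
    requested year; the conditional variance is the spatial Schur complement
    scaled by the stationary AR1 marginal ``sigma2 / (1 - phi^2)``.

    Returns ``(a_draws, extrapolation)`` where ``a_draws`` has shape
    ``(n_draws, n_points)`` and ``extrapolation`` flags points outside the
    bounding box of the fitted sites.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    points = np.asarray(points, dtype=float)
    years = list(fit.years)
    t = years.index(year) if year in years else int(year)
    if fit.kind == "temporal":
        a = np.exp(fit.eta_draws[:, 0] + fit.z_draws[:, t])
        return np.repeat(a[:, None], len(points), axis=1), np.zeros(len(points), bool)

    sites = fit.sites
    lo, hi = sites.min(axis=0), sites.max(axis=0)
    extrap = np.any((points < lo) | (points > hi), axis=1)
    T, S = len(fit.years), len(sites)
    Z = fit.z_draws.reshape(fit.n_draws, T, S)
    params = fit.param_draws
    n = fit.n_draws
    # group draws by hyperparameters to reuse kriging systems
    keys = fit.eta_draws[:, [1, 2, 4]].round(12)
    _, inv = np.unique(keys, axis=0, return_inverse=True)
    a_draws = np.empty((n, len(points)))
    done = {}
    for i in range(n):
        g = inv[i]
        if g not in done:
            done[g] = matern_krige(sites, points, params["kappa"][i])
        W, schur = done[g]
        marg = params["sigma2"][i] / (1.0 - params["phi"][i] ** 2)
        mean = W @ Z[i, t]
        z_new = mean + rng.standard_normal(len(points)) * np.sqrt(marg * schur)
        a_draws[i] = np.exp(params["b"][i] + z_new)
    return a_draws, extrap
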