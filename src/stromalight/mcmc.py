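"""MCMC drivers shared by the Bayesian stages of the pipeline.

Two engines with a common convergence contract (split R-hat and bulk
effective sample size, with doubling retries before an error is raised):

* :func:`run_sampler` -- affine-invariant ensemble sampler (vectorized
  log-posterior; walkers treated as chains for diagnostics), used for the
  low-dimensional noise and mono-exponential fits;
* :func:`hmc_sample` -- a compact Hamiltonian Monte Carlo implementation
  (independent chains, analytic gradients), used for the extended decay
  model whose posterior geometry defeats ensemble moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

import emcee

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

from .errors import InferenceError

__all__ = ["SamplerConfig", "HMCConfig", "PosteriorSamples", "run_sampler",
           "hmc_sample", "summarize"]


@dataclass
class SamplerConfig:
    """Ensemble-sampler settings and convergence gates.

    ``nwalkers`` plays the role of parallel chains; ``burn`` draws are
    discarded, ``draws`` retained per walker.
    """

    nwalkers: int = 32
    burn: int = 1000
    draws: int = 1000
    seed: int = 0
    rhat_max: float = 1.05
    ess_min: float = 400.0
    max_retries: int = 2  # on gate failure, rerun with doubled burn/draws

    def with_seed(self, seed: int) -> "SamplerConfig":
        cfg = SamplerConfig(**self.__dict__)
        cfg.seed = int(seed) % (2**31)
        return cfg


@dataclass
class PosteriorSamples:
    """Post-burn samples plus the diagnostics that gated them."""

    chain: np.ndarray          # (draws, nwalkers, ndim)
    names: list[str]
    rhat: np.ndarray           # (ndim,)
    ess: np.ndarray            # (ndim,)
    log_prob: np.ndarray = field(repr=False, default=None)

    @property
    def flat(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])

    def thin_flat(self, max_draws: int, seed: int = 0) -> np.ndarray:
        flat = self.flat
        if len(flat) <= max_draws:
            return flat
        idx = np.random.default_rng(seed).choice(len(flat), max_draws, replace=False)
        return flat[np.sort(idx)]

    def diagnostics(self) -> dict:
        return {
            "rhat_max": float(np.max(self.rhat)),
            "ess_min": float(np.min(self.ess)),
            "rhat": {n: float(r) for n, r in zip(self.names, self.rhat)},
            "ess": {n: float(e) for n, e in zip(self.names, self.ess)},
        }


def _diagnose(chain: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # chain: (draws, walkers, ndim) -> arviz wants (chain, draw, *shape)
    arr = np.moveaxis(chain, 1, 0)
    ds = az.convert_to_dataset({"theta": arr})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)["theta"].values
        ess = az.ess(ds)["theta"].values
    return np.atleast_1d(rhat), np.atleast_1d(ess)


def run_sampler(
    log_prob,
    p0: np.ndarray,
    config: SamplerConfig,
    names: list[str] | None = None,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Run the ensemble sampler from initial positions ``p0``.

    ``log_prob`` must accept an (nwalkers, ndim) array and return a length-
    nwalkers vector of log posterior densities (-inf allowed outside the
    support). Raises :class:`InferenceError` when the convergence gates
    (R-hat, ESS) fail or every starting point has zero posterior density.
    """
    p0 = np.asarray(p0, dtype=float)
    nwalkers, ndim = p0.shape
    if nwalkers != config.nwalkers:
        raise ValueError("p0 does not match config.nwalkers")
    names = names or [f"theta{i}" for i in range(ndim)]

    lp0 = np.asarray(log_prob(p0), dtype=float)
    if not np.any(np.isfinite(lp0)):
        raise InferenceError("no finite log-posterior at the initial positions")
    # replace bad starting walkers with jittered copies of good ones
    rng = np.random.default_rng(config.seed)
    bad = ~np.isfinite(lp0)
    for _ in range(20):
        if not bad.any():
            break
        good = np.flatnonzero(~bad)
        pick = rng.choice(good, size=bad.sum())
        p0[bad] = p0[pick] * (1 + 1e-3 * rng.standard_normal((bad.sum(), ndim)))
        lp0 = np.asarray(log_prob(p0), dtype=float)
        bad = ~np.isfinite(lp0)
    if bad.any():
        raise InferenceError("could not initialize all walkers in the support")

    moves = [
        (emcee.moves.DEMove(), 0.6),
        (emcee.moves.DESnookerMove(), 0.2),
        (emcee.moves.StretchMove(), 0.2),
    ]
    burn, draws = config.burn, config.draws
    result = None
    for attempt in range(config.max_retries + 1):
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_prob, vectorize=True, moves=moves)
        sampler._random = np.random.RandomState((config.seed + attempt) % (2**31))
        state = sampler.run_mcmc(p0, burn, skip_initial_state_check=True)
        sampler.reset()
        sampler.run_mcmc(state, draws, skip_initial_state_check=True)

        chain = sampler.get_chain()  # (draws, walkers, ndim)
        rhat, ess = _diagnose(chain)
        result = PosteriorSamples(
            chain=chain, names=names, rhat=rhat, ess=ess,
            log_prob=sampler.get_log_prob(),
        )
        converged = np.max(rhat) <= config.rhat_max and np.min(ess) >= config.ess_min
        if converged or not check_convergence:
            return result
        # restart from the last state with a longer run
        p0 = state.coords
        burn, draws = burn * 2, draws * 2

    raise InferenceError(
        f"sampler did not converge (max R-hat {np.max(result.rhat):.3f}, "
        f"min ESS {np.min(result.ess):.0f})",
        diagnostics=result.diagnostics(),
    )


def summarize(samples: np.ndarray, name: str = "") -> dict:
    """Posterior summary of a 1-D draw vector: mean, sd, and central intervals."""
    q = np.percentile(samples, [2.5, 25.0, 50.0, 75.0, 97.5])
    return {
        "mean": float(np.mean(samples)),
        "sd": float(np.std(samples, ddof=1)),
        "median": float(q[2]),
        "q2.5": float(q[0]),
        "q25": float(q[1]),
        "q75": float(q[3]),
        "q97.5": float(q[4]),
    }


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
#
# The extended decay model's posterior (log mean-free path + GP control
# values) is smooth, moderately high-dimensional and has a soft nonlinear
# ridge; affine-invariant ensemble moves mix an order of magnitude too
# slowly there. Gradients are cheap and analytic, so a compact HMC sampler
# with dual-averaging step-size adaptation and a diagonal mass matrix is
# the appropriate engine. Chains are genuinely independent, so the split
# R-hat / ESS gates carry their usual meaning.

@dataclass
class HMCConfig:
    """Settings for the gradient-based sampler."""

    n_chains: int = 4
    warmup: int = 500
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.85
    leapfrog_range: tuple = (20, 50)   # steps drawn uniformly per iteration
    init_step: float = 0.1
    rhat_max: float = 1.05
    ess_min: float = 400.0
    max_retries: int = 2  # on gate failure, rerun with doubled warmup/draws

    def with_seed(self, seed: int) -> "HMCConfig":
        cfg = HMCConfig(**self.__dict__)
        cfg.seed = int(seed) % (2**31)
        return cfg


def _leapfrog(logp_grad, x, p, eps, n_steps, inv_mass):
    lp, grad = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, -np.inf, grad
        p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _find_reasonable_eps(logp_grad, x, inv_mass, rng, eps0=1.0):
    """Double/halve the step size until a one-step acceptance crosses 0.5."""
    eps = eps0
    ndim = len(x)
    p0 = rng.standard_normal(ndim) / np.sqrt(inv_mass)
    # normalize to the typical kinetic energy so one extreme momentum draw
    # cannot drive the search to an absurdly small step size
    p0 *= np.sqrt(ndim / np.sum(inv_mass * p0 ** 2))
    lp, _ = logp_grad(x)
    h0 = lp - 0.5 * np.sum(inv_mass * p0 ** 2)

    def log_ratio(eps):
        _, p1, lp1, _ = _leapfrog(logp_grad, x, p0, eps, 1, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 ** 2)
        return h1 - h0 if np.isfinite(h1) else -np.inf

    if log_ratio(eps) > np.log(0.5):
        # acceptable: double until it stops being acceptable
        for _ in range(40):
            if log_ratio(eps * 2.0) <= np.log(0.5):
                break
            eps *= 2.0
    else:
        # unacceptable: halve until it becomes acceptable
        for _ in range(40):
            eps *= 0.5
            if log_ratio(eps) > np.log(0.5):
                break
    return float(min(eps, 10.0))


def _hmc_chain(logp_grad, x0, config: HMCConfig, seed: int,
               inv_mass0: np.ndarray | None = None):
    rng = np.random.default_rng(seed)
    ndim = len(x0)
    inv_mass = np.ones(ndim) if inv_mass0 is None else np.asarray(inv_mass0, float)
    x = np.asarray(x0, dtype=float)
    lp, _ = logp_grad(x)
    if not np.isfinite(lp):
        raise InferenceError("HMC chain started outside the support")

    gamma, t0, kappa = 0.05, 10.0, 0.75
    eps = _find_reasonable_eps(logp_grad, x, inv_mass, rng, config.init_step)
    mu, log_eps_bar, h_bar, t_da = np.log(10 * eps), 0.0, 0.0, 0

    warm_samples = []
    chain = np.empty((config.draws, ndim))
    n_iter = config.warmup + config.draws
    lo, hi = config.leapfrog_range
    # windowed mass-matrix updates, each followed by a fresh step-size run
    mass_update_at = sorted({config.warmup // 3, (2 * config.warmup) // 3})

    for it in range(n_iter):
        p0 = rng.standard_normal(ndim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0 ** 2)
        n_steps = int(rng.integers(lo, hi + 1))
        x_new, p_new, lp_new, _ = _leapfrog(logp_grad, x, p0, eps, n_steps, inv_mass)
        h_new = lp_new - 0.5 * np.sum(inv_mass * p_new ** 2)
        log_alpha = min(0.0, h_new - h0) if np.isfinite(h_new) else -np.inf
        accept_prob = float(np.exp(log_alpha)) if np.isfinite(log_alpha) else 0.0
        if rng.random() < accept_prob:
            x, lp = x_new, lp_new

        if it < config.warmup:
            t_da += 1
            h_bar = (1 - 1 / (t_da + t0)) * h_bar \
                + (config.target_accept - accept_prob) / (t_da + t0)
            log_eps = mu - np.sqrt(t_da) / gamma * h_bar
            w = t_da ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            warm_samples.append(x.copy())
            if (it + 1) in mass_update_at and len(warm_samples) > 30:
                recent = np.asarray(warm_samples[len(warm_samples) // 2:])
                var = np.var(recent, axis=0)
                if np.all(var > 0):
                    # regularized diagonal mass; the per-update change ratio
                    # is bounded so one sluggish window cannot collapse the
                    # mass (and thereby freeze the chain permanently)
                    new_inv = 0.9 * var + 0.1 * np.mean(var)
                    inv_mass = np.clip(new_inv, inv_mass / 25.0, inv_mass * 25.0)
                    eps = _find_reasonable_eps(logp_grad, x, inv_mass, rng, eps)
                    mu, log_eps_bar, h_bar, t_da = np.log(10 * eps), 0.0, 0.0, 0
            if it + 1 == config.warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            chain[it - config.warmup] = x
    return chain


def hmc_sample(
    logp_grad,
    x0: np.ndarray,
    config: HMCConfig,
    names: list[str] | None = None,
    jitter: float = 0.01,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Run independent HMC chains from jittered copies of ``x0``.

    ``logp_grad(x)`` must return ``(log_density, gradient)`` for a single
    parameter vector; ``x0`` is normally the posterior mode. The mass matrix
    is seeded with the diagonal Hessian of -log p at ``x0`` (finite
    differences of the gradient) and refined during warmup. Returns draws
    shaped (draws, chains, ndim); raises :class:`InferenceError` when the
    R-hat / ESS gates still fail after ``max_retries`` doubled reruns.
    """
    x0 = np.asarray(x0, dtype=float)
    ndim = len(x0)
    names = names or [f"theta{i}" for i in range(ndim)]
    rng = np.random.default_rng(config.seed)

    # diagonal-Hessian mass estimate at the mode
    h = 1e-5 * np.maximum(np.abs(x0), 1.0)
    hess = np.empty(ndim)
    for i in range(ndim):
        e = np.zeros(ndim)
        e[i] = h[i]
        _, gp = logp_grad(x0 + e)
        _, gm = logp_grad(x0 - e)
        hess[i] = -(gp[i] - gm[i]) / (2 * h[i])
    inv_mass0 = None
    if np.all(np.isfinite(hess)) and np.all(hess > 0):
        inv_mass0 = 1.0 / hess

    warmup, draws = config.warmup, config.draws
    result = None
    for attempt in range(config.max_retries + 1):
        cfg = HMCConfig(**{**config.__dict__, "warmup": warmup, "draws": draws})
        chains = []
        for c in range(config.n_chains):
            # shrink the jitter until the start lies inside the support
            # (the mode can sit close to a constraint boundary)
            start = x0
            for k in range(12):
                j = jitter * 0.5 ** k
                cand = x0 * (1 + j * rng.standard_normal(ndim)) \
                    + j * rng.standard_normal(ndim)
                if np.isfinite(logp_grad(cand)[0]):
                    start = cand
                    break
            chains.append(_hmc_chain(logp_grad, start, cfg,
                                     seed=int(rng.integers(2**31)),
                                     inv_mass0=inv_mass0))
        chain = np.stack(chains, axis=1)  # (draws, chains, ndim)
        rhat, ess = _diagnose(chain)
        result = PosteriorSamples(chain=chain, names=names, rhat=rhat, ess=ess)
        converged = np.max(rhat) <= config.rhat_max and np.min(ess) >= config.ess_min
        if converged or not check_convergence:
            return result
        warmup, draws = warmup * 2, draws * 2

    raise InferenceError(
        f"HMC did not converge (max R-hat {np.max(result.rhat):.3f}, "
        f"min ESS {np.min(result.ess):.0f})",
        diagnostics=result.diagnostics(),
    )
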