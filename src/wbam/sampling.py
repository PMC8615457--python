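"""Posterior sampling for the pre/post effect models.

The posteriors are low-dimensional (3-5 parameters) with analytically
marginalized patient-level effects, so an affine-invariant ensemble
sampler (emcee) is an efficient and dependency-light choice.  Each
"chain" is an independently seeded, independently initialised ensemble;
the Gelman-Rubin split-R^ diagnostic is computed across the flattened
per-ensemble draws, so disagreement between ensembles is detected the
same way as between classical single chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

from .dataset import pair_trials
from .models import ModelSpec, log_prior, marginal_loglik

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.10


class IdentifiabilityError(ValueError):
    """A model parameter has no data to inform it (e.g. no AF pairs)."""


class ConvergenceError(RuntimeError):
    """Reported R^ exceeds the convergence threshold."""


class InsufficientChainsError(ValueError):
    """R^ needs at least two chains."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``iterations`` counts ensemble steps per chain, of which the first
    ``warmup`` are discarded; each retained step contributes ``walkers``
    draws, so one chain yields ``(iterations - warmup) * walkers`` draws.
    """

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    walkers: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 2 or self.walkers < 4:
            raise ValueError("need >= 1 chain, >= 2 iterations, >= 4 walkers")
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("warmup must lie in [0, iterations)")


@dataclass
class ModelFit:
    """Posterior draws and diagnostics for one model.

    ``chain_draws`` maps parameter name -> (chains, draws_per_chain);
    ``pointwise_loglik`` holds the marginal (new-patient) log density of
    every paired observation under every retained draw.
    """

    spec: ModelSpec
    chain_draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    pointwise_loglik: np.ndarray = field(repr=False)
    paired: pd.DataFrame = field(repr=False)
    config: MCMCConfig = field(default_factory=MCMCConfig)

    @property
    def n_chains(self) -> int:
        return next(iter(self.chain_draws.values())).shape[0]

    def draws(self, name: str) -> np.ndarray:
        """All post-warmup draws of one parameter, flattened across chains."""
        return self.chain_draws[name].ravel()

    def draws_matrix(self) -> np.ndarray:
        """(total draws, n_params) matrix in ``spec.param_names`` order."""
        return np.column_stack([self.draws(name) for name in self.spec.param_names])

    @property
    def converged(self) -> bool:
        return all(r < RHAT_THRESHOLD for r in self.rhat.values())

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def compute_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor on split chains.

    Each chain is halved (dropping a trailing odd sample), the classic
    between/within variance ratio is formed over the 2m half-chains, and
    sqrt of the variance ratio is returned.  Zero total variance returns
    1.0 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a (n_chains, n_draws) array")
    m, n = chains.shape
    if m < 2:
        raise InsufficientChainsError("split-R^ needs at least 2 chains")
    if n < 4:
        raise ValueError("chains must have >= 4 draws")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    if np.ptp(split) == 0.0:
        return 1.0
    within = split.var(axis=1, ddof=1).mean()
    if within == 0.0:
        return np.inf
    between = half * split.mean(axis=1).var(ddof=1)
    var_hat = (half - 1) / half * within + between / half
    return float(np.sqrt(var_hat / within))


def _initial_walkers(
    spec: ModelSpec,
    paired: pd.DataFrame,
    bounds: dict[str, tuple[float, float]],
    n_walkers: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Start walkers near per-group least-squares multipliers (through origin)."""
    pre = paired.pre_value.to_numpy()
    post = paired.post_value.to_numpy()
    is_af = paired.is_af.to_numpy().astype(bool)
    beta_all = float(post @ pre / (pre @ pre))
    ct = ~is_af
    beta_ct0 = float(post[ct] @ pre[ct] / (pre[ct] @ pre[ct])) if ct.any() else beta_all
    if is_af.any():
        beta_af0 = float(post[is_af] @ pre[is_af] / (pre[is_af] @ pre[is_af])) - beta_ct0
    else:
        beta_af0 = 0.0
    resid = post - (beta_ct0 + is_af * beta_af0) * pre
    sigma0 = max(float(resid.std()), 1e-6)
    center = {
        "beta_ct": beta_ct0, "mu_ct": beta_ct0,
        "beta_af": beta_af0, "mu_af": beta_af0,
        "sigma": sigma0, "sigma_ct": 0.5 * sigma0, "sigma_af": 0.5 * sigma0,
    }
    # ball size ~ the posterior scale: sd(beta_hat) ~ sigma / sqrt(sum pre^2)
    effect_scale = max(sigma0 / np.sqrt(float(pre @ pre)), 1e-8)
    p0 = np.empty((n_walkers, len(spec.param_names)))
    for k, name in enumerate(spec.param_names):
        lo, hi = bounds[name]
        scale = 0.2 * sigma0 if name.startswith("sigma") else 2.0 * effect_scale
        vals = center[name] + scale * rng.standard_normal(n_walkers)
        eps = 1e-9 * (hi - lo)
        p0[:, k] = np.clip(vals, lo + eps, hi - eps)
    return p0


def fit_model(
    spec: ModelSpec | int,
    data,
    config: MCMCConfig | None = None,
    pairing_mode: str = "index",
) -> ModelFit:
    """Sample the posterior of one model by MCMC.

    ``data`` is a paired DataFrame (columns pre_value, post_value,
    is_af, ...) or a :class:`~wbam.dataset.RangeDataset`, which is paired
    first.  Priors are uniform within ``spec``'s (data-resolved) bounds.
    Non-convergence (any split-R^ >= 1.10) is logged and flagged on the
    returned fit, not raised.
    """
    if isinstance(spec, int):
        spec = ModelSpec(model_id=spec)
    if config is None:
        config = MCMCConfig()
    if not isinstance(data, pd.DataFrame):
        data = pair_trials(data, mode=pairing_mode)
    paired = data
    pre = paired.pre_value.to_numpy(dtype=float)
    post = paired.post_value.to_numpy(dtype=float)
    is_af = paired.is_af.to_numpy(dtype=float)
    if not is_af.any():
        raise IdentifiabilityError(
            "model includes a feedback effect but the dataset has no AF-group pairs"
        )
    if not (is_af == 0).any():
        logger.warning("dataset has no CT pairs; treadmill effect informed by AF arm only")
    bounds = spec.resolve_bounds(post)

    def log_posterior(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = log_prior(theta, spec, bounds)
        out = np.full(theta.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if ok.any():
            ll = marginal_loglik(spec, theta[ok], pre, post, is_af).sum(axis=-1)
            out[ok] = lp[ok] + ll
        return out

    ndim = len(spec.param_names)
    keep = config.iterations - config.warmup
    per_chain = np.empty((config.chains, keep * config.walkers, ndim))
    root = np.random.SeedSequence(config.seed)
    for c, child in enumerate(root.spawn(config.chains)):
        rng = np.random.Generator(np.random.PCG64(child))
        p0 = _initial_walkers(spec, paired, bounds, config.walkers, rng)
        sampler = emcee.EnsembleSampler(
            config.walkers, ndim, log_posterior, vectorize=True
        )
        sampler.random_state = np.random.RandomState(int(child.generate_state(1)[0])).get_state()
        sampler.run_mcmc(p0, config.iterations, progress=False)
        chain = sampler.get_chain(discard=config.warmup)  # (keep, walkers, ndim)
        per_chain[c] = chain.reshape(keep * config.walkers, ndim)

    chain_draws = {
        name: per_chain[:, :, k] for k, name in enumerate(spec.param_names)
    }
    rhat = {name: compute_rhat(chain_draws[name]) for name in spec.param_names}
    if any(r >= RHAT_THRESHOLD for r in rhat.values()):
        logger.warning("non-convergence: R^ = %s", {k: round(v, 3) for k, v in rhat.items()})
    flat = per_chain.reshape(-1, ndim)
    pointwise = marginal_loglik(spec, flat, pre, post, is_af)
    return ModelFit(
        spec=spec,
        chain_draws=chain_draws,
        rhat=rhat,
        pointwise_loglik=pointwise,
        paired=paired,
        config=config,
    )
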