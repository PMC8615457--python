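"""Pre/post treatment-effect models for the WBAM range.

All four models share the same observation law: a patient's post-
rehabilitation WBAM range is a multiple of the pre value plus Gaussian
trial noise,

    post_{i,j} ~ Normal( beta_eff * pre_{i,j}, sigma ),

with the effective multiplier assembling a treadmill-training component
(beta_CT, shared by both arms) and an additional auditory-feedback
component (beta_AF, AF arm only):

    model 1  beta_eff = beta_CT + g * beta_AF              (no individuality)
    model 2  beta_CT,j ~ Normal(mu_CT, sigma_CT)           (individual treadmill effect)
    model 3  beta_AF,j ~ Normal(mu_AF, sigma_AF)           (individual feedback effect)
    model 4  both patient-level effects drawn hierarchically

where g = 1 for AF-group pairs and 0 for CT.  Because the patient-level
effects enter linearly in a Gaussian likelihood, they can be integrated
out in closed form; the resulting *marginal* likelihood describes a new
patient drawn from the population and is the density used both for
fitting and for WAIC-based model comparison:

    model 2  post ~ N((mu_CT + g*beta_AF) pre, sqrt(sigma_CT^2 pre^2 + sigma^2))
    model 3  post ~ N((beta_CT + g*mu_AF) pre, sqrt(g sigma_AF^2 pre^2 + sigma^2))
    model 4  post ~ N((mu_CT + g*mu_AF) pre, sqrt((sigma_CT^2 + g sigma_AF^2) pre^2 + sigma^2))

Priors are non-informative uniforms: effect-type parameters on a wide
symmetric interval, scale-type parameters on [0, scale_cap) with the cap
set from the data's spread at fit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))

#: model_id -> (hierarchical treadmill effect, hierarchical feedback effect)
MODEL_HIERARCHY: dict[int, tuple[bool, bool]] = {
    1: (False, False),
    2: (True, False),
    3: (False, True),
    4: (True, True),
}

#: Human-readable individuality labels, mirroring the comparison table.
INDIVIDUALITY_LABELS = {1: "no", 2: "beta_CT,j", 3: "beta_AF,j", 4: "beta_CT,j, beta_AF,j"}

DEFAULT_EFFECT_BOUNDS = (-5.0, 5.0)


@dataclass
class ModelSpec:
    """One of the four pre/post effect models.

    ``prior_bounds`` maps parameter name -> (low, high) uniform prior
    bounds; entries missing at construction are filled at fit time
    (effect parameters get ``DEFAULT_EFFECT_BOUNDS``, scale parameters
    ``(0, 10 * sd(post))``).
    """

    model_id: int
    prior_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_HIERARCHY:
            raise ValueError("model_id must be 1, 2, 3 or 4")

    @property
    def hierarchical_ct(self) -> bool:
        return MODEL_HIERARCHY[self.model_id][0]

    @property
    def hierarchical_af(self) -> bool:
        return MODEL_HIERARCHY[self.model_id][1]

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["mu_ct" if self.hierarchical_ct else "beta_ct"]
        if self.hierarchical_ct:
            names.append("sigma_ct")
        names.append("mu_af" if self.hierarchical_af else "beta_af")
        if self.hierarchical_af:
            names.append("sigma_af")
        names.append("sigma")
        return tuple(names)

    @property
    def scale_params(self) -> tuple[str, ...]:
        return tuple(n for n in self.param_names if n.startswith("sigma"))

    @property
    def ct_effect_name(self) -> str:
        return "mu_ct" if self.hierarchical_ct else "beta_ct"

    @property
    def af_effect_name(self) -> str:
        return "mu_af" if self.hierarchical_af else "beta_af"

    def resolve_bounds(self, post_values: np.ndarray) -> dict[str, tuple[float, float]]:
        """Fill in unset prior bounds from the data scale."""
        sd = float(np.std(np.asarray(post_values, dtype=float)))
        scale_cap = 10.0 * sd if sd > 0 else 10.0
        bounds = {}
        for name in self.param_names:
            if name in self.prior_bounds:
                bounds[name] = self.prior_bounds[name]
            elif name in self.scale_params:
                bounds[name] = (0.0, scale_cap)
            else:
                bounds[name] = DEFAULT_EFFECT_BOUNDS
        return bounds


def _normal_logpdf(x, mean, sd):
    sd = np.asarray(sd, dtype=float)
    z = (np.asarray(x, dtype=float) - mean) / sd
    return -0.5 * (z**2 + _LOG_2PI) - np.log(sd)


def conditional_loglik(
    spec: ModelSpec,
    params: dict[str, float],
    pre: np.ndarray,
    post: np.ndarray,
    is_af: np.ndarray,
) -> np.ndarray:
    """Log density of ``post`` given *realised* (patient-level) effects.

    ``params`` supplies the effects as they apply to the pairs at hand:
    ``beta_ct`` (plus ``beta_af`` for AF pairs) regardless of hierarchy —
    for hierarchical models these are the drawn patient-level values.
    The feedback effect is gated by the AF indicator, so it never
    influences CT pairs.
    """
    sigma = float(params["sigma"])
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    beta_eff = float(params["beta_ct"]) + np.asarray(is_af, dtype=float) * float(
        params.get("beta_af", 0.0)
    )
    return _normal_logpdf(post, beta_eff * np.asarray(pre, dtype=float), sigma)


def marginal_loglik(
    spec: ModelSpec,
    params: np.ndarray | dict[str, float],
    pre: np.ndarray,
    post: np.ndarray,
    is_af: np.ndarray,
) -> np.ndarray:
    """New-patient log density with patient-level effects integrated out.

    ``params`` is either a dict of scalars keyed by ``spec.param_names``
    or an array whose last axis enumerates ``spec.param_names``; in the
    array case broadcasting applies, so a (draws, n_params) matrix against
    n observations yields a (draws, n) log-likelihood matrix.
    """
    if isinstance(params, dict):
        theta = np.array([params[name] for name in spec.param_names], dtype=float)
    else:
        theta = np.asarray(params, dtype=float)
    cols = {name: theta[..., k, None] for k, name in enumerate(spec.param_names)}
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    g = np.asarray(is_af, dtype=float)
    sigma = cols["sigma"]
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")

    mean_mult = cols[spec.ct_effect_name] + g * cols[spec.af_effect_name]
    var = np.broadcast_to(sigma**2, np.broadcast_shapes(sigma.shape, pre.shape)).copy()
    if spec.hierarchical_ct:
        var = var + cols["sigma_ct"] ** 2 * pre**2
    if spec.hierarchical_af:
        var = var + g * cols["sigma_af"] ** 2 * pre**2
    out = _normal_logpdf(post, mean_mult * pre, np.sqrt(var))
    if isinstance(params, dict):
        return np.squeeze(out, axis=0) if out.ndim > np.asarray(pre).ndim else out
    return out


def log_prior(
    theta: np.ndarray, spec: ModelSpec, bounds: dict[str, tuple[float, float]]
) -> np.ndarray:
    """Log of the product of uniform priors; -inf outside the box.

    Vectorised over leading axes of ``theta`` (last axis = parameters).
    """
    theta = np.asarray(theta, dtype=float)
    lo = np.array([bounds[name][0] for name in spec.param_names])
    hi = np.array([bounds[name][1] for name in spec.param_names])
    inside = np.all((theta >= lo) & (theta < hi), axis=-1)
    log_volume = float(np.sum(np.log(hi - lo)))
    return np.where(inside, -log_volume, -np.inf)
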