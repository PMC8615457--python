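"""Posterior effect summaries: intervals, percent reduction, bands, Cohen's d.

The treadmill effect multiplier beta_CT (or its population mean mu_CT)
describes both arms; the additional auditory-feedback multiplier beta_AF
(or mu_AF) applies to the AF arm only, so the AF arm's total effect is
beta_CT + beta_AF.  A negative beta_AF is a reduction of the WBAM range,
reported as -100 * beta_AF percent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import marginal_loglik  # noqa: F401  (re-exported for band users)
from .sampling import ModelFit


class NotConvergedError(RuntimeError):
    pass


def _summary(draws: np.ndarray) -> tuple[float, float, float]:
    draws = np.asarray(draws, dtype=float).ravel()
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), float(lo), float(hi)


def effect_summary(fit: ModelFit, force: bool = False) -> pd.DataFrame:
    """Mean and central 95% interval of each effect's posterior draws.

    Rows: the treadmill effect, the feedback effect, and the AF arm's
    combined effect computed drawwise as their sum (population means for
    hierarchical models).  Refuses a non-converged fit unless ``force``.
    """
    if not fit.converged and not force:
        raise NotConvergedError(
            f"fit flagged non-converged (max R^ = {fit.max_rhat:.3f}); pass force=True"
        )
    spec = fit.spec
    ct = fit.draws(spec.ct_effect_name)
    af = fit.draws(spec.af_effect_name)
    rows = []
    for label, draws in (
        (spec.ct_effect_name, ct),
        (spec.af_effect_name, af),
        ("combined", ct + af),
    ):
        mean, lo, hi = _summary(draws)
        rows.append((fit.spec.model_id, label, mean, lo, hi))
    return pd.DataFrame(rows, columns=["model", "effect", "mean", "lo95", "hi95"])


def percent_reduction(beta_af: np.ndarray | float) -> dict[str, float]:
    """Reduction of the WBAM range implied by the feedback effect, in percent.

    Drawwise -100 * beta_af; a scalar input gives a point value with a
    degenerate interval.
    """
    draws = -100.0 * np.atleast_1d(np.asarray(beta_af, dtype=float))
    if draws.size == 1:
        v = float(draws[0])
        return {"mean": v, "lo95": v, "hi95": v}
    mean, lo, hi = _summary(draws)
    # reduction flips the interval orientation: the most negative beta is the largest reduction
    return {"mean": mean, "lo95": lo, "hi95": hi}


def predictive_interval_curve(
    fit: ModelFit,
    pre_grid: np.ndarray,
    group: str = "AF",
    levels: tuple[float, ...] = (0.5, 0.95),
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Posterior-predictive mean line and central bands over a grid of pre values.

    For each posterior draw the marginal predictive of a new patient's
    post value is Normal(mean_multiplier * pre, sd(pre)); one predictive
    sample per draw is taken and pooled, and empirical central quantiles
    form the bands.  Lines pass through the origin: at pre = 0 the mean
    is 0 and the band half-width reflects trial noise only.
    """
    if group not in ("AF", "CT"):
        raise ValueError("group must be 'AF' or 'CT'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    spec = fit.spec
    g = 1.0 if group == "AF" else 0.0
    theta = fit.draws_matrix()
    cols = {name: theta[:, k] for k, name in enumerate(spec.param_names)}
    mult = cols[spec.ct_effect_name] + g * cols[spec.af_effect_name]
    var0 = cols["sigma"] ** 2
    slope_var = np.zeros_like(var0)
    if spec.hierarchical_ct:
        slope_var = slope_var + cols["sigma_ct"] ** 2
    if spec.hierarchical_af:
        slope_var = slope_var + g * cols["sigma_af"] ** 2
    pre_grid = np.atleast_1d(np.asarray(pre_grid, dtype=float))
    if np.any(pre_grid < 0):
        raise ValueError("pre values must be >= 0")
    # common random numbers across the grid keep the band curves smooth in pre
    z = rng.standard_normal(theta.shape[0])
    rows = []
    for pre in pre_grid:
        sd = np.sqrt(slope_var * pre**2 + var0)
        samples = mult * pre + sd * z
        row = {"group": group, "pre": float(pre), "mean": float((mult * pre).mean())}
        for level in levels:
            tail = 100.0 * (1.0 - level) / 2.0
            lo, hi = np.percentile(samples, [tail, 100.0 - tail])
            pct = int(round(level * 100))
            row[f"lo{pct}"] = float(lo)
            row[f"hi{pct}"] = float(hi)
        rows.append(row)
    return pd.DataFrame(rows)


def cohen_d(
    ct_effect_draws: np.ndarray, af_effect_draws: np.ndarray
) -> dict[str, float]:
    """Posterior distribution of the standardized between-arm effect size.

    The CT arm's effect draws (beta_CT) and the AF arm's combined effect
    draws (beta_CT + beta_AF) are compared drawwise:

        d_s = |ct_s - af_s| / sqrt((sd_ct^2 + sd_af^2) / 2)

    with sd_* the posterior standard deviation of each arm's effect.
    Returns the mean and central 95% interval of the d draws.
    """
    ct = np.asarray(ct_effect_draws, dtype=float).ravel()
    af = np.asarray(af_effect_draws, dtype=float).ravel()
    if ct.size == 0 or af.size == 0:
        raise ValueError("empty draw sets")
    pooled = np.sqrt((ct.std(ddof=1) ** 2 + af.std(ddof=1) ** 2) / 2.0)
    if pooled == 0:
        raise ZeroDivisionError("zero pooled scale: Cohen's d undefined")
    n = min(ct.size, af.size)
    d_draws = np.abs(ct[:n] - af[:n]) / pooled
    mean, lo, hi = _summary(d_draws)
    return {"mean": mean, "lo95": lo, "hi95": hi, "pooled_scale": float(pooled)}


def normal_band_halfwidth(sigma: float, level: float = 0.95) -> float:
    """Half-width of a central normal interval (e.g. 1.96 sigma at 95%)."""
    return float(stats.norm.ppf(0.5 + level / 2.0) * sigma)
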