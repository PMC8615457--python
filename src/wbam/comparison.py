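"""WAIC model comparison.

WAIC estimates a model's expected out-of-sample predictive accuracy from
posterior draws: lppd sums, over observations, the log of the posterior-
mean likelihood; p_waic penalises with the summed posterior variance of
the pointwise log likelihood.  We report the deviance-scaled value

    WAIC = -2 (lppd - p_waic)

so that *lower is better*.  For hierarchical models the pointwise log
likelihood is the marginalized (new-patient) density, so the comparison
targets prediction for patients outside the study.  Only differences
(dWAIC) and ranks are comparable across software, not absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .models import INDIVIDUALITY_LABELS


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float


def compute_waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from a (draws, observations) log-likelihood matrix.

    lppd via a numerically stable log-sum-exp; p_waic as the sample
    variance (ddof=1) of each observation's log likelihood over draws.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be (draws, observations)")
    n_draws = ll.shape[0]
    if n_draws < 2:
        raise ValueError("p_waic needs at least 2 draws")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood entries")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    waic = -2.0 * (lppd - p_waic)
    return WaicResult(lppd=lppd, p_waic=p_waic, waic=waic)


def rank_models(waics: dict[int, float]) -> pd.DataFrame:
    """Rank models by ascending WAIC.

    Returns a DataFrame (model, individuality, rank, waic, d_waic) with
    d_waic the difference from the best model (0 for rank 1); ties break
    by ascending model id.
    """
    if not waics:
        raise ValueError("need at least one model")
    frame = pd.DataFrame(
        {
            "model": list(waics.keys()),
            "individuality": [INDIVIDUALITY_LABELS.get(m, "?") for m in waics],
            "waic": list(waics.values()),
        }
    )
    frame = frame.sort_values(["waic", "model"], kind="mergesort").reset_index(drop=True)
    frame.insert(2, "rank", np.arange(1, len(frame) + 1))
    frame["d_waic"] = frame.waic - frame.waic.min()
    return frame
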