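"""Approximate leave-one-out model comparison (PSIS-LOO).

The unit of cross-validation is the single presented item — the same unit
as the fitted Bernoulli likelihood.  Pointwise log-likelihood matrices are
computed from posterior draws and fed to ArviZ's Pareto-smoothed
importance-sampling LOO; model differences are reported as delta-LOOIC with
the paired pointwise standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr

from .fit import PosteriorDraws
from .hierarchical import HierarchicalModel

__all__ = ["LooResult", "pointwise_loglik", "loo", "loo_compare"]

_PARETO_K_WARN = 0.7


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO summary for one fitted model."""

    model_id: str
    elpd: float
    se: float
    pointwise: np.ndarray
    bad_k_share: float
    n_draws: int

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd

    @property
    def n_items(self) -> int:
        return self.pointwise.size


def pointwise_loglik(draws: PosteriorDraws, items: pd.DataFrame) -> np.ndarray:
    """(items x draws) pointwise log-likelihood matrix.

    The item table must be the one the model was fitted to (checked via the
    data fingerprint).
    """
    model = HierarchicalModel(items, draws.spec, centered=draws.centered)
    if model.fingerprint != draws.data_fingerprint:
        raise ValueError(
            "item table does not match the fitted data "
            f"(fingerprint {model.fingerprint} != {draws.data_fingerprint})")
    return model.pointwise_loglik(draws.flat_theta()).T


def loo(draws: PosteriorDraws, items: pd.DataFrame, model_id: str = "model",
        *, force: bool = False) -> LooResult:
    """Pareto-smoothed importance-sampling LOO for one fit."""
    if not draws.converged and not force:
        raise RuntimeError(
            f"fit {model_id!r} did not meet convergence criteria; "
            "pass force=True to override")
    ll = pointwise_loglik(draws, items)  # items x draws
    nc, nd = draws.n_chains, draws.n_draws
    arr = ll.T.reshape(nc, nd, -1)
    idata = az.from_dict(
        posterior={"_dummy": np.zeros((nc, nd))},
        log_likelihood={"obs": arr},
    )
    res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k)
    return LooResult(
        model_id=model_id,
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i),
        bad_k_share=float(np.mean(k > _PARETO_K_WARN)),
        n_draws=nc * nd,
    )


def loo_compare(results: list[LooResult]) -> pd.DataFrame:
    """Rank models by elpd with pairwise differences against the best.

    Returns one row per model with ``elpd``, ``looic``, ``delta_looic``
    (model minus best; 0 for the best model) and the paired standard error
    of that difference.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    n_items = {r.n_items for r in results}
    if len(n_items) != 1:
        raise ValueError(f"models were fitted to different item counts: {n_items}")
    ranked = sorted(results, key=lambda r: -r.elpd)
    best = ranked[0]
    rows = []
    for r in ranked:
        diff = best.pointwise - r.pointwise
        n = diff.size
        se_diff = float(np.sqrt(n * np.var(diff, ddof=1))) if r is not best else 0.0
        rows.append({
            "model_id": r.model_id,
            "rank": len(rows),
            "elpd": r.elpd,
            "se": r.se,
            "looic": r.looic,
            "delta_looic": r.looic - best.looic,
            "delta_se": 2.0 * se_diff,
            "bad_k_share": r.bad_k_share,
        })
    return pd.DataFrame(rows)
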