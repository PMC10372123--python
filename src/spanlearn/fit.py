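"""Parameter estimation: static per-participant ML fits (exclusion filter)
and the hierarchical Bayesian learning model (NUTS or Laplace)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize

from . import core_model
from .hierarchical import HierarchicalModel, ModelSpec
from .sampler import (
    NutsStats,
    find_map,
    laplace_covariance,
    laplace_draws,
    nuts_chain,
)

__all__ = [
    "ModelSpec",
    "FitResultStatic",
    "PosteriorDraws",
    "fit_static",
    "fit_static_table",
    "apply_exclusion",
    "fit_learning_model",
    "diagnostics",
    "RHAT_LIMIT",
    "TAIL_ESS_LIMIT",
    "CAPACITY_CUTOFF",
]

#: Convergence limits used for the converged flag.
RHAT_LIMIT = 1.02
TAIL_ESS_LIMIT = 500.0

#: Minimum item capacity (threshold / 2) a participant must reach.
CAPACITY_CUTOFF = 1.0

# Static-fit optimization box on (log threshold, log shape).
_LOG_TH_BOUNDS = (np.log(0.05), np.log(50.0))
_LOG_SH_BOUNDS = (np.log(0.5), np.log(20.0))
_N_STARTS = 5


@dataclass(frozen=True)
class FitResultStatic:
    """One participant's static Weibull ML fit and exclusion status."""

    participant_id: str
    threshold50: float
    shape: float
    capacity: float
    loglik: float
    converged: bool
    excluded: bool


def _static_negloglik(x: np.ndarray, set_size: np.ndarray, correct: np.ndarray) -> float:
    th, sh = np.exp(x)
    return -core_model.loglik(set_size, correct, th, sh)


def fit_static(items: pd.DataFrame, seed: int = 0) -> FitResultStatic:
    """Maximum-likelihood static Weibull fit for a single participant.

    The threshold is time-invariant; the fit pools all the participant's
    trials.  Multi-start bounded optimization makes the exclusion decision
    deterministic even for chance-level responders (whose likelihood is
    maximized at the lower threshold bound).
    """
    pid = str(items["participant_id"].iloc[0])
    if items["participant_id"].nunique() != 1:
        raise ValueError("fit_static expects a single participant's items")
    ss = items["set_size"].to_numpy(dtype=float)
    y = items["correct"].to_numpy(dtype=float)
    if np.any(ss < 1):
        raise ValueError("set sizes must be >= 1")

    rng = np.random.default_rng(seed)
    bounds = [_LOG_TH_BOUNDS, _LOG_SH_BOUNDS]
    starts = [np.array([np.log(3.0), np.log(3.0)])]
    for _ in range(_N_STARTS - 1):
        starts.append(np.array([
            rng.uniform(*_LOG_TH_BOUNDS),
            rng.uniform(*_LOG_SH_BOUNDS),
        ]))
    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(_static_negloglik, x0, args=(ss, y),
                                method="L-BFGS-B", bounds=bounds)
        any_ok |= bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    th, sh = np.exp(best.x)
    cap = core_model.capacity(float(th))
    excluded = (not any_ok) or cap < CAPACITY_CUTOFF
    return FitResultStatic(
        participant_id=pid,
        threshold50=float(th),
        shape=float(sh),
        capacity=float(cap),
        loglik=-float(best.fun),
        converged=any_ok,
        excluded=excluded,
    )


def fit_static_table(items: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Static fits for every participant in an item table."""
    rows = []
    for pid, grp in items.groupby("participant_id", sort=True):
        r = fit_static(grp, seed=seed)
        cond = str(grp["condition"].iloc[0])
        rows.append({
            "participant_id": r.participant_id,
            "condition": cond,
            "threshold50": r.threshold50,
            "shape": r.shape,
            "capacity": r.capacity,
            "loglik": r.loglik,
            "converged": r.converged,
            "excluded": r.excluded,
        })
    return pd.DataFrame(rows)


def apply_exclusion(static_table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Retain participants whose capacity is at least one item.

    Returns the retained rows plus a per-condition exclusion report.
    """
    if static_table["participant_id"].duplicated().any():
        raise ValueError("static table must have one row per participant")
    excluded = static_table["excluded"].to_numpy(dtype=bool)
    retained = static_table.loc[~excluded].reset_index(drop=True)
    report = {
        "n_total": int(len(static_table)),
        "n_excluded": int(excluded.sum()),
        "n_retained": int(len(retained)),
        "excluded_by_condition": static_table.loc[excluded]
        .groupby("condition").size().to_dict(),
        "excluded_participants": static_table.loc[excluded, "participant_id"].tolist(),
    }
    return retained, report


@dataclass
class PosteriorDraws:
    """Labelled posterior draws plus convergence diagnostics.

    ``theta`` has shape (chains, draws, dim); ``param_names`` labels the
    last axis.  Draws for an individual parameter are available through
    :meth:`stacked` (flattened across chains) or :meth:`per_chain`.
    """

    theta: np.ndarray
    param_names: list[str]
    spec: ModelSpec
    data_fingerprint: str
    method: str
    seed: int
    rhat: dict[str, float] = field(default_factory=dict)
    ess_tail: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    sampler_stats: dict = field(default_factory=dict)
    #: non-centering exponent per random-effect key (1 = non-centered)
    centered: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def _index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r}; available: {self.param_names}") from None

    def stacked(self, name: str) -> np.ndarray:
        return self.theta[:, :, self._index(name)].reshape(-1)

    def per_chain(self, name: str) -> np.ndarray:
        return self.theta[:, :, self._index(name)]

    def flat_theta(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) table."""
        nc, nd, dim = self.theta.shape
        chain = np.repeat(np.arange(nc), nd * dim)
        draw = np.tile(np.repeat(np.arange(nd), dim), nc)
        par = np.tile(np.array(self.param_names, dtype=object), nc * nd)
        return pd.DataFrame({
            "chain": chain,
            "draw": draw,
            "parameter": par,
            "value": self.theta.reshape(-1),
        })

    def save(self, draws_csv: str | Path, sidecar_json: str | Path) -> None:
        self.to_frame().to_csv(draws_csv, index=False)
        meta = {
            "spec": self.spec.to_dict(),
            "data_fingerprint": self.data_fingerprint,
            "method": self.method,
            "seed": self.seed,
            "rhat": self.rhat,
            "ess_tail": self.ess_tail,
            "converged": self.converged,
            "sampler_stats": self.sampler_stats,
            "param_names": self.param_names,
            "centered": self.centered,
        }
        Path(sidecar_json).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, draws_csv: str | Path, sidecar_json: str | Path) -> "PosteriorDraws":
        meta = json.loads(Path(sidecar_json).read_text())
        frame = pd.read_csv(draws_csv)
        names = meta["param_names"]
        nc = int(frame["chain"].max()) + 1
        nd = int(frame["draw"].max()) + 1
        theta = np.empty((nc, nd, len(names)))
        pos = {n: i for i, n in enumerate(names)}
        theta[frame["chain"].to_numpy(),
              frame["draw"].to_numpy(),
              frame["parameter"].map(pos).to_numpy()] = frame["value"].to_numpy()
        return cls(
            theta=theta,
            param_names=names,
            spec=ModelSpec.from_dict(meta["spec"]),
            data_fingerprint=meta["data_fingerprint"],
            method=meta["method"],
            seed=meta["seed"],
            rhat=meta["rhat"],
            ess_tail=meta["ess_tail"],
            converged=meta["converged"],
            sampler_stats=meta.get("sampler_stats", {}),
            centered=dict(meta.get("centered", {})),
        )


def diagnostics(theta: np.ndarray, param_names: list[str]) -> tuple[dict, dict, bool]:
    """Split r-hat and tail effective sample size for every parameter.

    ``theta`` is (chains, draws, dim) with at least two chains.
    """
    if theta.shape[0] < 2:
        raise ValueError("r-hat requires at least 2 chains")
    data = {name: theta[:, :, i] for i, name in enumerate(param_names)}
    idata = az.from_dict(posterior=data)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata, method="tail")
    rhat = {n: float(rhat_ds[n].values) for n in param_names}
    ess = {n: float(ess_ds[n].values) for n in param_names}
    finite_rhat = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(
        finite_rhat
        and max(finite_rhat) < RHAT_LIMIT
        and min(ess.values()) > TAIL_ESS_LIMIT
    )
    return rhat, ess, converged


def fit_learning_model(items: pd.DataFrame, spec: ModelSpec, *,
                       method: str = "nuts",
                       chains: int = 4,
                       warmup: int = 1000,
                       draws: int = 1000,
                       seed: int = 0,
                       target_accept: float = 0.8,
                       max_treedepth: int = 10,
                       centered: bool | tuple[str, ...] | dict[str, float] = False,
                       ) -> PosteriorDraws:
    """Fit the hierarchical time-evolving model.

    ``method="nuts"`` runs full MCMC (production); ``method="laplace"``
    draws from a Gaussian approximation at the posterior mode (fast mode for
    calibration studies and smoke tests — its draws are split into
    pseudo-chains so the diagnostic plumbing still applies).
    """
    model = HierarchicalModel(items, spec, centered=centered)
    rng = np.random.default_rng(seed)
    dim = model.layout.dim

    if method == "nuts":
        # chains start from jittered copies of the posterior mode: cheap to
        # find with analytic gradients and it keeps early trajectories short
        xmap, _ = find_map(model.logp_and_grad, model.initial_point(),
                           n_restarts=2, rng=rng)
        # dense metric from the Laplace covariance at the mode: captures the
        # fixed-effect / random-intercept correlations that a diagonal mass
        # matrix cannot, keeping NUTS trajectories short
        cov = laplace_covariance(model.logp_and_grad, xmap)
        chain_draws = []
        stats_list: list[NutsStats] = []
        for c in range(chains):
            crng = np.random.default_rng(np.random.SeedSequence([seed, c]))
            theta0 = xmap + 0.2 * crng.standard_normal(dim)
            lp0 = model.logp(theta0)
            if not np.isfinite(lp0):
                theta0 = xmap
            dr, st = nuts_chain(model.logp_and_grad, theta0, warmup, draws, crng,
                                target_accept=target_accept,
                                max_treedepth=max_treedepth,
                                metric_cov=cov)
            chain_draws.append(dr)
            stats_list.append(st)
        theta = np.stack(chain_draws)
        sampler_stats = {
            "n_divergent": int(sum(s.n_divergent for s in stats_list)),
            "step_size": [s.step_size for s in stats_list],
            "mean_accept": [s.mean_accept for s in stats_list],
            "mean_treedepth": [s.mean_treedepth for s in stats_list],
        }
    elif method == "laplace":
        total = chains * draws
        theta0 = model.initial_point()
        flat, xmap = laplace_draws(model.logp_and_grad, theta0, total, rng)
        theta = flat.reshape(chains, draws, dim)
        sampler_stats = {"map_logp": float(model.logp(xmap))}
    else:
        raise ValueError(f"unknown method {method!r}")

    rhat, ess, converged = diagnostics(theta, model.layout.names)
    if method == "laplace":
        # draws are iid from the Gaussian approximation; MCMC mixing
        # criteria do not apply
        converged = True
    return PosteriorDraws(
        theta=theta,
        param_names=list(model.layout.names),
        spec=spec,
        data_fingerprint=model.fingerprint,
        method=method,
        seed=seed,
        rhat=rhat,
        ess_tail=ess,
        converged=converged,
        sampler_stats=sampler_stats,
        centered=dict(model.centering),
    )
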