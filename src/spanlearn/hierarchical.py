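"""Hierarchical time-evolving psychometric model: density and gradient.

The model places the three exponential-trajectory parameters (log start
threshold, log half-time, log asymptotic threshold) and the log Weibull
shape on additive linear predictors:

    log param = reference fixed effect
              + condition offset                  (zero-centered prior)
              + participant intercept             (non-centered, normal)
              + per-block monotone offset         (within-block models only)

The per-block offset for a parameter is ``total_delta * w(block)`` with
weights (1, w2, w3, 0) for blocks 1..4 and 1 >= w2 >= w3 >= 0, so block 4
is the reference and the parameter moves monotonically across blocks.

Everything here works on a flat unconstrained parameter vector; the class
exposes the joint log density with its analytic gradient (consumed by the
NUTS and Laplace fitters) and per-item pointwise log-likelihoods (consumed
by LOO model comparison).  Because all items of a trial share one
psychometric probability, the likelihood is evaluated per trial with
binomial-count aggregation — numerically identical to the disaggregated
per-item Bernoulli sum.
"""

from __future__ import annotations

import hashlib

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import GUESS_RATE, DECAY_BASE, PROB_CLAMP

__all__ = ["ModelSpec", "HierarchicalModel", "PARAM_KEYS", "CROSS_BLOCK_SETS"]

#: Trajectory parameter keys, in canonical order.
PARAM_KEYS = ("start", "rate", "asym")

CROSS_BLOCK_SETS = {
    "none": (),
    "full": ("start", "rate", "asym"),
    "start_only": ("start",),
    "rate_only": ("rate",),
    "asym_only": ("asym",),
}

_LN2 = np.log(2.0)
_LNB = np.log(DECAY_BASE)
_U_MAX = 1e10
_THETA_BOUND = 50.0  # |unconstrained param| beyond this => density treated as 0

try:  # pragma: no cover - exercised implicitly everywhere
    from ._kernels import fused_logp_grad as _fast_kernel
except Exception:  # numba unavailable: pure-numpy path below
    _fast_kernel = None


@dataclass(frozen=True)
class ModelSpec:
    """Which effects the hierarchical learning model carries.

    ``timescale`` selects the trial index driving the exponential: the
    overall index 1..120 ("E1"-style) or the within-block index 1..30
    ("E2"-style).  ``cross_block`` adds monotone per-block offsets and is
    only valid on the within-block timescale.
    """

    timescale: str = "overall_1_120"
    cross_block: str = "none"
    reference_condition: str = "constant"
    condition_effects: tuple[str, ...] = ("start", "rate", "asym", "shape")
    random_effects: tuple[str, ...] = ("start", "rate", "asym")

    def __post_init__(self) -> None:
        if self.timescale not in ("overall_1_120", "within_block_1_30"):
            raise ValueError(f"unknown timescale {self.timescale!r}")
        if self.cross_block not in CROSS_BLOCK_SETS:
            raise ValueError(f"unknown cross_block {self.cross_block!r}")
        if self.cross_block != "none" and self.timescale != "within_block_1_30":
            raise ValueError("cross-block flexibility requires the within-block timescale")
        for k in self.condition_effects:
            if k not in PARAM_KEYS + ("shape",):
                raise ValueError(f"unknown condition effect {k!r}")
        for k in self.random_effects:
            if k not in PARAM_KEYS:
                raise ValueError(f"unknown random effect {k!r}")

    @property
    def flexible_block_params(self) -> tuple[str, ...]:
        return CROSS_BLOCK_SETS[self.cross_block]

    def to_dict(self) -> dict:
        return {
            "timescale": self.timescale,
            "cross_block": self.cross_block,
            "reference_condition": self.reference_condition,
            "condition_effects": list(self.condition_effects),
            "random_effects": list(self.random_effects),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            timescale=d["timescale"],
            cross_block=d.get("cross_block", "none"),
            reference_condition=d["reference_condition"],
            condition_effects=tuple(d.get("condition_effects", PARAM_KEYS + ("shape",))),
            random_effects=tuple(d.get("random_effects", PARAM_KEYS)),
        )


# Prior hyperparameters (log scales).  Weakly informative on plausible
# set-size and trial scales; condition offsets are zero-centered.
_PRIOR_LOC = {"b_start": np.log(3.0), "b_rate": np.log(10.0),
              "b_asym": np.log(3.0), "b_shape": np.log(3.0)}
_PRIOR_SCALE = {"b_start": 1.0, "b_rate": 1.0, "b_asym": 1.0, "b_shape": 0.5}
_OFFSET_SCALE = {"start": 1.0, "rate": 1.0, "asym": 1.0, "shape": 0.5}
_SD_PRIOR_SCALE = 0.5
_BLK_SCALE = 1.0


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _numpy_fused(b4, d_all, sd3, z3, blk3, wvec3, ci, pi, bi,
                 t, log_s, k, n, nC, nP, want_grad):
    """Vectorized fallback mirroring :func:`spanlearn._kernels.fused_logp_grad`."""
    with np.errstate(all="ignore"):
        res = []
        for j in range(4):
            v = b4[j] + d_all[j, ci]
            if j < 3:
                v = v + sd3[j] * z3[j, pi] + blk3[j, ci] * wvec3[j, bi]
            res.append(np.clip(v, -60.0, 60.0))
        ls, lr, la, lb = res
        S, H, A, beta = np.exp(ls), np.exp(lr), np.exp(la), np.exp(lb)
        g = np.exp2(-(t - 1.0) / H)
        th = A + (S - A) * g
        lth = np.log(th)
        u = np.minimum(np.exp(np.minimum(beta * (log_s - lth), 23.0)), _U_MAX)
        q = np.exp(u * _LNB)
        p = np.clip(GUESS_RATE + (1.0 - GUESS_RATE) * q, PROB_CLAMP, 1.0 - PROB_CLAMP)
        total = float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
        gb4 = np.zeros(4)
        gd = np.zeros((4, nC))
        gz_raw = np.zeros((3, nP))
        gsd_raw = np.zeros(3)
        gblk = np.zeros((3, nC))
        gw2 = np.zeros(3)
        gw3 = np.zeros(3)
        if not want_grad:
            return total, p, gb4, gd, gz_raw, gsd_raw, gblk, gw2, gw3
        dLdp = k / p - (n - k) / (1.0 - p)
        common = dLdp * (1.0 - GUESS_RATE) * q * _LNB
        dLdth = common * (-beta * u / th)
        dL = [
            dLdth * g * S,
            dLdth * (S - A) * g * _LN2 * (t - 1.0) / H,
            dLdth * A * (1.0 - g),
            common * u * (log_s - lth) * beta,
        ]
        for j in range(4):
            dk = np.nan_to_num(dL[j], nan=0.0, posinf=0.0, neginf=0.0)
            gb4[j] = dk.sum()
            gd[j] = np.bincount(ci, weights=dk, minlength=nC)
            if j < 3:
                gz_raw[j] = np.bincount(pi, weights=dk, minlength=nP)
                gsd_raw[j] = float(np.sum(z3[j, pi] * dk))
                gblk[j] = np.bincount(ci, weights=dk * wvec3[j, bi], minlength=nC)
                dk_blk = dk * blk3[j, ci]
                gw2[j] = float(np.sum(dk_blk[bi == 1]))
                gw3[j] = float(np.sum(dk_blk[bi == 2]))
    return total, p, gb4, gd, gz_raw, gsd_raw, gblk, gw2, gw3


class _Layout:
    """Flat-vector layout: ordered names with slices per parameter group."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self.slices: dict[str, slice] = {}

    def add(self, group: str, names: list[str]) -> None:
        start = len(self.names)
        self.names.extend(names)
        self.slices[group] = slice(start, len(self.names))

    @property
    def dim(self) -> int:
        return len(self.names)

    def get(self, theta: np.ndarray, group: str) -> np.ndarray:
        return theta[..., self.slices[group]]


def data_fingerprint(items: pd.DataFrame) -> str:
    """Stable hash of the analysis-relevant columns of an item table."""
    cols = ["participant_id", "condition", "block", "trial_in_block",
            "set_size", "item_position", "correct"]
    sub = items[cols].sort_values(cols, kind="mergesort").reset_index(drop=True)
    payload = sub.to_csv(index=False).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]


class HierarchicalModel:
    """Joint posterior density of the learning model on one item table.

    ``centered`` selects the random-effect parameterization per trajectory
    parameter on the non-centering exponent scale ``a``: the deviation is
    ``sd**a * z`` with prior ``z ~ N(0, sd**(2*(1-a)))``, so ``a = 1`` is
    the standard non-centered form (robust when participant effects are
    weakly identified), ``a = 0`` the centered form (mixes better when the
    data pin the deviations), and intermediate values interpolate.  Pass
    ``True``/``False`` for fully centered/non-centered, an iterable of keys
    to center (e.g. ``("start", "asym")``), or a mapping from key to ``a``.
    """

    def __init__(self, items: pd.DataFrame, spec: ModelSpec,
                 centered: bool | tuple[str, ...] | dict[str, float] = False) -> None:
        self.spec = spec
        if centered is True:
            self.centering = {k: 0.0 for k in spec.random_effects}
        elif centered is False:
            self.centering = {k: 1.0 for k in spec.random_effects}
        elif isinstance(centered, dict):
            bad = set(centered) - set(spec.random_effects)
            if bad:
                raise ValueError(f"centered keys {sorted(bad)} are not random effects")
            self.centering = {k: float(centered.get(k, 1.0))
                              for k in spec.random_effects}
        else:
            keys = frozenset(centered)
            if not keys <= set(spec.random_effects):
                raise ValueError(
                    f"centered keys {sorted(keys)} must be a subset of "
                    f"random effects {spec.random_effects}")
            self.centering = {k: (0.0 if k in keys else 1.0)
                              for k in spec.random_effects}
        for k, a in self.centering.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"non-centering exponent for {k!r} must be in [0, 1]")
        required = {"participant_id", "condition", "block", "trial_in_block",
                    "trial_overall", "set_size", "correct"}
        missing = required - set(items.columns)
        if missing:
            raise ValueError(f"item table lacks columns: {sorted(missing)}")

        conds = sorted(items["condition"].unique())
        if spec.reference_condition not in conds:
            raise ValueError(
                f"reference condition {spec.reference_condition!r} absent from data "
                f"(present: {conds})")
        # Reference condition first; offsets exist for the remainder.
        self.conditions = [spec.reference_condition] + [
            c for c in conds if c != spec.reference_condition]
        self.participants = sorted(items["participant_id"].unique())
        self.fingerprint = data_fingerprint(items)

        if np.any(items["set_size"].to_numpy() < 1):
            raise ValueError("every item's set size must be >= 1")
        self.n_items = len(items)

        cond_pos = {c: i for i, c in enumerate(self.conditions)}
        part_pos = {p: i for i, p in enumerate(self.participants)}

        # Group items into trials: one psychometric evaluation per trial.
        key = (items["participant_id"].map(part_pos).to_numpy(dtype=np.int64)
               * 1000 + items["trial_overall"].to_numpy(dtype=np.int64))
        uniq, trial_of_item = np.unique(key, return_inverse=True)
        ntr = uniq.size
        first = np.zeros(ntr, dtype=np.intp)
        seen = np.full(ntr, -1, dtype=np.intp)
        for i, tr in enumerate(trial_of_item):
            if seen[tr] < 0:
                seen[tr] = i
        first = seen
        self._item_trial = trial_of_item
        self._item_y = items["correct"].to_numpy(dtype=float)

        self._ci = items["condition"].map(cond_pos).to_numpy(dtype=np.intp)[first]
        self._pi = items["participant_id"].map(part_pos).to_numpy(dtype=np.intp)[first]
        self._bi = items["block"].to_numpy(dtype=np.intp)[first] - 1
        trial_col = ("trial_overall" if spec.timescale == "overall_1_120"
                     else "trial_in_block")
        self._t = items[trial_col].to_numpy(dtype=float)[first]
        self._log_s = np.log(items["set_size"].to_numpy(dtype=float))[first]
        self._k = np.bincount(trial_of_item, weights=self._item_y, minlength=ntr)
        self._n = np.bincount(trial_of_item, minlength=ntr).astype(float)
        self.n_trials = ntr

        self.layout = _Layout()
        lay = self.layout
        lay.add("b", ["b_start", "b_rate", "b_asym", "b_shape"])
        for k in PARAM_KEYS + ("shape",):
            if k in spec.condition_effects and len(self.conditions) > 1:
                lay.add(f"d_{k}", [f"d_{k}__{c}" for c in self.conditions[1:]])
        for k in spec.random_effects:
            lay.add(f"log_sd_{k}", [f"log_sd_{k}"])
            # in centered mode these entries hold the deviations themselves
            lay.add(f"z_{k}", [f"z_{k}__{p}" for p in self.participants])
        for k in spec.flexible_block_params:
            lay.add(f"blk_{k}", [f"blk_{k}__{c}" for c in self.conditions])
            lay.add(f"w_{k}", [f"wraw_{k}__2", f"wraw_{k}__3"])

        # precomputed gaussian-prior vectors; log_sd and wraw entries get
        # inv-scale 0 here and are handled analytically in the prior
        loc = np.zeros(lay.dim)
        inv_sc = np.zeros(lay.dim)
        for j, name in enumerate(["b_start", "b_rate", "b_asym", "b_shape"]):
            loc[j] = _PRIOR_LOC[name]
            inv_sc[j] = 1.0 / _PRIOR_SCALE[name]
        for k in PARAM_KEYS + ("shape",):
            if f"d_{k}" in lay.slices:
                inv_sc[lay.slices[f"d_{k}"]] = 1.0 / _OFFSET_SCALE[k]
        for k in spec.random_effects:
            if self.centering[k] == 1.0:
                inv_sc[lay.slices[f"z_{k}"]] = 1.0
        for k in spec.flexible_block_params:
            inv_sc[lay.slices[f"blk_{k}"]] = 1.0 / _BLK_SCALE
        self._prior_loc = loc
        self._prior_inv_sc = inv_sc
        self._log_sd_idx = np.array(
            [lay.slices[f"log_sd_{k}"].start for k in spec.random_effects],
            dtype=np.intp)
        self._wraw_idx = np.array(
            [i for k in spec.flexible_block_params
             for i in range(lay.slices[f"w_{k}"].start, lay.slices[f"w_{k}"].stop)],
            dtype=np.intp)

    # -- linear predictors ------------------------------------------------

    def _pack(self, theta: np.ndarray):
        """Dense-array view of the parameter vector for the fused kernel.

        Absent effects (no condition offsets, no random effect, no block
        terms) are packed as zeros, which makes them exact no-ops in the
        linear predictors.
        """
        lay = self.layout
        nC, nP = len(self.conditions), len(self.participants)
        b4 = np.asarray(lay.get(theta, "b"), dtype=float)
        d_all = np.zeros((4, nC))
        sd3 = np.zeros(3)
        z3 = np.zeros((3, nP))
        blk3 = np.zeros((3, nC))
        wvec3 = np.zeros((3, 4))
        u12 = np.zeros((3, 2))
        for j, k in enumerate(PARAM_KEYS + ("shape",)):
            if f"d_{k}" in lay.slices:
                d_all[j, 1:] = lay.get(theta, f"d_{k}")
        for j, k in enumerate(PARAM_KEYS):
            if k in self.spec.random_effects:
                a = self.centering[k]
                sd3[j] = float(np.exp(a * lay.get(theta, f"log_sd_{k}")[0]))
                z3[j] = lay.get(theta, f"z_{k}")
            if k in self.spec.flexible_block_params:
                blk3[j] = lay.get(theta, f"blk_{k}")
                wraw = lay.get(theta, f"w_{k}")
                u1, u2 = _sigmoid(wraw[0]), _sigmoid(wraw[1])
                wvec3[j] = (1.0, u1, u1 * u2, 0.0)
                u12[j] = (u1, u2)
        return b4, d_all, sd3, z3, blk3, wvec3, u12

    # -- likelihood -------------------------------------------------------

    def _fused(self, theta: np.ndarray, want_grad: bool):
        b4, d_all, sd3, z3, blk3, wvec3, u12 = self._pack(theta)
        kern = _fast_kernel if _fast_kernel is not None else _numpy_fused
        out = kern(b4, d_all, sd3, z3, blk3, wvec3,
                   self._ci, self._pi, self._bi,
                   self._t, self._log_s, self._k, self._n,
                   len(self.conditions), len(self.participants), want_grad)
        return (sd3, z3, blk3, u12) + out

    def trial_accuracy(self, theta: np.ndarray) -> np.ndarray:
        """Clamped per-trial probability of a correct item response."""
        return self._fused(theta, False)[5]

    def item_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-item Bernoulli log-likelihood vector at one parameter point."""
        p = self.trial_accuracy(theta)[self._item_trial]
        y = self._item_y
        return y * np.log(p) + (1.0 - y) * np.log1p(-p)

    def loglik(self, theta: np.ndarray) -> float:
        return float(self._fused(theta, False)[4])

    # -- priors -----------------------------------------------------------

    def _log_prior_and_grad(self, theta: np.ndarray):
        # gaussian block (b, d, z, blk entries; others have inv-scale 0)
        r = (theta - self._prior_loc) * self._prior_inv_sc
        lp = -0.5 * float(r @ r)
        grad = -r * self._prior_inv_sc
        # half-normal on sd = exp(log_sd), including the log Jacobian
        if self._log_sd_idx.size:
            ls = theta[self._log_sd_idx]
            sd2 = np.exp(2.0 * ls) / _SD_PRIOR_SCALE**2
            lp += float(np.sum(-0.5 * sd2 + ls))
            grad[self._log_sd_idx] = -sd2 + 1.0
        # (partially) centered deviations: z ~ N(0, sd^(2*(1-a))); their
        # entries have zero weight in the gaussian precomp, so add the full
        # terms here (iterating in canonical key order for determinism)
        lay = self.layout
        nP = len(self.participants)
        for k in self.spec.random_effects:
            a = self.centering[k]
            if a == 1.0:
                continue
            i_sd = lay.slices[f"log_sd_{k}"].start
            inv_var = np.exp(-2.0 * (1.0 - a) * theta[i_sd])
            z = theta[lay.slices[f"z_{k}"]]
            ss = float(z @ z)
            lp += -0.5 * ss * inv_var - nP * (1.0 - a) * theta[i_sd]
            grad[lay.slices[f"z_{k}"]] += -z * inv_var
            grad[i_sd] += (1.0 - a) * (ss * inv_var - nP)
        # standard-logistic on wraw <=> uniform on each sigmoid-transformed u
        if self._wraw_idx.size:
            sig = _sigmoid(theta[self._wraw_idx])
            lp += float(np.sum(np.log(sig) + np.log1p(-sig)))
            grad[self._wraw_idx] = 1.0 - 2.0 * sig
        return lp, grad

    # -- joint density ----------------------------------------------------

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        lay = self.layout
        if np.any(np.abs(theta) > _THETA_BOUND) or not np.all(np.isfinite(theta)):
            return -np.inf, np.zeros(lay.dim)
        (sd3, z3, blk3, u12,
         logl, _, gb4, gd, gz_raw, gsd_raw, gblk, gw2, gw3) = self._fused(theta, True)

        grad = np.zeros(lay.dim)
        grad[lay.slices["b"]] = gb4
        for j, k in enumerate(PARAM_KEYS + ("shape",)):
            if f"d_{k}" in lay.slices:
                grad[lay.slices[f"d_{k}"]] = gd[j, 1:]
        for j, k in enumerate(PARAM_KEYS):
            if k in self.spec.random_effects:
                # deviation = sd^a * z, so d/dz = sd^a and d/dlog_sd = a*sd^a*z
                a = self.centering[k]
                grad[lay.slices[f"z_{k}"]] = sd3[j] * gz_raw[j]
                grad[lay.slices[f"log_sd_{k}"]] = a * sd3[j] * gsd_raw[j]
            if k in self.spec.flexible_block_params:
                grad[lay.slices[f"blk_{k}"]] = gblk[j]
                u1, u2 = u12[j]
                gsl = grad[lay.slices[f"w_{k}"]]
                gsl[0] = (gw2[j] + u2 * gw3[j]) * u1 * (1.0 - u1)
                gsl[1] = gw3[j] * u1 * u2 * (1.0 - u2)

        lp_prior, g_prior = self._log_prior_and_grad(theta)
        grad += g_prior
        total = logl + lp_prior
        if not np.isfinite(total):
            return -np.inf, np.zeros(lay.dim)
        grad[~np.isfinite(grad)] = 0.0
        return total, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_and_grad(theta)[0]

    def log_prior(self, theta: np.ndarray) -> float:
        return self._log_prior_and_grad(theta)[0]

    def initial_point(self, rng: np.random.Generator | None = None,
                      jitter: float = 0.0) -> np.ndarray:
        theta = np.zeros(self.layout.dim)
        b = self.layout.slices["b"]
        theta[b] = [_PRIOR_LOC["b_start"], _PRIOR_LOC["b_rate"],
                    _PRIOR_LOC["b_asym"], _PRIOR_LOC["b_shape"]]
        for k in self.spec.random_effects:
            theta[self.layout.slices[f"log_sd_{k}"]] = np.log(0.2)
        if jitter and rng is not None:
            theta = theta + jitter * rng.standard_normal(self.layout.dim)
        return theta

    # -- convenience ------------------------------------------------------

    def pointwise_loglik(self, thetas: np.ndarray) -> np.ndarray:
        """(draws x items) pointwise log-likelihood matrix."""
        thetas = np.atleast_2d(thetas)
        out = np.empty((thetas.shape[0], self.n_items))
        for d in range(thetas.shape[0]):
            out[d] = self.item_loglik(thetas[d])
        return out
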