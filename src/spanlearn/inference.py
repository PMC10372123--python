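"""Posterior contrasts with the 95%-credible-interval reliability rule.

A contrast is any expression over named posterior draws, evaluated
draw-wise.  It is "reliable" when its equal-tailed 95% interval excludes
zero.  :func:`standard_battery` emits the study-style set of contrasts:
within-condition learning magnitude, between-condition offsets, and (for
within-block models) block-1-minus-block-4 differences per flexible
parameter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import PosteriorDraws
from .hierarchical import PARAM_KEYS

__all__ = ["Contrast", "contrast", "standard_battery", "battery_frame"]

_CI_LO, _CI_HI = 2.5, 97.5


@dataclass(frozen=True)
class Contrast:
    """Summary of one draw-wise posterior quantity."""

    name: str
    median: float
    mean: float
    ci_low: float
    ci_high: float
    reliable: bool
    n_draws: int

    @property
    def b(self) -> float:
        """Point estimate (posterior median by convention)."""
        return self.median


_TOKEN = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_ALLOWED_CALLS = {"exp": np.exp, "log": np.log, "sqrt": np.sqrt, "abs": np.abs}


def _evaluate(draws: PosteriorDraws, expression: str) -> np.ndarray:
    names = set(draws.param_names)
    env: dict[str, object] = {}
    for tok in set(_TOKEN.findall(expression)):
        if tok in _ALLOWED_CALLS:
            env[tok] = _ALLOWED_CALLS[tok]
        elif tok in names:
            env[tok] = draws.stacked(tok)
        else:
            close = [n for n in draws.param_names if tok in n]
            raise KeyError(
                f"unknown parameter {tok!r} in contrast expression; "
                f"{'did you mean ' + ', '.join(close[:5]) + '?' if close else ''}"
                f" available: {draws.param_names}")
    values = eval(expression, {"__builtins__": {}}, env)  # noqa: S307 - vetted tokens
    return np.broadcast_to(np.asarray(values, dtype=float),
                           (draws.n_chains * draws.n_draws,)).copy()


def contrast(draws: PosteriorDraws, expression: str, name: str | None = None,
             *, force: bool = False) -> Contrast:
    """Evaluate an expression over posterior draws and summarize it.

    Raises if the fit failed its convergence checks unless ``force``.
    """
    if not draws.converged and not force:
        raise RuntimeError(
            "fit did not meet convergence criteria "
            f"(max r-hat {max(draws.rhat.values()):.3f}); pass force=True to override")
    values = _evaluate(draws, expression)
    lo, hi = np.percentile(values, [_CI_LO, _CI_HI])
    return Contrast(
        name=name or expression,
        median=float(np.median(values)),
        mean=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        reliable=bool(lo > 0.0 or hi < 0.0),
        n_draws=values.size,
    )


def _cond_term(draws: PosteriorDraws, key: str, cond: str) -> str:
    """Expression for a condition's fixed effect on one log parameter."""
    base = f"b_{key}"
    ref = draws.spec.reference_condition
    if cond == ref or f"d_{key}__{cond}" not in draws.param_names:
        return base
    return f"({base} + d_{key}__{cond})"


def standard_battery(draws: PosteriorDraws, *, force: bool = False) -> list[Contrast]:
    """The study-style contrast battery for a fitted model.

    Emits, per condition, the learning magnitude (log asymptote minus log
    start); per non-reference condition, the start/rate/asymptote offsets;
    and, for within-block fits with cross-block flexibility, the block 1
    minus block 4 difference of each flexible parameter per condition.
    """
    spec = draws.spec
    conds = sorted({n.split("__", 1)[1] for n in draws.param_names
                    if any(n.startswith(f"d_{k}__") for k in PARAM_KEYS)})
    all_conds = [spec.reference_condition] + conds
    out: list[Contrast] = []
    for c in all_conds:
        expr = f"{_cond_term(draws, 'asym', c)} - {_cond_term(draws, 'start', c)}"
        out.append(contrast(draws, expr, name=f"learning_magnitude[{c}]", force=force))
    for c in conds:
        for key in PARAM_KEYS:
            pname = f"d_{key}__{c}"
            if pname in draws.param_names:
                out.append(contrast(draws, pname, name=f"offset_{key}[{c}]", force=force))
    for key in spec.flexible_block_params:
        for c in all_conds:
            pname = f"blk_{key}__{c}"
            # weight(block 1) = 1 and weight(block 4) = 0, so the block-1
            # minus block-4 contrast is the total delta itself
            out.append(contrast(draws, pname, name=f"block1_minus_block4_{key}[{c}]",
                                force=force))
    return out


def battery_frame(contrasts: list[Contrast]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": c.name,
        "b": c.median,
        "mean": c.mean,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "reliable": c.reliable,
        "n_draws": c.n_draws,
    } for c in contrasts])
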