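"""Gradient-based posterior samplers.

A self-contained No-U-Turn sampler (dynamic Hamiltonian Monte Carlo with
slice termination and dual-averaging step-size adaptation) supporting
either an adaptively estimated diagonal metric or a fixed dense metric
(e.g. the Laplace covariance at the posterior mode, which captures the
fixed-effect / random-intercept correlations of hierarchical models), plus
a Laplace approximation used where full MCMC would be wasteful.

Both operate on a callable ``logp_grad(theta) -> (logp, grad)`` over an
unconstrained parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["nuts_chain", "NutsStats", "laplace_draws", "find_map",
           "laplace_covariance"]

_MAX_DELTA_ENERGY = 1000.0  # divergence threshold


@dataclass
class NutsStats:
    step_size: float
    n_divergent: int
    mean_accept: float
    mean_treedepth: float


class _Metric:
    """Euclidean metric: momentum distribution and velocity map.

    ``cov`` is the inverse mass matrix — ideally an estimate of the
    posterior covariance.  1-D arrays give a diagonal metric; 2-D arrays a
    dense one (factorized once).
    """

    def __init__(self, cov: np.ndarray):
        self.cov = cov
        self.dense = cov.ndim == 2
        if self.dense:
            # cov = L L^T; momentum ~ N(0, cov^{-1}) is L^{-T} z
            self._chol = np.linalg.cholesky(cov)
        else:
            self._sqrt = np.sqrt(cov)

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.cov.shape[0])
        if self.dense:
            return np.linalg.solve(self._chol.T, z)
        return z / self._sqrt

    def velocity(self, p: np.ndarray) -> np.ndarray:
        if self.dense:
            return self.cov @ p
        return self.cov * p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.velocity(p))


def _leapfrog(logp_grad, metric, q, p, grad, eps):
    p = p + 0.5 * eps * grad
    q = q + eps * metric.velocity(p)
    lp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


def _find_reasonable_epsilon(logp_grad, metric, q0, rng):
    eps = 1.0
    lp0, grad0 = logp_grad(q0)
    p0 = metric.sample_momentum(rng)
    h0 = lp0 - metric.kinetic(p0)

    def energy(eps):
        _, p1, lp1, _ = _leapfrog(logp_grad, metric, q0, p0, grad0, eps)
        h1 = lp1 - metric.kinetic(p1)
        return h1 if np.isfinite(h1) else -np.inf

    direction = 1.0 if (energy(eps) - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        if direction * (energy(eps) - h0) <= direction * np.log(0.5):
            break
    return float(np.clip(eps, 1e-8, 10.0))


class _Tree:
    """State accumulated by one NUTS trajectory (multinomial variant).

    Subtree proposals carry log weights ``logsumexp(H)`` over their leaves;
    within a subtree the proposal is drawn proportionally, and across
    subtrees with Stan's biased-progressive probability, which favors the
    newer (farther) subtree.
    """

    __slots__ = ("logp_grad", "metric", "eps", "h0", "rng",
                 "alpha_sum", "n_alpha", "divergent")

    def __init__(self, logp_grad, metric, eps, h0, rng):
        self.logp_grad = logp_grad
        self.metric = metric
        self.eps = eps
        self.h0 = h0
        self.rng = rng
        self.alpha_sum = 0.0
        self.n_alpha = 0
        self.divergent = False

    def build(self, q, p, grad, v, j):
        """Returns (q-, p-, g-, q+, p+, g+, q_prop, logw, cont)."""
        if j == 0:
            q1, p1, lp1, g1 = _leapfrog(self.logp_grad, self.metric, q, p, grad,
                                        v * self.eps)
            h1 = lp1 - self.metric.kinetic(p1)
            if not np.isfinite(h1):
                h1 = -np.inf
            diverged = (h1 - self.h0) < -_MAX_DELTA_ENERGY
            self.divergent |= bool(diverged)
            self.alpha_sum += min(1.0, np.exp(min(h1 - self.h0, 0.0)))
            self.n_alpha += 1
            return q1, p1, g1, q1, p1, g1, q1, h1 - self.h0, (not diverged)
        qm, pm, gm, qp, pp, gp, qprop, w1, cont = self.build(q, p, grad, v, j - 1)
        if cont:
            if v == -1:
                qm, pm, gm, _, _, _, qprop2, w2, cont2 = self.build(qm, pm, gm, v, j - 1)
            else:
                _, _, _, qp, pp, gp, qprop2, w2, cont2 = self.build(qp, pp, gp, v, j - 1)
            if cont2 and self.rng.random() < np.exp(min(w2 - np.logaddexp(w1, w2), 0.0)):
                qprop = qprop2
            w1 = np.logaddexp(w1, w2)
            cont = cont2 and _no_u_turn(self.metric, qm, pm, qp, pp)
        return qm, pm, gm, qp, pp, gp, qprop, w1, cont


def _no_u_turn(metric, qm, pm, qp, pp):
    dq = qp - qm
    return (np.dot(dq, metric.velocity(pm)) >= 0) and \
        (np.dot(dq, metric.velocity(pp)) >= 0)


def _adaptation_windows(n_warmup, init_buffer=75, term_buffer=50, base_window=25):
    """Stan-style warmup schedule: iteration indices ending each mass window."""
    if n_warmup < init_buffer + term_buffer + base_window:
        # short warmup: one mass window over the middle half
        return [int(n_warmup * 0.75)] if n_warmup >= 20 else []
    ends = []
    start = init_buffer
    window = base_window
    while start + window <= n_warmup - term_buffer:
        end = start + window
        if end + 2 * window > n_warmup - term_buffer:
            end = n_warmup - term_buffer
        ends.append(end)
        start = end
        window *= 2
    return ends


def nuts_chain(logp_grad, theta0, n_warmup, n_draws, rng,
               target_accept=0.8, max_treedepth=10, metric_cov=None,
               adapt_metric=None):
    """One NUTS chain; returns (draws array, NutsStats).

    ``metric_cov`` seeds the inverse mass matrix: a 1-D array for a
    diagonal metric or a 2-D posterior-covariance estimate for a dense
    metric.  ``adapt_metric`` controls windowed re-estimation from the
    chain's own variance (default: on for diagonal metrics, off for dense
    ones, where the supplied covariance is typically already good).
    """
    dim = theta0.size
    if metric_cov is None:
        metric_cov = np.ones(dim)
    metric = _Metric(np.asarray(metric_cov, dtype=float))
    if adapt_metric is None:
        adapt_metric = not metric.dense

    q = np.asarray(theta0, dtype=float).copy()
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_epsilon(logp_grad, metric, q, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = np.log(eps), 0.0
    da_it = 0  # dual-averaging counter; restarts with each adaptation window
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _adaptation_windows(n_warmup) if adapt_metric else []
    accum_from = min(75, n_warmup // 4)  # skip the early step-size-only buffer
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)
    next_window = windows.pop(0) if windows else None

    draws = np.empty((n_draws, dim))
    n_div = 0
    accept_sum = 0.0
    depth_sum = 0
    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        p0 = metric.sample_momentum(rng)
        h0 = lp - metric.kinetic(p0)
        # small step-size jitter decorrelates trajectory lengths
        tree = _Tree(logp_grad, metric, eps * rng.uniform(0.9, 1.1), h0, rng)
        qm = qp = q
        pm = pp = p0
        gm = gp = grad
        qprop = q
        logw, cont, j = 0.0, True, 0
        while cont and j < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                qm, pm, gm, _, _, _, qcand, w2, cont2 = tree.build(qm, pm, gm, v, j)
            else:
                _, _, _, qp, pp, gp, qcand, w2, cont2 = tree.build(qp, pp, gp, v, j)
            if cont2 and rng.random() < np.exp(min(w2 - logw, 0.0)):
                qprop = qcand
            if cont2:
                logw = np.logaddexp(logw, w2)
            cont = cont2 and _no_u_turn(metric, qm, pm, qp, pp)
            j += 1
        if qprop is not q:
            q = qprop
            lp, grad = logp_grad(q)
        alpha = tree.alpha_sum / max(tree.n_alpha, 1)

        if warming:
            # dual averaging toward the target acceptance statistic
            da_it += 1
            h_bar = (1.0 - 1.0 / (da_it + t0)) * h_bar + \
                (target_accept - alpha) / (da_it + t0)
            log_eps = mu - np.sqrt(da_it) / gamma * h_bar
            w = da_it ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if next_window is not None and it >= accum_from:
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
                if it + 1 == next_window:
                    if welford_n >= 5:
                        var = welford_m2 / (welford_n - 1)
                        var = ((welford_n / (welford_n + 5.0)) * var
                               + 1e-3 * (5.0 / (welford_n + 5.0)))
                        metric = _Metric(np.clip(var, 1e-8, 1e8))
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    # keep the averaged step size; re-center dual averaging
                    # on it under the new metric
                    eps = float(np.exp(log_eps_bar))
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar = np.log(eps), 0.0
                    da_it = 0
                    next_window = windows.pop(0) if windows else None
        else:
            if it == n_warmup:
                eps = float(np.exp(log_eps_bar))
            draws[it - n_warmup] = q
            n_div += int(tree.divergent)
            accept_sum += alpha
            depth_sum += j

    stats = NutsStats(step_size=eps, n_divergent=n_div,
                      mean_accept=accept_sum / max(n_draws, 1),
                      mean_treedepth=depth_sum / max(n_draws, 1))
    return draws, stats


# -- Laplace ------------------------------------------------------------


def find_map(logp_grad, theta0, n_restarts=2, rng=None, maxiter=2000):
    """Posterior mode via L-BFGS with analytic gradients."""

    def negf(x):
        lp, g = logp_grad(x)
        if not np.isfinite(lp):
            return 1e12, np.zeros_like(x)
        return -lp, -g

    best = None
    starts = [np.asarray(theta0, dtype=float)]
    if rng is not None:
        for _ in range(n_restarts - 1):
            starts.append(theta0 + 0.3 * rng.standard_normal(theta0.size))
    for x0 in starts:
        res = optimize.minimize(negf, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -best.fun


def _grad_hessian(logp_grad, x, h=1e-4):
    """Dense Hessian of logp by central differences of the gradient."""
    dim = x.size
    hess = np.empty((dim, dim))
    for i in range(dim):
        step = h * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += step
        xm = x.copy()
        xm[i] -= step
        gp = logp_grad(xp)[1]
        gm = logp_grad(xm)[1]
        hess[i] = (gp - gm) / (2.0 * step)
    return 0.5 * (hess + hess.T)


def laplace_covariance(logp_grad, xmap):
    """Covariance of the Gaussian approximation at the mode.

    The negative inverse Hessian, regularized to positive definiteness.
    """
    prec = -_grad_hessian(logp_grad, xmap)
    jitter = 1e-8
    dim = prec.shape[0]
    for _ in range(12):
        try:
            np.linalg.cholesky(prec + jitter * np.eye(dim))
            break
        except np.linalg.LinAlgError:
            jitter *= 10.0
    else:
        raise RuntimeError("Hessian could not be regularized to positive definite")
    prec = prec + jitter * np.eye(dim)
    cov = np.linalg.inv(prec)
    return 0.5 * (cov + cov.T)


def laplace_draws(logp_grad, theta0, n_total_draws, rng, n_restarts=2):
    """Gaussian posterior approximation at the mode.

    Returns (draws, map_point).
    """
    xmap, _ = find_map(logp_grad, theta0, n_restarts=n_restarts, rng=rng)
    cov = laplace_covariance(logp_grad, xmap)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_total_draws, xmap.size))
    return xmap + z @ chol.T, xmap
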