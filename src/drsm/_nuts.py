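"""A No-U-Turn sampler with Stan-style windowed warmup adaptation.

Implements multinomial NUTS (dynamic Hamiltonian Monte Carlo) on an
unconstrained parameter vector, with a diagonal mass matrix estimated in
doubling warmup windows and step-size tuning by dual averaging toward a
target acceptance statistic.  The caller supplies ``logp_grad(q)``
returning the log target density and its gradient; constraint transforms
and their Jacobians are the caller's responsibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["nuts_sample", "NUTSResult"]

_DIVERGENCE = 1000.0  # energy error treated as a divergent transition


@dataclass
class NUTSResult:
    draws: np.ndarray  # (chains, draws, dim)
    accept_stat: np.ndarray  # (chains,)
    divergences: np.ndarray  # (chains,)
    step_size: np.ndarray  # (chains,)
    treedepth_hits: np.ndarray  # (chains,) saturated-depth count


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


class _Welford:
    """Online mean/variance for the mass-matrix windows."""

    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularize toward unit scale as Stan does
        w = self.n / (self.n + 5.0)
        return w * var + 1e-3 * (1 - w)


@dataclass
class _Subtree:
    q_minus: np.ndarray
    p_minus: np.ndarray
    g_minus: np.ndarray
    lp_minus: float
    q_plus: np.ndarray
    p_plus: np.ndarray
    g_plus: np.ndarray
    lp_plus: float
    q_prop: np.ndarray
    g_prop: np.ndarray
    lp_prop: float
    log_sum_w: float
    sum_metro: float
    n_leaf: int
    turning: bool
    diverging: bool


def _leapfrog(q, p, grad, eps, inv_mass, logp_grad):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, grad, logp


def _kinetic(p, inv_mass) -> float:
    return 0.5 * float(np.dot(p, inv_mass * p))


def _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _build_tree(depth, q, p, grad, lp, direction, eps, inv_mass, H0, logp_grad, rng):
    if depth == 0:
        q1, p1, g1, lp1 = _leapfrog(q, p, grad, direction * eps, inv_mass, logp_grad)
        H = -lp1 + _kinetic(p1, inv_mass) if np.isfinite(lp1) else np.inf
        dH = H - H0
        diverging = not np.isfinite(dH) or dH > _DIVERGENCE
        logw = -dH if not diverging else -np.inf
        metro = min(1.0, math.exp(min(0.0, -dH))) if not diverging else 0.0
        return _Subtree(q1, p1, g1, lp1, q1, p1, g1, lp1, q1, g1, lp1,
                        logw, metro, 1, False, diverging)
    first = _build_tree(depth - 1, q, p, grad, lp, direction, eps, inv_mass, H0,
                        logp_grad, rng)
    if first.turning or first.diverging:
        return first
    if direction == 1:
        second = _build_tree(depth - 1, first.q_plus, first.p_plus, first.g_plus,
                             first.lp_plus, direction, eps, inv_mass, H0, logp_grad, rng)
    else:
        second = _build_tree(depth - 1, first.q_minus, first.p_minus, first.g_minus,
                             first.lp_minus, direction, eps, inv_mass, H0, logp_grad, rng)
    sum_metro = first.sum_metro + second.sum_metro
    n_leaf = first.n_leaf + second.n_leaf
    if second.turning or second.diverging:
        first.sum_metro, first.n_leaf = sum_metro, n_leaf
        first.turning, first.diverging = second.turning, second.diverging
        return first
    log_sum_w = np.logaddexp(first.log_sum_w, second.log_sum_w)
    # multinomial sampling within the subtree
    if math.log(rng.random()) < second.log_sum_w - log_sum_w:
        prop = (second.q_prop, second.g_prop, second.lp_prop)
    else:
        prop = (first.q_prop, first.g_prop, first.lp_prop)
    if direction == 1:
        edges = (first.q_minus, first.p_minus, first.g_minus, first.lp_minus,
                 second.q_plus, second.p_plus, second.g_plus, second.lp_plus)
    else:
        edges = (second.q_minus, second.p_minus, second.g_minus, second.lp_minus,
                 first.q_plus, first.p_plus, first.g_plus, first.lp_plus)
    turning = _uturn(edges[0], edges[4], edges[1], edges[5], inv_mass)
    return _Subtree(*edges, *prop, log_sum_w, sum_metro, n_leaf, turning, False)


def _nuts_step(q, grad, lp, eps, inv_mass, max_treedepth, logp_grad, rng):
    p0 = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    H0 = -lp + _kinetic(p0, inv_mass)
    q_minus = q_plus = q
    p_minus = p_plus = p0
    g_minus = g_plus = grad
    lp_minus = lp_plus = lp
    q_prop, g_prop, lp_prop = q, grad, lp
    log_sum_w = 0.0
    sum_metro, n_leaf = 0.0, 0
    diverged = False
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(depth, q_plus, p_plus, g_plus, lp_plus, 1,
                              eps, inv_mass, H0, logp_grad, rng)
            q_plus, p_plus, g_plus, lp_plus = sub.q_plus, sub.p_plus, sub.g_plus, sub.lp_plus
        else:
            sub = _build_tree(depth, q_minus, p_minus, g_minus, lp_minus, -1,
                              eps, inv_mass, H0, logp_grad, rng)
            q_minus, p_minus, g_minus, lp_minus = sub.q_minus, sub.p_minus, sub.g_minus, sub.lp_minus
        sum_metro += sub.sum_metro
        n_leaf += sub.n_leaf
        if sub.diverging:
            diverged = True
            break
        if sub.turning:
            break
        # biased progressive sampling favours the new subtree
        if math.log(rng.random()) < sub.log_sum_w - log_sum_w:
            q_prop, g_prop, lp_prop = sub.q_prop, sub.g_prop, sub.lp_prop
        log_sum_w = np.logaddexp(log_sum_w, sub.log_sum_w)
        if _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass):
            break
        depth += 1
    accept_stat = sum_metro / max(n_leaf, 1)
    return q_prop, g_prop, lp_prop, accept_stat, diverged, depth >= max_treedepth


def _find_reasonable_eps(q, grad, lp, inv_mass, logp_grad, rng) -> float:
    eps = 1.0
    p0 = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    H0 = -lp + _kinetic(p0, inv_mass)
    _, p1, _, lp1 = _leapfrog(q, p0, grad, eps, inv_mass, logp_grad)
    H1 = -lp1 + _kinetic(p1, inv_mass) if np.isfinite(lp1) else np.inf
    direction = 1 if (H0 - H1) > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, _, lp1 = _leapfrog(q, p0, grad, eps, inv_mass, logp_grad)
        H1 = -lp1 + _kinetic(p1, inv_mass) if np.isfinite(lp1) else np.inf
        crossed = (H0 - H1) > math.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return eps


def _adaptation_windows(warmup: int) -> tuple[int, int, list[int]]:
    """(init_buffer, term_buffer, metric-window end iterations)."""
    init_buf, term_buf, base = 75, 50, 25
    if warmup < init_buf + term_buf + base:
        init_buf = max(int(0.15 * warmup), 1)
        term_buf = max(int(0.1 * warmup), 1)
        base = max(warmup - init_buf - term_buf, 1)
    ends = []
    size, pos = base, init_buf
    while pos + size < warmup - term_buf:
        ends.append(pos + size)
        pos += size
        size *= 2
    ends.append(warmup - term_buf)
    return init_buf, term_buf, ends


def _run_chain(logp_grad, q0, warmup, draws, rng, max_treedepth, target_accept):
    dim = q0.shape[0]
    q = q0.copy()
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim)
    eps = _find_reasonable_eps(q, grad, lp, inv_mass, logp_grad, rng)
    da = _DualAveraging(eps, target=target_accept)
    init_buf, term_buf, window_ends = _adaptation_windows(warmup)
    welford = _Welford(dim)
    next_window = 0

    for it in range(warmup):
        q, grad, lp, astat, div, _ = _nuts_step(
            q, grad, lp, eps, inv_mass, max_treedepth, logp_grad, rng
        )
        eps = da.update(astat)
        if init_buf <= it < warmup - term_buf:
            welford.add(q)
        if next_window < len(window_ends) and it + 1 == window_ends[next_window]:
            if welford.n >= 10:
                inv_mass = welford.variance()
            welford = _Welford(dim)
            next_window += 1
            eps = _find_reasonable_eps(q, grad, lp, inv_mass, logp_grad, rng)
            da = _DualAveraging(eps, target=target_accept)
    eps = da.adapted if da.count > 0 else eps

    out = np.empty((draws, dim))
    accept_sum, n_div, depth_hits = 0.0, 0, 0
    for it in range(draws):
        q, grad, lp, astat, div, hit = _nuts_step(
            q, grad, lp, eps, inv_mass, max_treedepth, logp_grad, rng
        )
        out[it] = q
        accept_sum += astat
        n_div += int(div)
        depth_hits += int(hit)
    return out, accept_sum / max(draws, 1), n_div, eps, depth_hits


def nuts_sample(
    logp_grad,
    dim: int,
    *,
    chains: int = 4,
    warmup: int = 500,
    draws: int = 500,
    seed: int | np.random.SeedSequence | None = None,
    max_treedepth: int = 8,
    target_accept: float = 0.8,
    init: np.ndarray | None = None,
    init_scale: float = 0.3,
) -> NUTSResult:
    """Run NUTS chains and return post-warmup draws.

    ``init`` may supply per-chain start points (chains, dim); otherwise
    starts are drawn uniform in ``(-init_scale, init_scale)``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(chains)
    all_draws = np.empty((chains, draws, dim))
    astats = np.empty(chains)
    divs = np.empty(chains, dtype=int)
    epss = np.empty(chains)
    hits = np.empty(chains, dtype=int)
    for c in range(chains):
        rng = np.random.default_rng(child_seeds[c])
        q0 = init[c] if init is not None else rng.uniform(-init_scale, init_scale, dim)
        all_draws[c], astats[c], divs[c], epss[c], hits[c] = _run_chain(
            logp_grad, np.asarray(q0, dtype=float), warmup, draws, rng,
            max_treedepth, target_accept,
        )
    return NUTSResult(all_draws, astats, divs, epss, hits)
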