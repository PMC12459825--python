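"""A No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

The sampler targets an unconstrained log density supplied as a
``logp_and_grad(q) -> (float, ndarray)`` callable. Warmup follows the
usual three-phase scheme: a fast initial buffer adapting only the step
size, a sequence of doubling "slow" windows in which the diagonal mass
matrix is re-estimated from the warmup draws, and a terminal buffer
re-equilibrating the step size. Tree building uses slice sampling over
the Hamiltonian level set with the standard uniform-progressive state
selection and a no-U-turn termination criterion; trajectories whose
energy error exceeds ``DIVERGENCE_THRESHOLD`` are flagged as divergent.

Kinetic energy is 0.5 * p' M^-1 p with p ~ Normal(0, M) and M diagonal,
estimated as the reciprocal posterior variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray           # (n_draws, dim), post-warmup
    divergences: int            # post-warmup divergent transitions
    step_size: float
    accept_rate: float          # mean post-warmup acceptance statistic
    tree_depths: np.ndarray = field(repr=False, default=None)


class _DualAveraging:
    """Nesterov dual averaging of log step size (target acceptance statistic)."""

    def __init__(self, eps0: float, target: float = 0.87):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    def restart(self, eps: float) -> None:
        self.mu = np.log(10.0 * eps)
        self.log_eps = np.log(eps)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # Stan-style shrinkage toward unit scale for short windows
        return (self.n / (self.n + 5.0)) * var + 1e-3 * (5.0 / (self.n + 5.0))


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "grad_minus", "q_plus", "p_plus", "grad_plus",
        "q_sample", "grad_sample", "logp_sample", "n_valid", "stop",
        "sum_accept", "n_accept", "diverged",
    )


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * inv_mass * p1
    logp1, grad1 = logp_and_grad(q1)
    p2 = p1 + 0.5 * eps * grad1
    return q1, p2, logp1, grad1


def _hamiltonian(logp, p, inv_mass) -> float:
    return logp - 0.5 * float(np.dot(p, inv_mass * p))


def _no_uturn(q_minus, q_plus, p_minus, p_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (
        float(np.dot(dq, inv_mass * p_minus)) < 0
        or float(np.dot(dq, inv_mass * p_plus)) < 0
    )


def _build_tree(logp_and_grad, q, p, grad, logp, log_u, direction, depth, eps,
                inv_mass, h0, rng):
    t = _Tree()
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_and_grad, q, p, grad, direction * eps, inv_mass)
        h1 = _hamiltonian(logp1, p1, inv_mass)
        t.q_minus = t.q_plus = t.q_sample = q1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = t.grad_sample = grad1
        t.logp_sample = logp1
        t.diverged = (not np.isfinite(h1)) or (log_u - h1 > DIVERGENCE_THRESHOLD)
        t.n_valid = int(log_u <= h1)
        t.stop = t.diverged
        t.sum_accept = float(min(1.0, np.exp(min(0.0, h1 - h0))))
        t.n_accept = 1
        return t
    # inner then outer subtree
    t = _build_tree(logp_and_grad, q, p, grad, logp, log_u, direction, depth - 1,
                    eps, inv_mass, h0, rng)
    if t.stop:
        return t
    if direction == -1:
        t2 = _build_tree(logp_and_grad, t.q_minus, t.p_minus, t.grad_minus, logp,
                         log_u, direction, depth - 1, eps, inv_mass, h0, rng)
        t.q_minus, t.p_minus, t.grad_minus = t2.q_minus, t2.p_minus, t2.grad_minus
    else:
        t2 = _build_tree(logp_and_grad, t.q_plus, t.p_plus, t.grad_plus, logp,
                         log_u, direction, depth - 1, eps, inv_mass, h0, rng)
        t.q_plus, t.p_plus, t.grad_plus = t2.q_plus, t2.p_plus, t2.grad_plus
    total = t.n_valid + t2.n_valid
    if total > 0 and t2.n_valid > 0 and rng.random() < t2.n_valid / total:
        t.q_sample, t.grad_sample, t.logp_sample = t2.q_sample, t2.grad_sample, t2.logp_sample
    t.n_valid = total
    t.sum_accept += t2.sum_accept
    t.n_accept += t2.n_accept
    t.stop = t2.stop or _no_uturn(t.q_minus, t.q_plus, t.p_minus, t.p_plus, inv_mass)
    t.diverged = t.diverged or t2.diverged
    return t


def _nuts_step(logp_and_grad, q, logp, grad, eps, inv_mass, mass_sd, max_depth, rng):
    p0 = mass_sd * rng.standard_normal(q.shape[0])
    h0 = _hamiltonian(logp, p0, inv_mass)
    log_u = h0 + np.log(rng.random())  # slice variable on the log scale
    q_minus = q_plus = q
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    q_new, logp_new, grad_new = q, logp, grad
    n_valid, depth = 1, 0
    sum_accept, n_accept = 0.0, 0
    diverged = False
    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            t = _build_tree(logp_and_grad, q_minus, p_minus, grad_minus, logp,
                            log_u, direction, depth, eps, inv_mass, h0, rng)
            q_minus, p_minus, grad_minus = t.q_minus, t.p_minus, t.grad_minus
        else:
            t = _build_tree(logp_and_grad, q_plus, p_plus, grad_plus, logp,
                            log_u, direction, depth, eps, inv_mass, h0, rng)
            q_plus, p_plus, grad_plus = t.q_plus, t.p_plus, t.grad_plus
        sum_accept += t.sum_accept
        n_accept += t.n_accept
        diverged = diverged or t.diverged
        if t.stop:
            break
        if t.n_valid > 0 and rng.random() < min(1.0, t.n_valid / n_valid):
            q_new, logp_new, grad_new = t.q_sample, t.logp_sample, t.grad_sample
        n_valid += t.n_valid
        depth += 1
        if _no_uturn(q_minus, q_plus, p_minus, p_plus, inv_mass):
            break
    accept_stat = sum_accept / max(n_accept, 1)
    return q_new, logp_new, grad_new, accept_stat, diverged, depth


def _find_reasonable_eps(logp_and_grad, q, logp, grad, inv_mass, mass_sd, rng) -> float:
    eps = 0.1
    p = mass_sd * rng.standard_normal(q.shape[0])
    h0 = _hamiltonian(logp, p, inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
    h1 = _hamiltonian(logp1, p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
        h1 = _hamiltonian(logp1, p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return float(eps)


def _slow_windows(n_warmup: int):
    """(start, end) iterations of the mass-matrix estimation windows."""
    init_buffer, term_buffer, base = 75, 50, 25
    if n_warmup < init_buffer + term_buffer + base:
        # short warmup: single window over the middle half
        return [(n_warmup // 4, max(n_warmup // 4 + 1, 3 * n_warmup // 4))]
    windows = []
    start, size = init_buffer, base
    while start + size < n_warmup - term_buffer:
        if start + 3 * size >= n_warmup - term_buffer:
            size = n_warmup - term_buffer - start  # absorb the remainder
        windows.append((start, start + size))
        start += size
        size *= 2
    return windows


def nuts(
    logp_and_grad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_depth: int = 9,
    target_accept: float = 0.87,
) -> ChainResult:
    """Run one NUTS chain; returns post-warmup draws and sampler diagnostics."""
    q = np.asarray(q0, dtype=float).copy()
    dim = q.shape[0]
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")
    # overflow in trial trajectories is expected and handled as divergence
    old_err = np.seterr(over="ignore", invalid="ignore")
    inv_mass = np.ones(dim)
    mass_sd = np.ones(dim)
    eps = _find_reasonable_eps(logp_and_grad, q, logp, grad, inv_mass, mass_sd, rng)
    da = _DualAveraging(eps, target=target_accept)
    windows = _slow_windows(n_warmup)
    window_idx = 0
    welford = _Welford(dim)
    draws = np.empty((n_draws, dim))
    depths = np.empty(n_draws, dtype=int)
    divergences = 0
    accepts = []
    try:
        for it in range(n_warmup + n_draws):
            warming = it < n_warmup
            q, logp, grad, accept_stat, diverged, depth = _nuts_step(
                logp_and_grad, q, logp, grad, eps, inv_mass, mass_sd, max_depth, rng
            )
            if warming:
                eps = da.update(accept_stat)
                if window_idx < len(windows):
                    w_start, w_end = windows[window_idx]
                    if w_start <= it < w_end:
                        welford.push(q)
                    if it == w_end - 1:
                        var = welford.variance()
                        inv_mass = var
                        mass_sd = 1.0 / np.sqrt(var)
                        welford = _Welford(dim)
                        window_idx += 1
                        eps = _find_reasonable_eps(
                            logp_and_grad, q, logp, grad, inv_mass, mass_sd, rng
                        )
                        da.restart(eps)
                if it == n_warmup - 1:
                    eps = da.adapted
            else:
                i = it - n_warmup
                draws[i] = q
                depths[i] = depth
                divergences += int(diverged)
                accepts.append(accept_stat)
    finally:
        np.seterr(**old_err)
    return ChainResult(
        draws=draws,
        divergences=divergences,
        step_size=float(eps),
        accept_rate=float(np.mean(accepts)) if accepts else float("nan"),
        tree_depths=depths,
    )
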