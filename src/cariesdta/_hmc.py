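"""Vectorized Hamiltonian Monte Carlo with dual-averaging step-size adaptation.

All chains run in lockstep: the target supplies a joint ``logp_grad`` over a
(chains, dim) position matrix, so one numpy pass advances every chain.
Warmup follows the usual windowed scheme: an initial step-size-only buffer,
a sequence of doubling windows that each re-estimate a diagonal mass matrix
from the window's draws (after which the step size is re-initialized by a
bracketing search and dual averaging restarts), and a terminal step-size
polish.  Trajectory lengths are jittered uniformly on [1, max_leapfrog]
(shared across chains per iteration, preserving the lockstep vectorization)
to break resonances.  A proposal whose energy error exceeds 1000 is counted
as divergent and rejected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_DIVERGENCE_ENERGY = 1000.0


@dataclass
class HmcRun:
    positions: np.ndarray  # (chains, draws, dim)
    accept_rate: np.ndarray  # (chains,)
    divergences: int
    step_size: np.ndarray  # (chains,)
    mass_diag: np.ndarray  # (dim,)


class _DualAveraging:
    """Nesterov dual averaging of log step size, one state per chain."""

    def __init__(self, eps0, target):
        eps0 = np.asarray(eps0, dtype=float)
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = np.zeros_like(eps0)
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob):
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return np.exp(self.log_eps)

    @property
    def eps_final(self):
        return np.exp(self.log_eps_bar)


def _leapfrog(logp_grad, x, p, eps, inv_mass, n_steps):
    lp, grad = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        x = x + eps * (p * inv_mass)
        lp, grad = logp_grad(x)
        p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _find_reasonable_eps(logp_grad, x, mass, rng, start=None):
    """Bracketing search: double/halve a shared step size until the one-step
    acceptance probability crosses 1/2 (in the median across chains)."""
    C, D = x.shape
    eps = float(start) if start else 1.0 / max(D, 1) ** 0.25
    lp0, _ = logp_grad(x)
    direction = 0
    for _ in range(40):
        p = rng.standard_normal((C, D)) * np.sqrt(mass)
        h0 = -lp0 + 0.5 * np.sum(p**2 / mass, axis=1)
        with np.errstate(over="ignore", invalid="ignore"):
            x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, eps, 1.0 / mass, 1)
            h1 = -lp1 + 0.5 * np.sum(p1**2 / mass, axis=1)
            alpha = np.exp(np.clip(h0 - h1, -700, 0))
        alpha = np.where(np.isfinite(h1), alpha, 0.0)
        med = np.median(alpha)
        step = 1 if med > 0.5 else -1
        if direction == 0:
            direction = step
        elif step != direction:
            break
        eps *= 2.0**step
    return eps


def _warmup_schedule(warmup: int):
    """(initial buffer, list of mass-window end points, terminal buffer start)."""
    if warmup < 60:
        return warmup, [], warmup
    init = max(int(0.15 * warmup), 20)
    term = max(int(0.1 * warmup), 25)
    span = warmup - init - term
    ends, w = [], max(span // 15, 10)
    pos = init
    while span > 0:
        take = min(w, span)
        # absorb a too-small final window into the previous one
        if span - take < w and span - take > 0:
            take = span
        pos += take
        span -= take
        ends.append(pos)
        w *= 2
    return init, ends, warmup - term


def sample_hmc(
    logp_grad,
    init: np.ndarray,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_leapfrog: int = 48,
) -> HmcRun:
    x = np.array(init, dtype=float)
    C, D = x.shape
    mass = np.ones(D)
    eps0 = _find_reasonable_eps(logp_grad, x, mass, rng)
    da = _DualAveraging(np.full(C, eps0), target_accept)

    init_buf, window_ends, term_start = _warmup_schedule(warmup)
    window: list[np.ndarray] = []

    positions = np.empty((C, draws, D))
    accepts = np.zeros(C)
    divergences = 0

    eps = da.eps[:, None]
    for it in range(warmup + draws):
        in_warmup = it < warmup
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        p0 = rng.standard_normal((C, D)) * np.sqrt(mass)
        lp0, _ = logp_grad(x)
        h0 = -lp0 + 0.5 * np.sum(p0**2 / mass, axis=1)
        # wildly off-target proposals overflow harmlessly: they surface as
        # non-finite energies and are rejected below
        with np.errstate(over="ignore", invalid="ignore"):
            x1, p1, lp1, _ = _leapfrog(logp_grad, x, p0, eps, 1.0 / mass, n_steps)
            h1 = -lp1 + 0.5 * np.sum(p1**2 / mass, axis=1)
        delta = h0 - h1
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        if not in_warmup:
            divergences += int(np.sum(delta < -_DIVERGENCE_ENERGY))
        with np.errstate(over="ignore"):
            alpha = np.exp(np.clip(delta, -700, 0))
        accept = rng.random(C) < alpha
        x = np.where(accept[:, None], x1, x)

        if in_warmup:
            da.update(alpha)
            eps = da.eps[:, None]
            if init_buf <= it < term_start:
                window.append(x.copy())
            if it + 1 in window_ends and len(window) * C >= 10:
                block = np.concatenate(window, axis=0)
                n = block.shape[0]
                # regularized posterior variance -> inverse metric; the
                # momentum mass is its reciprocal
                var = (n * np.var(block, axis=0) + 5e-3) / (n + 5.0)
                mass = 1.0 / np.maximum(var, 1e-8)
                window = []
                eps_new = _find_reasonable_eps(
                    logp_grad, x, mass, rng, start=float(np.median(da.eps_final))
                )
                da = _DualAveraging(np.full(C, eps_new), target_accept)
                eps = da.eps[:, None]
            if it + 1 == warmup:
                eps = da.eps_final[:, None]
        else:
            positions[:, it - warmup, :] = x
            accepts += accept

    return HmcRun(
        positions=positions,
        accept_rate=accepts / max(draws, 1),
        divergences=divergences,
        step_size=eps[:, 0],
        mass_diag=mass,
    )
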