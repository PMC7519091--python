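"""Shared MCMC machinery: multi-chain adaptive random-walk Metropolis.

The proposal is a joint Gaussian whose scale and covariance are adapted
during burn-in (Robbins-Monro on the log step size toward a target
acceptance rate; empirical covariance of the burn-in history) and frozen
afterwards, so retained draws come from a fixed-kernel Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

TARGET_ACCEPT = 0.30
_ADAPT_INTERVAL = 50
_COV_INTERVAL = 500


@dataclass
class ChainRun:
    """Retained draws of one sampler run: shape (n_chains, n_keep, dim)."""

    draws: np.ndarray
    accept_rates: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_keep(self) -> int:
        return self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """Draws pooled across chains, shape (n_chains * n_keep, dim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])


def _find_start(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    jitter: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jitter x0 until the log posterior is finite (shrinking the jitter)."""
    scale = 1.0
    for _ in range(200):
        x = x0 + scale * jitter * rng.standard_normal(x0.size)
        if np.isfinite(logpost(x)):
            return x
        scale *= 0.8
    if np.isfinite(logpost(x0)):
        return x0.copy()
    raise RuntimeError("could not find a starting point with finite log posterior")


def run_chains(
    logpost: Callable[[np.ndarray], float],
    x0: Sequence[float],
    *,
    n_chains: int,
    n_iter: int,
    n_burn: int,
    thin: int,
    seed: int | np.random.SeedSequence,
    init_scale: Sequence[float] | None = None,
    jitter: Sequence[float] | None = None,
) -> ChainRun:
    """Run ``n_chains`` adaptive Metropolis chains on ``logpost``.

    Each chain runs ``n_iter`` iterations; the first ``n_burn`` are used for
    adaptation and discarded, and the remainder thinned by ``thin``.
    Retained count per chain is ``(n_iter - n_burn) // thin``.
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    if n_burn >= n_iter:
        raise ValueError("n_burn must be smaller than n_iter")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if init_scale is None:
        init_scale = np.maximum(np.abs(x0) * 0.1, 0.1)
    init_scale = np.broadcast_to(np.asarray(init_scale, float), (dim,)).copy()
    if jitter is None:
        jitter = init_scale
    jitter = np.broadcast_to(np.asarray(jitter, float), (dim,)).copy()

    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    chain_seeds = seed_seq.spawn(n_chains)

    n_keep = (n_iter - n_burn) // thin
    draws = np.empty((n_chains, n_keep, dim))
    accept_rates = np.empty(n_chains)

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        x = _find_start(logpost, x0, jitter, rng)
        lp = logpost(x)

        log_s = np.log(2.38 / np.sqrt(dim))
        chol = np.diag(init_scale)
        history = np.empty((n_burn, dim)) if n_burn else None
        n_acc_window = 0
        n_acc_total = 0
        kept = 0

        for i in range(n_iter):
            step = np.exp(log_s) * (chol @ rng.standard_normal(dim))
            x_prop = x + step
            lp_prop = logpost(x_prop)
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = x_prop, lp_prop
                n_acc_window += 1
                n_acc_total += 1

            if i < n_burn:
                history[i] = x
                if (i + 1) % _ADAPT_INTERVAL == 0:
                    acc = n_acc_window / _ADAPT_INTERVAL
                    log_s += 0.66 * (acc - TARGET_ACCEPT)
                    n_acc_window = 0
                if (i + 1) % _COV_INTERVAL == 0 and i + 1 >= _COV_INTERVAL:
                    recent = history[(i + 1) // 2 : i + 1]
                    cov = np.cov(recent.T).reshape(dim, dim)
                    cov += 1e-10 * np.eye(dim) + 1e-8 * np.diag(np.diag(cov))
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
            else:
                j = i - n_burn
                if (j + 1) % thin == 0 and kept < n_keep:
                    draws[c, kept] = x
                    kept += 1

        accept_rates[c] = n_acc_total / n_iter

    return ChainRun(draws=draws, accept_rates=accept_rates)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar quantity.

    ``chains`` has shape (n_chains, n_samples). Uses the classic
    between/within-chain variance ratio; values below 1 arising from
    finite-sample noise are clamped to 1, so identical chains give exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_samples)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("at least 2 chains are required for the PSRF")
    if n < 2:
        raise ValueError("chains must contain at least 2 samples")
    chain_means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chain_means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b_over_n
    return float(max(1.0, np.sqrt(var_plus / w)))


def equal_tailed_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credibility range of pooled draws."""
    lo = (1.0 - prob) / 2.0
    q = np.quantile(np.asarray(draws, float).ravel(), [lo, 1.0 - lo])
    return float(q[0]), float(q[1])
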