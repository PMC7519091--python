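"""Bayesian stable-isotope mixing model with source and DTDF uncertainty.

For dietary proportions p on the simplex, each consumer's isotope value is

    X_ij ~ N( sum_k p_k (mu_kj + Delta_kj),  V_j(p) )

where V_j is the p^2-weighted source + discrimination variance plus either
an additive residual variance (the simmr-style formulation, default) or a
multiplicative residual factor on the process variance (the MixSIAR-style
formulation). Proportions are sampled in an unconstrained additive-log-ratio
space with adaptive random-walk Metropolis and mapped back by softmax; the
Dirichlet prior picks up the log-ratio Jacobian so that, absent data, the
draws reproduce the Dirichlet exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _mcmc
from ._mcmc import gelman_rubin as _psrf
from .bayes_fit import ConvergenceWarning, McmcSettings, PSRF_THRESHOLD
from .dtdf import DtdfSpec
from .synthetic_data import DietSource

__all__ = [
    "MixtureProblem",
    "MixtureEstimate",
    "fit_mixing_model",
    "summarize_proportions",
    "compare_dtdf_scenarios",
]

_RESID_SD_PRIOR = 5.0  # half-normal sd for the additive residual, per mil
_MULT_PRIOR_SD = 2.0  # half-normal sd for the multiplicative factor

#: Default mixing-run settings (3 chains x 100k, burn 50k, thin 3).
MIXING_DEFAULTS = McmcSettings(n_chains=3, n_iter=100_000, n_burn=50_000, thin=3)


@dataclass(frozen=True)
class MixtureProblem:
    """Consumers from one group x tissue, candidate sources and their DTDFs."""

    consumers: pd.DataFrame
    sources: list[DietSource]
    dtdfs: list[DtdfSpec]
    prior_alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sources) < 2:
            raise ValueError("need at least 2 sources")
        if len(self.dtdfs) != len(self.sources):
            raise ValueError("need exactly one DtdfSpec per source")
        by_name = {d.source: d for d in self.dtdfs}
        missing = [s.name for s in self.sources if s.name not in by_name]
        if missing:
            raise ValueError(f"sources without a DtdfSpec: {missing}")
        # align dtdf order with sources
        object.__setattr__(self, "dtdfs", [by_name[s.name] for s in self.sources])
        alpha = (
            np.ones(len(self.sources))
            if self.prior_alpha is None
            else np.asarray(self.prior_alpha, float)
        )
        if alpha.size != len(self.sources) or np.any(alpha <= 0):
            raise ValueError("prior_alpha must be positive with one entry per source")
        object.__setattr__(self, "prior_alpha", alpha)
        mu = self._corrected_means()
        if np.allclose(mu, mu[0], atol=1e-9):
            raise ValueError(
                "unidentifiable problem: all sources identical in both isotopes"
            )

    def _corrected_means(self) -> np.ndarray:
        return np.array(
            [
                [s.mu_c + d.delta_c, s.mu_n + d.delta_n]
                for s, d in zip(self.sources, self.dtdfs)
            ]
        )

    @property
    def n_consumers(self) -> int:
        return len(self.consumers)


@dataclass
class MixtureEstimate:
    """Posterior dietary proportions for one fitted problem."""

    source_names: list[str]
    p_draws: np.ndarray  # (n_chains, n_keep, K), rows on the simplex
    resid_draws: np.ndarray  # (n_chains, n_keep, 2) residual parameter per isotope
    summary: pd.DataFrame  # per source: mean, cr_low, cr_high (fractions)
    psrf: dict[str, float]
    converged: bool
    error_structure: str = "additive"

    def flat_draws(self) -> np.ndarray:
        return self.p_draws.reshape(-1, self.p_draws.shape[-1])


def _softmax_full(z: np.ndarray) -> np.ndarray:
    """Map K-1 free coordinates to the K-simplex (last coordinate pinned)."""
    zfull = np.append(z, 0.0)
    zfull -= zfull.max()
    e = np.exp(zfull)
    return e / e.sum()


def fit_mixing_model(
    problem: MixtureProblem,
    settings: McmcSettings | None = None,
    error_structure: str = "additive",
) -> MixtureEstimate:
    """Sample the posterior of dietary proportions.

    ``error_structure`` selects the residual term: "additive" adds a
    half-normal residual variance per isotope; "multiplicative" scales the
    p^2-weighted process variance by a per-isotope factor, which lets the
    model shrink its predictive spread below the raw source + DTDF spread
    (needed when consumers are far less variable than their sources).
    With an empty consumer table the likelihood is skipped and the draws
    reproduce the Dirichlet prior.
    """
    if error_structure not in {"additive", "multiplicative"}:
        raise ValueError("error_structure must be 'additive' or 'multiplicative'")
    settings = settings or MIXING_DEFAULTS
    k = len(problem.sources)
    alpha = problem.prior_alpha

    mu_corr = problem._corrected_means()  # (K, 2)
    var_proc = np.array(
        [
            [d.sd_c**2 + s.sd_c**2, d.sd_n**2 + s.sd_n**2]
            for s, d in zip(problem.sources, problem.dtdfs)
        ]
    )  # (K, 2) source + discrimination variance per isotope

    have_data = problem.n_consumers > 0
    if have_data:
        x_obs = problem.consumers[["d13c", "d15n"]].to_numpy(float)
        n = x_obs.shape[0]

    def logpost(x: np.ndarray) -> float:
        z = x[: k - 1]
        r = x[k - 1 :]
        if np.any(r <= 0):
            return -np.inf
        p = _softmax_full(z)
        if np.any(p <= 0):  # softmax underflow: outside the usable region
            return -np.inf
        # Dirichlet prior + ALR Jacobian (prod p_k) => sum alpha_k log p_k
        lp = float(alpha @ np.log(p))
        if error_structure == "additive":
            lp += -0.5 * float(np.sum((r / _RESID_SD_PRIOR) ** 2))
        else:
            lp += -0.5 * float(np.sum((r / _MULT_PRIOR_SD) ** 2))
        if have_data:
            mean = p @ mu_corr  # (2,)
            pvar = (p**2) @ var_proc  # (2,)
            var = pvar + r**2 if error_structure == "additive" else pvar * r**2
            if np.any(var <= 0):
                return -np.inf
            dev = x_obs - mean
            lp += float(
                -0.5 * n * np.sum(np.log(2.0 * np.pi * var))
                - 0.5 * np.sum(dev**2 / var)
            )
        return lp

    x0 = np.concatenate([np.zeros(k - 1), np.ones(2)])
    run = _mcmc.run_chains(
        logpost,
        x0,
        n_chains=settings.n_chains,
        n_iter=settings.n_iter,
        n_burn=settings.n_burn,
        thin=settings.thin,
        seed=settings.seed,
        init_scale=np.concatenate([np.full(k - 1, 1.0), np.full(2, 0.5)]),
    )
    z_draws = run.draws[..., : k - 1]
    resid_draws = run.draws[..., k - 1 :]
    zfull = np.concatenate([z_draws, np.zeros(z_draws.shape[:-1] + (1,))], axis=-1)
    zfull -= zfull.max(axis=-1, keepdims=True)
    e = np.exp(zfull)
    p_draws = e / e.sum(axis=-1, keepdims=True)

    names = [s.name for s in problem.sources]
    psrf = {name: _psrf(p_draws[..., j]) for j, name in enumerate(names)}
    flat = p_draws.reshape(-1, k)
    rows = []
    for j, name in enumerate(names):
        lo, hi = _mcmc.equal_tailed_interval(flat[:, j])
        rows.append(
            {
                "source": name,
                "mean": float(flat[:, j].mean()),
                "cr_low": lo,
                "cr_high": hi,
                "psrf": psrf[name],
            }
        )
    summary = pd.DataFrame(rows).set_index("source")
    converged = all(v <= PSRF_THRESHOLD for v in psrf.values())
    if not converged:
        bad = {kk: round(v, 3) for kk, v in psrf.items() if v > PSRF_THRESHOLD}
        warnings.warn(
            f"mixing model did not converge (PSRF > {PSRF_THRESHOLD}): {bad}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return MixtureEstimate(
        source_names=names,
        p_draws=p_draws,
        resid_draws=resid_draws,
        summary=summary,
        psrf=psrf,
        converged=converged,
        error_structure=error_structure,
    )


def summarize_proportions(draws: np.ndarray, source_names=None) -> pd.DataFrame:
    """Per-source mean and equal-tailed 95% CR of simplex draws, in percent.

    Values are full precision; round to 1 decimal for display.
    """
    draws = np.asarray(draws, float)
    if draws.ndim == 3:
        draws = draws.reshape(-1, draws.shape[-1])
    if draws.size == 0:
        raise ValueError("no draws to summarize")
    if np.any(draws < -1e-9) or np.any(np.abs(draws.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("draws must lie on the simplex")
    k = draws.shape[1]
    names = list(source_names) if source_names is not None else [str(i + 1) for i in range(k)]
    rows = []
    for j in range(k):
        lo, hi = _mcmc.equal_tailed_interval(draws[:, j])
        rows.append(
            {
                "source": names[j],
                "mean_pct": 100.0 * float(draws[:, j].mean()),
                "cr_low_pct": 100.0 * lo,
                "cr_high_pct": 100.0 * hi,
            }
        )
    return pd.DataFrame(rows).set_index("source")


def compare_dtdf_scenarios(
    consumers: pd.DataFrame,
    sources: list[DietSource],
    dtdf_variants: dict[str, list[DtdfSpec]],
    settings: McmcSettings | None = None,
    error_structure: str = "additive",
    prior_alpha=None,
) -> dict[str, MixtureEstimate]:
    """Fit the same consumers under several DTDF variants with matched seeds."""
    out: dict[str, MixtureEstimate] = {}
    for name, dtdfs in dtdf_variants.items():
        problem = MixtureProblem(
            consumers=consumers, sources=sources, dtdfs=dtdfs, prior_alpha=prior_alpha
        )
        out[name] = fit_mixing_model(
            problem, settings=settings, error_structure=error_structure
        )
    return out
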