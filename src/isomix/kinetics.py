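"""Compartmental isotope-incorporation curves and residence-time arithmetic.

After a diet switch, a tissue's isotope value relaxes from its pre-switch
value toward a new asymptote. One-compartment kinetics assume a single
first-order pool; two-compartment kinetics mix two exponential pools with
fractional sizes ``p`` and ``1 - p``. Time is measured in days and rates in
day^-1 throughout; delta values are plain per-mil floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

__all__ = [
    "CompartmentParams",
    "ResidenceTime",
    "predict",
    "predict_one_compartment",
    "predict_two_compartment",
    "residence_time",
]


@dataclass(frozen=True)
class CompartmentParams:
    """Parameters of a one- or two-compartment incorporation curve.

    Parameters
    ----------
    dX0
        Tissue delta value at the moment of the diet switch (per mil).
    dXinf
        Asymptotic (equilibrium) delta value (per mil).
    lambda1
        Fractional incorporation rate of the (first) pool, day^-1, > 0.
    lambda2
        Rate of the second pool (day^-1, > 0). ``None`` for one-compartment.
    p
        Fractional size of the first pool, in [0, 1]. ``None`` for
        one-compartment. ``p`` and ``lambda2`` must be supplied together.
    """

    dX0: float
    dXinf: float
    lambda1: float
    lambda2: float | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.dX0) or not np.isfinite(self.dXinf):
            raise ValueError("dX0 and dXinf must be finite")
        if self.lambda1 <= 0:
            raise ValueError(f"lambda1 must be > 0, got {self.lambda1}")
        if (self.lambda2 is None) != (self.p is None):
            raise ValueError("lambda2 and p must be supplied together")
        if self.lambda2 is not None and self.lambda2 <= 0:
            raise ValueError(f"lambda2 must be > 0, got {self.lambda2}")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")

    @property
    def is_two_compartment(self) -> bool:
        return self.lambda2 is not None


@dataclass(frozen=True)
class ResidenceTime:
    """Average residence time(s) of the incorporation process, in days.

    ``tau`` is 1/lambda of the (first) pool; ``tau_mean`` is the pool-size
    weighted average ``p/lambda1 + (1-p)/lambda2`` for two-compartment
    parameters, ``None`` otherwise.
    """

    tau: float
    tau_mean: float | None = None


def _as_times(t: npt.ArrayLike) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be non-negative")
    return t


def predict_one_compartment(params: CompartmentParams, t: npt.ArrayLike) -> np.ndarray:
    """Evaluate the one-compartment curve at time(s) ``t`` (days).

    Returns ``dXinf - (dXinf - dX0) * exp(-t * lambda1)``; scalar in,
    scalar array out.
    """
    if params.is_two_compartment:
        raise ValueError("params describe a two-compartment model")
    t = _as_times(t)
    return params.dXinf - (params.dXinf - params.dX0) * np.exp(-t * params.lambda1)


def predict_two_compartment(params: CompartmentParams, t: npt.ArrayLike) -> np.ndarray:
    """Evaluate the two-compartment curve at time(s) ``t`` (days).

    Returns ``dXinf - (dXinf - dX0) * (p exp(-t l1) + (1-p) exp(-t l2))``.
    """
    if not params.is_two_compartment:
        raise ValueError("params describe a one-compartment model")
    t = _as_times(t)
    decay = params.p * np.exp(-t * params.lambda1) + (1.0 - params.p) * np.exp(
        -t * params.lambda2
    )
    return params.dXinf - (params.dXinf - params.dX0) * decay


def predict(params: CompartmentParams, t: npt.ArrayLike) -> np.ndarray:
    """Dispatch to the one- or two-compartment curve based on ``params``."""
    if params.is_two_compartment:
        return predict_two_compartment(params, t)
    return predict_one_compartment(params, t)


def residence_time(params: CompartmentParams) -> ResidenceTime:
    """Average residence time tau = 1/lambda (days).

    For two-compartment parameters additionally returns the pool-weighted
    ``tau_mean = p/lambda1 + (1-p)/lambda2``.
    """
    tau = 1.0 / params.lambda1
    if not params.is_two_compartment:
        return ResidenceTime(tau=tau)
    tau_mean = params.p / params.lambda1 + (1.0 - params.p) / params.lambda2
    return ResidenceTime(tau=tau, tau_mean=tau_mean)
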