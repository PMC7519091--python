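"""Generators for every input the pipeline needs, with explicit seeds.

Two scenarios are covered: a hypothetical mixing setup of four
well-separated diet sources consumed by four specialist groups and one
generalist, and a diet-switch feeding trial (5 consumer groups x 2 tissues,
sampling days 0-120, 3 fish per group per occasion) whose trajectories
follow compartmental kinetics with homoscedastic Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dtdf import DtdfSpec, literature_dtdf
from .kinetics import CompartmentParams, predict

__all__ = [
    "DietSource",
    "ExperimentDesign",
    "default_sources",
    "hypothetical_sources",
    "default_trial_params",
    "simulate_feeding_trial",
    "simulate_mixture_scenario",
    "default_mixture_scenario",
]

DEFAULT_SCHEDULE = (0, 10, 20, 30, 40, 50, 60, 90, 120)
TISSUES = ("muscle", "fin")
ISOTOPES = ("c", "n")


@dataclass(frozen=True)
class DietSource:
    """A food source's isotope distribution: mean and sd per isotope (per mil)."""

    name: str
    mu_c: float
    sd_c: float
    mu_n: float
    sd_n: float

    def __post_init__(self) -> None:
        if self.sd_c < 0 or self.sd_n < 0:
            raise ValueError("source standard deviations must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling schedule and noise structure of a diet-switch trial."""

    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    n_per_occasion: int = 3
    noise_sd_c: float = 0.3
    noise_sd_n: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        sched = tuple(self.schedule)
        if not sched or sched[0] != 0:
            raise ValueError("schedule must start at day 0")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must be strictly increasing")
        if self.n_per_occasion < 1:
            raise ValueError("n_per_occasion must be >= 1")
        if self.noise_sd_c < 0 or self.noise_sd_n < 0:
            raise ValueError("noise sds must be >= 0")
        object.__setattr__(self, "schedule", sched)


def default_sources() -> list[DietSource]:
    """The five formulated experimental diets (mean +/- sd per isotope)."""
    return [
        DietSource("1", -14.7, 0.01, 9.9, 0.26),
        DietSource("2", -23.5, 0.02, 10.8, 0.06),
        DietSource("3", -22.9, 0.06, 1.4, 0.52),
        DietSource("4", -26.8, 0.08, 0.8, 0.03),
        DietSource("5", -21.9, 0.76, 4.5, 0.83),
    ]


def hypothetical_sources() -> list[DietSource]:
    """Four synthetic sources on a well-separated quadrilateral.

    Pairwise Euclidean separation in (d13C, d15N) space exceeds 12 per mil,
    which keeps the mixing problem identifiable for specialist consumers.
    These are illustrative defaults, not measured values.
    """
    return [
        DietSource("1", -12.0, 0.5, 12.0, 0.5),
        DietSource("2", -26.0, 0.5, 14.0, 0.5),
        DietSource("3", -20.0, 0.5, 0.0, 0.5),
        DietSource("4", -32.0, 0.5, 2.0, 0.5),
    ]


def default_trial_params() -> dict[tuple[int, str, str], CompartmentParams]:
    """One-compartment generating values for the default synthetic trial.

    Keyed by (group, tissue, isotope). Groups 1-4 use equilibrium values
    and rates characteristic of the feeding trial; group 5 (the mixed diet)
    uses intermediate values.
    """
    raw = {
        # (group, tissue, isotope): (dX0, dXinf, lambda)
        (1, "muscle", "c"): (-22.83, -19.23, 0.20),
        (2, "muscle", "c"): (-22.81, -20.07, 0.37),
        (3, "muscle", "c"): (-22.78, -20.14, 0.27),
        (4, "muscle", "c"): (-22.82, -21.36, 0.23),
        (1, "fin", "c"): (-21.20, -17.95, 0.03),
        (2, "fin", "c"): (-21.35, -18.48, 0.03),
        (3, "fin", "c"): (-21.78, -18.51, 0.04),
        (4, "fin", "c"): (-21.52, -22.88, 0.01),
        (1, "muscle", "n"): (8.71, 10.41, 0.05),
        (2, "muscle", "n"): (8.67, 10.65, 0.07),
        (3, "muscle", "n"): (9.04, 8.95, 0.59),
        (4, "muscle", "n"): (9.04, 8.51, 0.52),
        (1, "fin", "n"): (8.72, 11.42, 0.05),
        (2, "fin", "n"): (8.80, 11.48, 0.06),
        (3, "fin", "n"): (9.35, 7.12, 0.02),
        (4, "fin", "n"): (9.17, 6.38, 0.02),
        # group 5: mixed diet, intermediate equilibria (synthetic defaults)
        (5, "muscle", "c"): (-22.80, -20.50, 0.25),
        (5, "fin", "c"): (-21.45, -19.20, 0.03),
        (5, "muscle", "n"): (8.90, 9.60, 0.10),
        (5, "fin", "n"): (9.00, 9.20, 0.04),
    }
    return {
        key: CompartmentParams(dX0=v[0], dXinf=v[1], lambda1=v[2])
        for key, v in raw.items()
    }


def simulate_feeding_trial(
    true_params: dict[tuple[int, str, str], CompartmentParams],
    design: ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Simulate a diet-switch trial from known kinetics.

    ``true_params`` must provide a CompartmentParams for both isotopes of
    every (group, tissue) pair it mentions. Each scheduled day yields
    ``design.n_per_occasion`` fish per group, measured for both tissues;
    values are the kinetic prediction plus N(0, noise_sd) error. Output is
    a tidy frame with columns group, tissue, day, fish_id, d13c, d15n.
    """
    design = design or ExperimentDesign()
    group_tissues = sorted({(g, tis) for g, tis, _ in true_params})
    for g, tis in group_tissues:
        for iso in ISOTOPES:
            if (g, tis, iso) not in true_params:
                raise ValueError(f"missing CompartmentParams for {(g, tis, iso)}")

    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    for group, tissue in group_tissues:
        par_c = true_params[(group, tissue, "c")]
        par_n = true_params[(group, tissue, "n")]
        for day in design.schedule:
            mu_c = float(predict(par_c, day))
            mu_n = float(predict(par_n, day))
            for rep in range(1, design.n_per_occasion + 1):
                rows.append(
                    {
                        "group": group,
                        "tissue": tissue,
                        "day": int(day),
                        "fish_id": f"g{group}_d{day}_f{rep}",
                        "d13c": mu_c + design.noise_sd_c * rng.standard_normal(),
                        "d15n": mu_n + design.noise_sd_n * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


def _check_simplex(p: np.ndarray) -> None:
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must lie on the simplex, got {p}")


def simulate_mixture_scenario(
    sources: list[DietSource],
    dtdfs: list[DtdfSpec],
    proportions: dict[int, np.ndarray] | list,
    n_consumers: int = 30,
    consumer_sd: float = 0.5,
    seed: int = 0,
    tissue: str = "muscle",
) -> pd.DataFrame:
    """Draw consumer groups around mixture means ``sum_k p_k (mu_k + Delta_k)``.

    ``proportions`` maps each consumer-group label to a simplex vector over
    the sources; every group gets ``n_consumers`` iid bivariate-normal
    consumers with sd ``consumer_sd`` per isotope.
    """
    if len(dtdfs) != len(sources):
        raise ValueError("need one DtdfSpec per source")
    if consumer_sd < 0:
        raise ValueError("consumer_sd must be >= 0")
    if isinstance(proportions, dict):
        prop_items = sorted(proportions.items())
    else:
        prop_items = list(enumerate(proportions, start=1))

    mu = np.array([[s.mu_c, s.mu_n] for s in sources])
    delta = np.array([[d.delta_c, d.delta_n] for d in dtdfs])

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for group, p in prop_items:
        p = np.asarray(p, dtype=float)
        if p.size != len(sources):
            raise ValueError("proportion vector length must match source count")
        _check_simplex(p)
        mean = p @ (mu + delta)
        vals = mean + consumer_sd * rng.standard_normal((n_consumers, 2))
        for i in range(n_consumers):
            rows.append(
                {
                    "group": group,
                    "tissue": tissue,
                    "day": 0,
                    "fish_id": f"g{group}_c{i + 1}",
                    "d13c": vals[i, 0],
                    "d15n": vals[i, 1],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MixtureScenario:
    """A simulated mixing scenario plus the ground truth that built it."""

    consumers: pd.DataFrame
    sources: list[DietSource]
    dtdfs: list[DtdfSpec]
    true_proportions: dict[int, np.ndarray] = field(repr=False)


def default_mixture_scenario(
    seed: int = 0, n_consumers: int = 30, consumer_sd: float = 0.5
) -> MixtureScenario:
    """Four specialist groups (unit-vector diets) and one generalist (1/4 each),
    built on the hypothetical sources with literature discrimination."""
    sources = hypothetical_sources()
    dtdfs = [literature_dtdf(s.name) for s in sources]
    k = len(sources)
    props = {g: np.eye(k)[g - 1] for g in range(1, k + 1)}
    props[k + 1] = np.full(k, 1.0 / k)
    consumers = simulate_mixture_scenario(
        sources, dtdfs, props, n_consumers=n_consumers, consumer_sd=consumer_sd, seed=seed
    )
    return MixtureScenario(
        consumers=consumers, sources=sources, dtdfs=dtdfs, true_proportions=props
    )
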