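"""Scenario and run configuration.

A :class:`ScenarioConfig` pins down one simulation condition: the input-variable
model (all-categorical or mixed categorical/continuous), the outcome-prevalence
tier (which sets the log-risk intercept), the sample size, the number of
replicate iterations, and a master seed from which every iteration derives its
own child seed deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class InputType(str, Enum):
    """Input-variable model: all-categorical, or mixed with continuous X1/X6."""

    CATEGORICAL = "categorical"
    MIXED = "mixed"


class PrevalenceTier(str, Enum):
    """Outcome prevalence tier; fixes the intercept of the generating model."""

    RARE = "rare"      # intercept -3, baseline risk exp(-3) ~ 5%
    COMMON = "common"  # intercept -1.5, baseline risk exp(-1.5) ~ 22%
    HALF = "half"      # sensitivity tier, all-null prevalence 0.5


#: Log-risk intercept per tier.  The half tier is log(0.5) so that an
#: all-null coefficient draw yields exactly 50% prevalence.
INTERCEPTS: dict[PrevalenceTier, float] = {
    PrevalenceTier.RARE: -3.0,
    PrevalenceTier.COMMON: -1.5,
    PrevalenceTier.HALF: float(np.log(0.5)),
}

#: Relative-risk truncation windows (protective window, harmful window) per
#: tier.  Effects are sampled from a normal centred at RR=1 (SD 0.30) and
#: accepted only inside one of the two windows, which excludes near-null
#: effects.  The half tier reuses the common-tier windows.
RR_WINDOWS: dict[PrevalenceTier, tuple[tuple[float, float], tuple[float, float]]] = {
    PrevalenceTier.RARE: ((0.20, 0.76), (1.24, 1.80)),
    PrevalenceTier.COMMON: ((0.20, 0.89), (1.11, 1.80)),
    PrevalenceTier.HALF: ((0.20, 0.89), (1.11, 1.80)),
}

#: Effect-size distribution on the relative-risk scale.
RR_MEAN = 1.0
RR_SD = 0.30

#: Number of distinct intersections in the simulation design: 4*2*2*2*2*3.
N_INTERSECTIONS = 192

#: Category counts of x1..x6 used to form intersections.
INTERSECTION_LEVELS = (4, 2, 2, 2, 2, 3)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    Parameters
    ----------
    input_type
        ``categorical`` or ``mixed``.
    prevalence_tier
        ``rare``, ``common`` or ``half`` (the 50% sensitivity tier).
    n_individuals
        Sample size N of each generated dataset.
    n_iterations
        Number of replicate iterations of the scenario.
    master_seed
        Seed of the whole scenario; iteration ``k`` uses the child sequence
        ``SeedSequence(master_seed, spawn_key=(k,))`` so any single iteration
        is reproducible in isolation.
    interaction_boost
        Sensitivity variant: interaction coefficients are sampled only from
        the harmful (larger-effect) window.
    """

    input_type: InputType = InputType.CATEGORICAL
    prevalence_tier: PrevalenceTier = PrevalenceTier.RARE
    n_individuals: int = 2000
    n_iterations: int = 1
    master_seed: int = 0
    interaction_boost: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_type", InputType(self.input_type))
        object.__setattr__(self, "prevalence_tier", PrevalenceTier(self.prevalence_tier))
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def intercept(self) -> float:
        return INTERCEPTS[self.prevalence_tier]

    @property
    def rr_windows(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return RR_WINDOWS[self.prevalence_tier]

    def iteration_seed(self, iteration: int) -> np.random.SeedSequence:
        """Deterministic child seed sequence for one iteration."""
        return np.random.SeedSequence(self.master_seed, spawn_key=(iteration,))

    def iteration_rng(self, iteration: int) -> np.random.Generator:
        return np.random.default_rng(self.iteration_seed(iteration))

    def label(self) -> str:
        boost = "+boost" if self.interaction_boost else ""
        return (
            f"{self.prevalence_tier.value}/{self.input_type.value}{boost}"
            f"/N={self.n_individuals}"
        )


@dataclass
class RunConfig:
    """Configuration of a full experiment grid.

    ``methods`` names estimators from the registry in
    :mod:`intersectprev.runner`.  Results are invariant to ``n_jobs`` because
    every iteration derives its own seed from the scenario master seed.
    """

    scenarios: list[ScenarioConfig] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: ["cross_classification"])
    output_dir: str | None = None
    n_jobs: int = 1
    rf_n_trees: int = 500
    rf_n_permutations: int = 0  # permutation-VIM p-values disabled unless > 0

    def __post_init__(self) -> None:
        from .runner import METHOD_NAMES  # local import to avoid cycle

        unknown = [m for m in self.methods if m not in METHOD_NAMES]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}; choose from {sorted(METHOD_NAMES)}")
        for sc in self.scenarios:
            if "chaid" in self.methods and sc.input_type is InputType.MIXED:
                raise ValueError(
                    "CHAID is chi-square based and applies only to categorical "
                    f"inputs; scenario {sc.label()} has mixed inputs"
                )
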