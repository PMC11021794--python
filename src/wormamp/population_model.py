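"""Deterministic birth-death model linking single-cell effects to bulk counts.

A well-mixed population whose cells elongate/divide at net per-capita rate
``alpha`` and lyse at rate ``lambda`` grows as ``N(t) = N0 exp((alpha -
lambda) t)``.  The treated-to-control ratio after an exposure of duration T
is therefore

    ratio = exp(((alpha_t - lambda_t) - (alpha_c - lambda_c)) * T)

which converts single-cell growth inhibition and lysis rates, measured in
the mother machine, into a predicted bulk CFU fold-change — and can be
inverted to ask how much growth inhibition (or lysis) a given bulk reduction
requires.  Balanced growth is assumed: the single-cell elongation rate is
used as the population's net per-capita growth rate (tested against the
agent-based simulator in :mod:`wormamp.trench_sim`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PopulationParams", "predict_ratio", "reduction_percent",
           "required_inhibition", "required_lysis_rate"]


@dataclass(frozen=True)
class PopulationParams:
    """Net growth and lysis rates (1/min) for control and treated arms.

    ``duration_min`` defaults to the bulk assay's 210 min incubation.
    """

    alpha_control: float
    alpha_treated: float
    lambda_control: float = 0.0
    lambda_treated: float = 0.0
    duration_min: float = 210.0
    n0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_control", "alpha_treated",
                     "lambda_control", "lambda_treated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")


def predict_ratio(p: PopulationParams) -> float:
    """Treated/control population ratio after ``duration_min``."""
    net_t = p.alpha_treated - p.lambda_treated
    net_c = p.alpha_control - p.lambda_control
    return math.exp((net_t - net_c) * p.duration_min)


def reduction_percent(ratio: float) -> float:
    """Percent reduction, ``100 * (1 - ratio)``; 0 for identical arms."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    return 100.0 * (1.0 - ratio)


def required_inhibition(target_reduction_percent: float, alpha_control: float,
                        lambda_control: float = 0.0, lambda_treated: float = 0.0,
                        duration_min: float = 210.0) -> float:
    """Growth-inhibition fraction needed for a target bulk reduction.

    Inverts :func:`predict_ratio` for ``alpha_treated`` and returns
    ``1 - alpha_treated / alpha_control``.  Raises if the target cannot be
    met by growth inhibition alone (would need ``alpha_treated < 0``).
    """
    if not 0 <= target_reduction_percent < 100:
        raise ValueError("target reduction must be in [0, 100)")
    if alpha_control <= 0:
        raise ValueError("alpha_control must be positive")
    ratio = 1.0 - target_reduction_percent / 100.0
    alpha_t = (math.log(ratio) / duration_min
               + alpha_control - lambda_control + lambda_treated)
    if alpha_t < 0:
        raise ValueError(
            "infeasible: target reduction requires negative treated growth "
            "rate; growth inhibition alone cannot achieve it")
    return 1.0 - alpha_t / alpha_control


def required_lysis_rate(target_reduction_percent: float,
                        duration_min: float = 210.0) -> float:
    """Extra lysis rate (1/min, over control) needed for a target reduction
    with no growth inhibition: ``-ln(1 - target/100) / duration``."""
    if not 0 <= target_reduction_percent < 100:
        raise ValueError("target reduction must be in [0, 100)")
    return -math.log(1.0 - target_reduction_percent / 100.0) / duration_min
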