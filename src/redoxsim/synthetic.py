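"""Synthetic fixtures: toy networks with closed-form behaviour, log-normal
parameter perturbations, and dose grids.

These generators make every pipeline stage testable without the full
pathway parameterisation: the toy networks have analytic trajectories or
steady states, the perturbations emulate the parameter uncertainty inherent
to kinetic constants assembled from heterogeneous experimental sources, and
the dose grids stand in for tabulated dosing schedules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    constant_flux,
    mass_action,
)

__all__ = ["PerturbationSpec", "make_toy_network", "perturb_parameters",
           "make_dose_grid", "TOY_KINDS"]

TOY_KINDS = ("decay", "synthesis_decay", "oscillator", "scavenger_chain")


@dataclass
class PerturbationSpec:
    """Log-normal, median-1 multiplicative parameter noise."""

    coefficient_of_variation: float = 0.2
    distribution: str = "lognormal"
    seed: int = 0
    constants_subset: list[str] | None = None

    def __post_init__(self) -> None:
        if self.coefficient_of_variation <= 0:
            raise ValueError("coefficient_of_variation must be positive")
        if self.distribution != "lognormal":
            raise ValueError("only lognormal perturbations are supported")


def make_toy_network(kind: str, **params: float) -> ReactionNetwork:
    """Small networks with documented closed-form behaviour.

    decay:            A -> 0 at k_d;            A(t) = A0 exp(-k_d t)
    synthesis_decay:  0 -> A at k_s, A -> 0;    steady state k_s / k_d
    oscillator:       Lotka–Volterra prey/predator pair on a clamped
                      substrate; sustained oscillations (never steady)
    scavenger_chain:  0 -> X at k_src, X -> 0 at k_clear, X + S -> sink with
                      clamped scavenger S; steady state
                      k_src / (k_clear + k_scav·[S])
    """
    if kind == "decay":
        k_d = params.get("k_d", 1e-3)
        a0 = params.get("a0", 100.0)
        return ReactionNetwork("toy_decay",
                               [Species("A", initial_concentration=a0)],
                               [Reaction("decay", reactants=[("A", 1)],
                                         rate_law=mass_action(k_d))])
    if kind == "synthesis_decay":
        k_s = params.get("k_s", 4.2e-4)
        k_d = params.get("k_d", 1e-5)
        a0 = params.get("a0", 0.0)
        return ReactionNetwork(
            "toy_synthesis_decay",
            [Species("A", initial_concentration=a0)],
            [Reaction("synthesis", products=[("A", 1)], rate_law=constant_flux(k_s)),
             Reaction("decay", reactants=[("A", 1)], rate_law=mass_action(k_d))])
    if kind == "oscillator":
        k1 = params.get("k1", 2e-3)
        k2 = params.get("k2", 1e-3)
        k3 = params.get("k3", 2e-3)
        return ReactionNetwork(
            "toy_oscillator",
            [Species("F", "food", 1.0, constant=True),
             Species("X", "prey", 1.5),
             Species("Y", "predator", 1.0)],
            [Reaction("growth", reactants=[("F", 1), ("X", 1)],
                      products=[("F", 1), ("X", 2)], rate_law=mass_action(k1)),
             Reaction("predation", reactants=[("X", 1), ("Y", 1)],
                      products=[("Y", 2)], rate_law=mass_action(k2)),
             Reaction("death", reactants=[("Y", 1)], rate_law=mass_action(k3))])
    if kind == "scavenger_chain":
        k_src = params.get("k_src", 1e-2)
        k_clear = params.get("k_clear", 1e-3)
        k_scav = params.get("k_scav", 1e-4)
        s0 = params.get("scavenger", 10.0)
        return ReactionNetwork(
            "toy_scavenger_chain",
            [Species("X", initial_concentration=0.0),
             Species("S", "scavenger", s0, constant=True),
             Species("XS", "scavenged", 0.0, sink=True)],
            [Reaction("source", products=[("X", 1)], rate_law=constant_flux(k_src)),
             Reaction("clearance", reactants=[("X", 1)], rate_law=mass_action(k_clear)),
             Reaction("scavenging", reactants=[("X", 1), ("S", 1)],
                      products=[("XS", 1)], rate_law=mass_action(k_scav))])
    raise ValueError(f"unknown toy network kind {kind!r}")


def perturb_parameters(params: ParameterSet | dict,
                       spec: PerturbationSpec) -> ParameterSet:
    """Multiply selected constants by independent median-1 log-normal factors.

    sigma = sqrt(log(1 + cv^2)) so the factors have the requested
    coefficient of variation; the median stays 1, keeping perturbations
    unbiased on the log scale.  Reproducible under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.coefficient_of_variation ** 2))
    subset = set(spec.constants_subset) if spec.constants_subset else None
    out = ParameterSet(params, getattr(params, "units", None))
    for name in sorted(out):
        factor = float(rng.lognormal(mean=0.0, sigma=sigma))
        if subset is None or name in subset:
            out[name] = out[name] * factor
    return out


def make_dose_grid(max_dose: float, n_points: int,
                   spacing: str = "linear") -> np.ndarray:
    """Sorted dose grid including 0 and max_dose.

    Log spacing places the nonzero points at equal ratios spanning two
    decades below the maximum.
    """
    if max_dose <= 0:
        raise ValueError("max_dose must be positive")
    if n_points < 2:
        raise ValueError("need at least two dose points")
    if spacing == "linear":
        return np.linspace(0.0, max_dose, n_points)
    if spacing == "log":
        nonzero = np.geomspace(max_dose / 100.0, max_dose, n_points - 1)
        return np.concatenate([[0.0], nonzero])
    raise ValueError(f"unknown spacing {spacing!r}")
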