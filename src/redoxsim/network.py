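"""Reaction networks: species, rate laws, stoichiometry and ODE assembly.

A :class:`ReactionNetwork` is the executable form of a pathway model: an
ordered set of species (concentrations in nM) and reactions whose rate laws
are drawn from a small, closed vocabulary — mass action, Michaelis–Menten,
Hill and constant flux.  The module builds the integer stoichiometry matrix,
assembles the governing ODE right-hand side (dc/dt = S · v(c), in nM/s), and
computes conserved moieties as the left null space of the stoichiometry
matrix restricted to dynamic species.

Units are nM for concentrations and seconds for time throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy

__all__ = [
    "Species",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "ParameterSet",
    "mass_action",
    "michaelis_menten",
    "hill",
    "constant_flux",
    "evaluate_rate",
    "stoichiometry_matrix",
    "flux_vector",
    "assemble_rhs",
    "conserved_moieties",
    "validate_network",
    "NetworkConfigError",
]

RATE_LAW_FORMS = ("mass_action", "michaelis_menten", "hill", "constant_flux")


class NetworkConfigError(ValueError):
    """Raised for structural problems: unknown species, missing constants."""


class ParameterSet(dict):
    """Named kinetic constants / initial concentrations.

    A thin dict subclass (name -> value) with an optional ``units`` mapping,
    kept separate so perturbation and calibration can treat parameter sets
    as plain mappings.
    """

    def __init__(self, values: Mapping[str, float] | None = None,
                 units: Mapping[str, str] | None = None):
        super().__init__(values or {})
        self.units = dict(units or {})

    def copy(self) -> "ParameterSet":
        return ParameterSet(self, self.units)


@dataclass
class Species:
    """A chemical species.

    ``constant`` marks clamped pools (bulk H2O, dissolved O2, a compound held
    at its serum level): their stoichiometry row is zeroed.  ``sink`` marks
    pure bookkeeping accumulators (scavenged-mass pools, termination
    products); they integrate normally but are exempt from steady-state
    detection since they grow without bound by design.
    """

    id: str
    display_name: str = ""
    initial_concentration: float = 0.0
    constant: bool = False
    sink: bool = False

    def __post_init__(self) -> None:
        if not self.display_name:
            self.display_name = self.id


@dataclass
class RateLaw:
    """A typed rate law.

    form            one of mass_action | michaelis_menten | hill | constant_flux
    parameters      named non-negative constants:
                      mass_action: k (nM^(1-n)/s for total order n)
                      michaelis_menten: Vmax (nM/s), Km (nM)
                      hill: Vmax, Km, hill_n
                      constant_flux: k (nM/s)
    species_orders  mass action only: [(species_id, exponent), ...] defining
                    the concentration product; filled from reactant
                    stoichiometry (+ first-order modifiers) if omitted.
    substrate       Michaelis–Menten / Hill only: the saturating species.
    """

    form: str
    parameters: dict[str, float] = field(default_factory=dict)
    species_orders: list[tuple[str, float]] | None = None
    substrate: str | None = None

    def referenced_species(self) -> list[str]:
        if self.form == "mass_action":
            return [s for s, _ in (self.species_orders or [])]
        if self.form in ("michaelis_menten", "hill"):
            return [self.substrate] if self.substrate else []
        return []


def mass_action(k: float, orders: Sequence[tuple[str, float]] | None = None) -> RateLaw:
    return RateLaw("mass_action", {"k": float(k)},
                   species_orders=list(orders) if orders is not None else None)


def michaelis_menten(vmax: float, km: float, substrate: str) -> RateLaw:
    return RateLaw("michaelis_menten", {"Vmax": float(vmax), "Km": float(km)},
                   substrate=substrate)


def hill(vmax: float, km: float, n: float, substrate: str) -> RateLaw:
    return RateLaw("hill", {"Vmax": float(vmax), "Km": float(km), "hill_n": float(n)},
                   substrate=substrate)


def constant_flux(k: float) -> RateLaw:
    return RateLaw("constant_flux", {"k": float(k)})


@dataclass
class Reaction:
    """reactants/products are [(species_id, stoichiometric coefficient >= 1)]."""

    id: str
    reactants: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    rate_law: RateLaw = field(default_factory=lambda: constant_flux(0.0))

    def resolved_rate_law(self) -> RateLaw:
        """Rate law with mass-action orders defaulted from the reaction."""
        law = self.rate_law
        if law.form == "mass_action" and law.species_orders is None:
            orders = [(s, c) for s, c in self.reactants]
            orders += [(m, 1.0) for m in self.modifiers]
            return replace(law, species_orders=orders)
        return law


@dataclass
class ReactionNetwork:
    name: str
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)

    def initial_state_map(self) -> dict[str, float]:
        return {s.id: s.initial_concentration for s in self.species}

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            name=self.name,
            species=[replace(s) for s in self.species],
            reactions=[
                Reaction(
                    id=r.id,
                    reactants=list(r.reactants),
                    products=list(r.products),
                    modifiers=list(r.modifiers),
                    rate_law=replace(
                        r.rate_law,
                        parameters=dict(r.rate_law.parameters),
                        species_orders=(None if r.rate_law.species_orders is None
                                        else list(r.rate_law.species_orders)),
                    ),
                )
                for r in self.reactions
            ],
        )


def evaluate_rate(rate_law: RateLaw, concentrations: Mapping[str, float]) -> float:
    """Evaluate one rate law at a concentration map; returns flux in nM/s.

    Raises NetworkConfigError for a missing species and ValueError for a
    negative concentration.
    """
    for sid in rate_law.referenced_species():
        if sid not in concentrations:
            raise NetworkConfigError(f"rate law references unknown species {sid!r}")
        if concentrations[sid] < 0:
            raise ValueError(f"negative concentration for {sid!r}")

    p = rate_law.parameters
    if rate_law.form == "constant_flux":
        return p["k"]
    if rate_law.form == "mass_action":
        rate = p["k"]
        for sid, order in rate_law.species_orders or []:
            rate *= concentrations[sid] ** order
        return rate
    s = concentrations[rate_law.substrate]
    if rate_law.form == "michaelis_menten":
        return p["Vmax"] * s / (p["Km"] + s)
    if rate_law.form == "hill":
        n = p["hill_n"]
        sn = s ** n
        return p["Vmax"] * sn / (p["Km"] ** n + sn)
    raise NetworkConfigError(f"unknown rate-law form {rate_law.form!r}")


def stoichiometry_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer net-production matrix (n_species x n_reactions).

    Rows of constant (clamped) species are identically zero.
    """
    idx = network.species_index()
    S = np.zeros((len(network.species), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for sid, coef in rxn.reactants:
            S[idx[sid], j] -= coef
        for sid, coef in rxn.products:
            S[idx[sid], j] += coef
    for i, sp in enumerate(network.species):
        if sp.constant:
            S[i, :] = 0.0
    return S


def _compile_rates(network: ReactionNetwork) -> Callable[[np.ndarray], np.ndarray]:
    """Closure computing the flux vector from a state array (fast path)."""
    idx = network.species_index()
    evaluators: list[Callable[[np.ndarray], float]] = []
    for rxn in network.reactions:
        law = rxn.resolved_rate_law()
        p = law.parameters
        if law.form == "constant_flux":
            k = p["k"]
            evaluators.append(lambda y, k=k: k)
        elif law.form == "mass_action":
            k = p["k"]
            terms = [(idx[s], o) for s, o in law.species_orders or []]
            def ev(y, k=k, terms=terms):
                r = k
                for i, o in terms:
                    ci = y[i]
                    if ci < 0.0:
                        ci = 0.0
                    r *= ci if o == 1.0 else ci ** o
                return r
            evaluators.append(ev)
        elif law.form == "michaelis_menten":
            vmax, km, i = p["Vmax"], p["Km"], idx[law.substrate]
            def ev(y, vmax=vmax, km=km, i=i):
                s = y[i] if y[i] > 0.0 else 0.0
                return vmax * s / (km + s)
            evaluators.append(ev)
        elif law.form == "hill":
            vmax, km, n, i = p["Vmax"], p["Km"], p["hill_n"], idx[law.substrate]
            def ev(y, vmax=vmax, km=km, n=n, i=i):
                s = y[i] if y[i] > 0.0 else 0.0
                sn = s ** n
                return vmax * sn / (km ** n + sn)
            evaluators.append(ev)
        else:  # pragma: no cover - guarded by validate_network
            raise NetworkConfigError(f"unknown rate-law form {law.form!r}")

    def fluxes(y: np.ndarray) -> np.ndarray:
        return np.array([ev(y) for ev in evaluators])

    return fluxes


def flux_vector(network: ReactionNetwork, state: Mapping[str, float] | np.ndarray) -> np.ndarray:
    """Flux of every reaction (nM/s) at the given state."""
    if isinstance(state, Mapping):
        y = np.array([state[s.id] for s in network.species], float)
    else:
        y = np.asarray(state, float)
    return _compile_rates(network)(y)


def assemble_rhs(network: ReactionNetwork) -> Callable[[np.ndarray, float], np.ndarray]:
    """Return f(state, t) -> dc/dt = S · v(c), with constant-species rows zero.

    Negative entries of the state (solver round-off) are treated as zero when
    evaluating rates, which keeps the assembled system non-negativity
    preserving at solver tolerances.
    """
    findings = validate_network(network)
    if findings:
        raise NetworkConfigError("invalid network: " + "; ".join(findings))
    S = stoichiometry_matrix(network)
    fluxes = _compile_rates(network)
    n = len(network.species)

    def rhs(state: np.ndarray, t: float = 0.0) -> np.ndarray:
        y = np.asarray(state, float)
        if y.shape != (n,):
            raise ValueError(f"state vector length {y.shape} != {n} species")
        return S @ fluxes(y)

    return rhs


def conserved_moieties(network: ReactionNetwork) -> list[np.ndarray]:
    """Integer basis of the left null space of S over dynamic species.

    Each returned vector v (length n_species, zero on constant species)
    satisfies v^T S = 0, so v^T c(t) is constant along exact trajectories.
    Computed exactly over the rationals with sympy and scaled to integers.
    """
    dynamic = [i for i, s in enumerate(network.species) if not s.constant]
    if not dynamic:
        return []
    S = stoichiometry_matrix(network)[dynamic, :]
    M = sympy.Matrix(S.astype(int)) if np.allclose(S, np.round(S)) else sympy.Matrix(S)
    basis = M.T.nullspace()
    out = []
    for v in basis:
        denoms = [sympy.fraction(sympy.nsimplify(x))[1] for x in v]
        scale = sympy.ilcm(*[int(d) for d in denoms]) if denoms else 1
        vec = np.zeros(len(network.species))
        for row, i in enumerate(dynamic):
            vec[i] = float(v[row] * scale)
        out.append(vec)
    return out


def validate_network(network: ReactionNetwork) -> list[str]:
    """Structural findings; an empty list means the network is simulable."""
    findings: list[str] = []
    ids = [s.id for s in network.species]
    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            findings.append(f"duplicate species id {sid!r}")
        seen.add(sid)
    rids: set[str] = set()
    for rxn in network.reactions:
        if rxn.id in rids:
            findings.append(f"duplicate reaction id {rxn.id!r}")
        rids.add(rxn.id)
    for sp in network.species:
        if sp.initial_concentration < 0:
            findings.append(
                f"species {sp.id!r} has negative initial concentration "
                f"{sp.initial_concentration}")
    known = set(ids)
    for rxn in network.reactions:
        law = rxn.resolved_rate_law()
        for sid, _ in rxn.reactants + rxn.products:
            if sid not in known:
                findings.append(f"reaction {rxn.id!r} references unknown species {sid!r}")
        for sid in rxn.modifiers + law.referenced_species():
            if sid not in known:
                findings.append(f"reaction {rxn.id!r} references unknown species {sid!r}")
        if not rxn.reactants and law.form != "constant_flux":
            findings.append(
                f"reaction {rxn.id!r} has no reactants and is not a constant-flux source")
        if law.form not in RATE_LAW_FORMS:
            findings.append(f"reaction {rxn.id!r} has unknown rate-law form {law.form!r}")
        for name, val in law.parameters.items():
            if not math.isfinite(val) or val < 0:
                findings.append(f"reaction {rxn.id!r} parameter {name}={val} invalid")
        if law.form in ("michaelis_menten", "hill") and law.parameters.get("Km", 1.0) <= 0:
            findings.append(f"reaction {rxn.id!r} requires Km > 0")
        if law.form == "hill" and law.parameters.get("hill_n", 1.0) < 1:
            findings.append(f"reaction {rxn.id!r} requires hill_n >= 1")
    return findings
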