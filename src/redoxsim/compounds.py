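"""Phytonutrient mechanisms, dose-to-serum mapping, network perturbation.

Six compounds (cyanidin, delphinidin, ellagic acid, kaempferol, malvidin,
rutin) act on the two pathway models.  All six scavenge superoxide via a
second-order reaction with the compound clamped at its serum level for the
whole simulation (constant administration).  Five additionally engage the
Nrf2 axis, each through a saturating (Emax-style) factor in serum
concentration s, f(s) = 1 + a·s/(b + s):

* nrf2_activation (delphinidin, malvidin) and p21_upregulation (rutin,
  lumped into the same factor since p21 is not a state variable): the
  nuclear-import rate is multiplied by f(s);
* keap1_downregulation (ellagic acid): the Keap1 pool is divided by f(s);
* nrf2_degradation_inhibition (kaempferol): the Keap1-routed Nrf2
  degradation rate is divided by f(s).

Saturating laws keep every perturbation finite at high dose, which is what
produces the reported high-dose response plateau of ellagic acid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .network import (
    NetworkConfigError,
    Reaction,
    ReactionNetwork,
    Species,
    mass_action,
)

__all__ = [
    "COMPOUND_NAMES",
    "NRF2_AXIS_TARGETS",
    "CompoundMechanism",
    "DoseSpec",
    "load_compound_registry",
    "dose_to_serum",
    "apply_compound",
    "apply_combination",
    "nrf2_axis_scalings",
    "saturating_factor",
]

COMPOUND_NAMES = ("cyanidin", "delphinidin", "ellagic_acid", "kaempferol",
                  "malvidin", "rutin")
ALL_TARGETS = ("ros_scavenging", "nrf2_activation", "keap1_downregulation",
               "nrf2_degradation_inhibition", "p21_upregulation")
NRF2_AXIS_TARGETS = ALL_TARGETS[1:]

#: species the scavenging reaction consumes (the ROS readout pool)
ROS_POOL_ID = "O2m"


@dataclass
class CompoundMechanism:
    """A compound's pathway targets and potency constants.

    effect_constants keys: ``scavenging_k`` (nM^-1 s^-1), ``nrf2_effect``
    (dimensionless Emax a), ``nrf2_ec50`` (nM serum, the b of the factor).
    """

    compound: str
    targets: tuple[str, ...]
    effect_constants: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compound not in COMPOUND_NAMES:
            raise NetworkConfigError(f"unknown compound {self.compound!r}")
        unknown = set(self.targets) - set(ALL_TARGETS)
        if unknown:
            raise NetworkConfigError(f"unknown targets {sorted(unknown)}")
        if "ros_scavenging" not in self.targets:
            raise NetworkConfigError(
                f"{self.compound}: every compound scavenges ROS")
        axis = set(self.targets) & set(NRF2_AXIS_TARGETS)
        if self.compound == "cyanidin" and axis:
            raise NetworkConfigError(
                "cyanidin acts on ROS scavenging only")
        if self.compound != "cyanidin" and not axis:
            raise NetworkConfigError(
                f"{self.compound}: expected an Nrf2-axis target")


@dataclass
class DoseSpec:
    """Dietary dose (µM) -> peak-serum concentration (nM) via Cmax scaling."""

    compound: str
    dietary_dose: float
    cmax: float
    reference_dose: float
    saturation: float | None = None  # optional serum cap, nM

    @property
    def serum_level(self) -> float:
        return dose_to_serum(self)


def dose_to_serum(spec: DoseSpec) -> float:
    """Serum level = (dose / reference dose) · Cmax, optionally capped."""
    if spec.dietary_dose < 0:
        raise ValueError("dietary dose must be non-negative")
    if spec.cmax <= 0 or spec.reference_dose <= 0:
        raise ValueError("cmax and reference_dose must be positive")
    serum = spec.dietary_dose / spec.reference_dose * spec.cmax
    if spec.saturation is not None:
        serum = min(serum, spec.saturation)
    return serum


@dataclass
class CompoundRecord:
    mechanism: CompoundMechanism
    cmax: float
    reference_dose: float
    max_dose: float

    def dose_spec(self, dose: float) -> DoseSpec:
        return DoseSpec(self.mechanism.compound, dose, self.cmax,
                        self.reference_dose)

    def max_serum(self) -> float:
        return dose_to_serum(self.dose_spec(self.max_dose))


def load_compound_registry(overrides: Mapping[str, Mapping] | None = None,
                           ) -> dict[str, CompoundRecord]:
    """Shipped compound definitions, optionally overridden per compound."""
    raw = yaml.safe_load(
        resources.files("redoxsim.data").joinpath("compounds.yaml").read_text())
    registry: dict[str, CompoundRecord] = {}
    for name, rec in raw["compounds"].items():
        rec = dict(rec)
        rec.update((overrides or {}).get(name, {}))
        constants = {}
        if "scavenging_k" in rec:
            constants["scavenging_k"] = float(rec["scavenging_k"])
        if "nrf2_effect" in rec:
            constants["nrf2_effect"] = float(rec["nrf2_effect"])
            constants["nrf2_ec50"] = float(rec["nrf2_ec50"])
        registry[name] = CompoundRecord(
            mechanism=CompoundMechanism(name, tuple(rec["targets"]), constants),
            cmax=float(rec["cmax"]),
            reference_dose=float(rec["reference_dose"]),
            max_dose=float(rec["max_dose"]),
        )
    return registry


def saturating_factor(serum: float, a: float, b: float) -> float:
    """Emax-style fold factor 1 + a·s/(b+s); 1 at s=0, bounded by 1+a."""
    if serum < 0:
        raise ValueError("serum must be non-negative")
    return 1.0 + a * serum / (b + serum)


def _axis_anchor(network: ReactionNetwork, target: str) -> bool:
    ids = {r.id for r in network.reactions}
    if target in ("nrf2_activation", "p21_upregulation"):
        return "nrf2_import" in ids
    if target == "keap1_downregulation":
        return "Keap1" in {s.id for s in network.species}
    if target == "nrf2_degradation_inhibition":
        return "keap1_nrf2_degradation" in ids
    if target == "ros_scavenging":
        return ROS_POOL_ID in {s.id for s in network.species}
    return False


def apply_compound(network: ReactionNetwork,
                   mechanism: CompoundMechanism,
                   serum: float,
                   targets: Iterable[str] | None = None) -> ReactionNetwork:
    """Copy of the network perturbed by one compound at the given serum level.

    Only the mechanism targets whose anchor exists in this network are
    applied (the scavenging reaction needs the ROS pool; the Nrf2-axis
    factors need the Keap1–Nrf2 reactions), so the same mechanism can be
    applied to either pathway model; requesting a target the mechanism does
    not declare, or a mechanism none of whose targets resolve, is a
    configuration error.  serum = 0 returns a flux-identical copy.
    """
    if serum < 0:
        raise ValueError("serum must be non-negative")
    targets = tuple(targets) if targets is not None else mechanism.targets
    unknown = set(targets) - set(mechanism.targets)
    if unknown:
        raise NetworkConfigError(
            f"{mechanism.compound} does not declare targets {sorted(unknown)}")
    resolvable = [t for t in targets if _axis_anchor(network, t)]
    if not resolvable:
        raise NetworkConfigError(
            f"no target of {mechanism.compound} resolves in network "
            f"{network.name!r}")

    out = network.copy()
    if serum == 0:
        return out
    c = mechanism.effect_constants
    for target in resolvable:
        if target == "ros_scavenging":
            comp_id = f"compound_{mechanism.compound}"
            sink_id = f"scavenged_{mechanism.compound}"
            out.species.append(Species(
                comp_id, mechanism.compound.replace("_", " "),
                serum, constant=True))
            out.species.append(Species(
                sink_id, f"scavenged ROS ({mechanism.compound})", 0.0, sink=True))
            out.reactions.append(Reaction(
                f"ros_scavenging_{mechanism.compound}",
                reactants=[(ROS_POOL_ID, 1), (comp_id, 1)],
                products=[(sink_id, 1)],
                rate_law=mass_action(c["scavenging_k"])))
            continue
        f = saturating_factor(serum, c["nrf2_effect"], c["nrf2_ec50"])
        if target in ("nrf2_activation", "p21_upregulation"):
            out.get_reaction("nrf2_import").rate_law.parameters["k"] *= f
        elif target == "keap1_downregulation":
            sp = out.get_species("Keap1")
            sp.initial_concentration /= f
        elif target == "nrf2_degradation_inhibition":
            out.get_reaction("keap1_nrf2_degradation").rate_law.parameters["k"] /= f
    return out


def apply_combination(network: ReactionNetwork,
                      mechanisms: Sequence[tuple[CompoundMechanism, float]],
                      targets: Iterable[str] | None = None) -> ReactionNetwork:
    """Sequential application of several compounds.

    Scaling factors commute and the scavenging reactions are disjoint, so
    the resulting fluxes are order-independent.  Duplicate compounds are
    rejected.
    """
    names = [m.compound for m, _ in mechanisms]
    if len(set(names)) != len(names):
        raise NetworkConfigError(f"duplicate compounds in combination: {names}")
    out = network.copy()
    for mechanism, serum in mechanisms:
        applicable = tuple(targets) if targets is not None else mechanism.targets
        applicable = [t for t in applicable if t in mechanism.targets
                      and _axis_anchor(network, t)]
        if not applicable:
            continue
        out = apply_compound(out, mechanism, serum, applicable)
    return out


def nrf2_axis_scalings(mechanisms: Sequence[tuple[CompoundMechanism, float]],
                       ) -> dict[str, float]:
    """Joint multiplicative factors on the Nrf2-axis constants.

    Returns {"import_scale", "keap1_scale", "kn_deg_scale"} as the analytic
    steady-state solver consumes them; mirrors apply_compound exactly.
    """
    import_scale = keap1_scale = kn_deg_scale = 1.0
    for mech, serum in mechanisms:
        c = mech.effect_constants
        if "nrf2_effect" not in c or serum == 0:
            continue
        f = saturating_factor(serum, c["nrf2_effect"], c["nrf2_ec50"])
        for target in mech.targets:
            if target in ("nrf2_activation", "p21_upregulation"):
                import_scale *= f
            elif target == "keap1_downregulation":
                keap1_scale /= f
            elif target == "nrf2_degradation_inhibition":
                kn_deg_scale /= f
    return {"import_scale": import_scale, "keap1_scale": keap1_scale,
            "kn_deg_scale": kn_deg_scale}
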