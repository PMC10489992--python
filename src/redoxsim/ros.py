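"""The ROS-production network: NOX source, Fenton chemistry, lipid
peroxidation and enzymatic clearance (SOD, catalase, GSH/GPx cycle).

The pro-oxidant source is NADPH oxidase (NOX) generating superoxide; SOD
dismutates superoxide to H2O2, which is cleared by catalase and by the
GSH/GPx cycle or converted to hydroxyl radical by Fenton chemistry on the
Fe2+/Fe3+ couple.  Hydroxyl radical initiates a lipid-peroxidation chain on
the LH pool.  The aging condition scales the NOX turnover (default
two-fold); the "ROS" biomarker defaults to the superoxide pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from .network import (
    NetworkConfigError,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    constant_flux,
    mass_action,
    validate_network,
)

__all__ = ["RosModelConfig", "load_default_ros_config", "build_ros_network",
           "apply_aging_condition", "ros_biomarker", "NOX_REACTION_ID",
           "TABLE1_SPECIES_IDS"]

NOX_REACTION_ID = "nox_superoxide_source"

#: verbatim published key -> internal species id (SBML-safe)
TABLE1_SPECIES_IDS = {
    "LH": "LH",
    "O2": "O2",
    "H2O": "H2O",
    "Fe2+": "Fe2",
    "Fe3+": "Fe3",
    "SOD": "SOD",
    "H2O2": "H2O2",
    "Catalase": "CAT",
    "GSH": "GSH",
    "GPr": "GPr",
    "NADPH Oxidase": "NOX",
}

_REQUIRED_CONSTANTS = (
    "k_nox", "k_sod", "k_cat", "k_gpx", "k_fenton", "k_fe_red", "k_lh",
    "k_lo2", "k_prop", "k_term", "k_looh_clear", "k_gsh_syn", "k_gsh_deg",
    "k_gssg_red",
)


@dataclass
class RosModelConfig:
    """Configuration mirroring the published initial-concentration table.

    initial_concentrations uses the table's verbatim keys ("Fe2+",
    "NADPH Oxidase", ...); ros_readout maps internal species ids to weights
    defining the reported ROS biomarker (default: superoxide, weight 1).
    """

    initial_concentrations: dict[str, float]
    kinetic_constants: ParameterSet
    clamped_species: list[str] = field(default_factory=lambda: ["H2O", "O2", "NADPH Oxidase"])
    aging_fold: float = 2.0
    ros_readout: dict[str, float] = field(default_factory=lambda: {"O2m": 1.0})
    name: str = "ros_production"

    def __post_init__(self) -> None:
        if self.aging_fold <= 0:
            raise ValueError("aging_fold must be positive")
        missing = [k for k in TABLE1_SPECIES_IDS if k not in self.initial_concentrations]
        if missing:
            raise NetworkConfigError(f"missing initial concentrations: {missing}")
        for name in _REQUIRED_CONSTANTS:
            if name not in self.kinetic_constants:
                raise NetworkConfigError(f"missing kinetic constant {name!r}")


def load_default_ros_config() -> RosModelConfig:
    """Shipped parameterisation (initial concentrations + kinetic constants)."""
    raw = yaml.safe_load(
        resources.files("redoxsim.data").joinpath("ros_model.yaml").read_text())
    return RosModelConfig(
        initial_concentrations={k: float(v) for k, v in raw["initial_concentrations"].items()},
        kinetic_constants=ParameterSet({k: float(v) for k, v in raw["kinetic_constants"].items()}),
        clamped_species=list(raw.get("clamped_species", [])),
        aging_fold=float(raw.get("aging_fold", 2.0)),
        ros_readout={k: float(v) for k, v in raw["ros_readout"].items()},
        name=raw.get("name", "ros_production"),
    )


def build_ros_network(config: RosModelConfig | None = None) -> ReactionNetwork:
    """Assemble and validate the ROS-production reaction network."""
    config = config or load_default_ros_config()
    k = config.kinetic_constants
    init = config.initial_concentrations
    clamped = set(config.clamped_species)

    species = [
        Species(TABLE1_SPECIES_IDS[key], display_name=key,
                initial_concentration=float(init[key]),
                constant=key in clamped)
        for key in TABLE1_SPECIES_IDS
    ]
    species += [
        Species("O2m", "superoxide (O2.-)", 0.0),
        Species("OH", "hydroxyl radical (OH.)", 0.0),
        Species("L", "lipid radical (L.)", 0.0),
        Species("LOO", "lipid peroxyl radical (LOO.)", 0.0),
        Species("LOOH", "lipid hydroperoxide", 0.0),
        Species("GSSG", "glutathione disulfide", 0.0),
    ]

    reactions = [
        # NOX-catalysed superoxide production; the aging condition scales k.
        Reaction(NOX_REACTION_ID,
                 reactants=[("NOX", 1), ("O2", 1)],
                 products=[("NOX", 1), ("O2m", 1)],
                 rate_law=mass_action(k["k_nox"])),
        # SOD dismutation: 2 O2.- -> H2O2 + O2, first order in substrate.
        Reaction("sod_dismutation",
                 reactants=[("O2m", 2)],
                 products=[("H2O2", 1), ("O2", 1)],
                 modifiers=["SOD"],
                 rate_law=mass_action(k["k_sod"], [("SOD", 1), ("O2m", 1)])),
        # Catalase: 2 H2O2 -> 2 H2O + O2, first order in H2O2.
        Reaction("catalase_decomposition",
                 reactants=[("H2O2", 2)],
                 products=[("H2O", 2), ("O2", 1)],
                 modifiers=["CAT"],
                 rate_law=mass_action(k["k_cat"], [("CAT", 1), ("H2O2", 1)])),
        # GPx cycle: H2O2 + 2 GSH -> GSSG + 2 H2O (rate per GPr, H2O2, GSH).
        Reaction("gpx_h2o2_reduction",
                 reactants=[("H2O2", 1), ("GSH", 2)],
                 products=[("GSSG", 1), ("H2O", 2)],
                 modifiers=["GPr"],
                 rate_law=mass_action(k["k_gpx"], [("GPr", 1), ("H2O2", 1), ("GSH", 1)])),
        Reaction("glutathione_reductase",
                 reactants=[("GSSG", 1)],
                 products=[("GSH", 2)],
                 rate_law=mass_action(k["k_gssg_red"])),
        Reaction("gsh_synthesis", products=[("GSH", 1)],
                 rate_law=constant_flux(k["k_gsh_syn"])),
        Reaction("gsh_turnover", reactants=[("GSH", 1)],
                 rate_law=mass_action(k["k_gsh_deg"])),
        # Fenton chemistry and iron recycling (total iron is conserved).
        Reaction("fenton",
                 reactants=[("Fe2", 1), ("H2O2", 1)],
                 products=[("Fe3", 1), ("OH", 1)],
                 rate_law=mass_action(k["k_fenton"])),
        Reaction("iron_recycling",
                 reactants=[("Fe3", 1)],
                 products=[("Fe2", 1)],
                 rate_law=mass_action(k["k_fe_red"])),
        # Lipid peroxidation chain.
        Reaction("lipid_initiation",
                 reactants=[("LH", 1), ("OH", 1)],
                 products=[("L", 1), ("H2O", 1)],
                 rate_law=mass_action(k["k_lh"])),
        Reaction("lipid_oxygenation",
                 reactants=[("L", 1), ("O2", 1)],
                 products=[("LOO", 1)],
                 rate_law=mass_action(k["k_lo2"])),
        Reaction("lipid_propagation",
                 reactants=[("LOO", 1), ("LH", 1)],
                 products=[("LOOH", 1), ("L", 1)],
                 rate_law=mass_action(k["k_prop"])),
        Reaction("lipid_termination",
                 reactants=[("LOO", 2)],
                 rate_law=mass_action(k["k_term"])),
        Reaction("looh_clearance",
                 reactants=[("LOOH", 1)],
                 rate_law=mass_action(k["k_looh_clear"])),
    ]

    net = ReactionNetwork(config.name, species, reactions)
    findings = validate_network(net)
    if findings:
        raise NetworkConfigError("ROS network invalid: " + "; ".join(findings))
    return net


def apply_aging_condition(network: ReactionNetwork, fold: float) -> ReactionNetwork:
    """Copy of the network with the NOX catalytic rate scaled by ``fold``.

    The aged oxidative-stress state roughly doubles NADPH-oxidase activity;
    the scaling is applied to the catalytic rate constant, which for a law
    linear in the enzyme is equivalent to scaling the enzyme level.
    """
    if fold <= 0:
        raise ValueError("aging fold must be positive")
    out = network.copy()
    try:
        rxn = out.get_reaction(NOX_REACTION_ID)
    except KeyError:
        raise NetworkConfigError(
            f"network {network.name!r} has no NADPH-oxidase source reaction")
    rxn.rate_law.parameters["k"] *= fold
    return out


def ros_biomarker(state: Mapping[str, float],
                  config: RosModelConfig | None = None) -> float:
    """Weighted readout over the configured radical pool (default superoxide)."""
    config = config or load_default_ros_config()
    total = 0.0
    for sid, weight in config.ros_readout.items():
        if sid not in state:
            raise KeyError(f"readout species {sid!r} absent from state")
        total += weight * state[sid]
    return total
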