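"""The antioxidant-enzyme production network (Keap1–Nrf2–Maf/ARE axis).

Cytosolic Nrf2 is sequestered by Keap1 and degraded from the complex;
intracellular H2O2 drives oxidative release, freeing Nrf2 for nuclear
import, where it dimerises with Maf.  The nuclear Nrf2·Maf complex drives
saturating ARE synthesis of the four antioxidant enzymes (CAT, HO-1, SOD,
GPx), each with first-order turnover.

Besides the ODE network, the module provides an exact algebraic steady-state
solver for this axis (used by the deterministic effect-constant fitting) and
the closed-form synthesis-rate calibration that pins the enzyme baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from dataclasses import replace as dc_replace
from importlib import resources
from typing import Iterable, Mapping

import yaml
from scipy.optimize import brentq

from .network import (
    NetworkConfigError,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    constant_flux,
    mass_action,
    michaelis_menten,
    validate_network,
)
from .simulate import BiomarkerPanel

__all__ = [
    "AntioxidantModelConfig",
    "load_default_antioxidant_config",
    "build_antioxidant_network",
    "nrf2_axis_steady_state",
    "couple_models",
    "calibrate_baselines",
    "ENZYMES",
    "ENZYME_SYNTHESIS_IDS",
]

ENZYMES = ("CAT", "HO1", "SOD", "GPx")
ENZYME_SYNTHESIS_IDS = {e: f"are_synthesis_{e}" for e in ENZYMES}

TABLE2_SPECIES_IDS = {"Maf": "Maf", "Keap1": "Keap1", "Nrf2": "Nrf2",
                      "H2O2i": "H2O2i"}

_REQUIRED = (
    "k_keap1_bind", "k_keap1_unbind", "k_oxidative_release", "k_nrf2_deg_keap1",
    "k_nrf2_syn", "k_nrf2_import", "k_nrf2n_deg", "k_maf_bind", "k_maf_unbind",
    "k_enz_deg", "K_A", "k_syn_CAT", "k_syn_HO1", "k_syn_SOD", "k_syn_GPx",
)


@dataclass
class AntioxidantModelConfig:
    initial_concentrations: dict[str, float]
    kinetic_constants: ParameterSet
    clamped_species: list[str] = field(default_factory=lambda: ["H2O2i"])
    enzyme_baselines: dict[str, float] = field(default_factory=dict)
    name: str = "antioxidant_production"

    def __post_init__(self) -> None:
        missing = [k for k in TABLE2_SPECIES_IDS if k not in self.initial_concentrations]
        if missing:
            raise NetworkConfigError(f"missing initial concentrations: {missing}")
        for name in _REQUIRED:
            if name not in self.kinetic_constants:
                raise NetworkConfigError(f"missing kinetic constant {name!r}")
            if name.startswith(("k_syn", "k_enz", "k_nrf2_deg")) \
                    and self.kinetic_constants[name] <= 0:
                raise NetworkConfigError(f"constant {name!r} must be positive")


def load_default_antioxidant_config() -> AntioxidantModelConfig:
    raw = yaml.safe_load(
        resources.files("redoxsim.data").joinpath("antioxidant_model.yaml").read_text())
    return AntioxidantModelConfig(
        initial_concentrations={k: float(v) for k, v in raw["initial_concentrations"].items()},
        kinetic_constants=ParameterSet({k: float(v) for k, v in raw["kinetic_constants"].items()}),
        clamped_species=list(raw.get("clamped_species", [])),
        enzyme_baselines={k: float(v) for k, v in raw.get("enzyme_baselines", {}).items()},
        name=raw.get("name", "antioxidant_production"),
    )


def build_antioxidant_network(config: AntioxidantModelConfig | None = None,
                              maf_turnover: bool = False) -> ReactionNetwork:
    """Assemble and validate the Nrf2/ARE network.

    With ``maf_turnover`` disabled (default) total Maf (free + in the nuclear
    complex) is a conserved moiety, as is total Keap1.
    """
    config = config or load_default_antioxidant_config()
    k = config.kinetic_constants
    init = config.initial_concentrations
    clamped = set(config.clamped_species)

    species = [
        Species("Maf", "Maf nuclear protein", init["Maf"], constant="Maf" in clamped),
        Species("Keap1", "Kelch-like ECH-associated protein 1", init["Keap1"]),
        Species("Nrf2", "Nrf2 (cytosolic)", init["Nrf2"]),
        Species("H2O2i", "basal intracellular H2O2", init["H2O2i"],
                constant="H2O2i" in clamped),
        Species("KN", "Keap1.Nrf2 complex", 0.0),
        Species("Nrf2n", "Nrf2 (nuclear)", 0.0),
        Species("NM", "nuclear Nrf2.Maf complex", 0.0),
        Species("CAT", "catalase", 0.0),
        Species("HO1", "heme oxygenase-1", 0.0),
        Species("SOD", "superoxide dismutase", 0.0),
        Species("GPx", "glutathione peroxidase", 0.0),
    ]

    reactions = [
        Reaction("keap1_nrf2_binding",
                 reactants=[("Keap1", 1), ("Nrf2", 1)], products=[("KN", 1)],
                 rate_law=mass_action(k["k_keap1_bind"])),
        Reaction("keap1_nrf2_unbinding",
                 reactants=[("KN", 1)], products=[("Keap1", 1), ("Nrf2", 1)],
                 rate_law=mass_action(k["k_keap1_unbind"])),
        # H2O2 oxidises Keap1 cysteines, releasing Nrf2 from the complex.
        Reaction("oxidative_release",
                 reactants=[("KN", 1)], products=[("Keap1", 1), ("Nrf2", 1)],
                 modifiers=["H2O2i"],
                 rate_law=mass_action(k["k_oxidative_release"],
                                      [("KN", 1), ("H2O2i", 1)])),
        # Keap1-promoted proteasomal degradation of complexed Nrf2.
        Reaction("keap1_nrf2_degradation",
                 reactants=[("KN", 1)], products=[("Keap1", 1)],
                 rate_law=mass_action(k["k_nrf2_deg_keap1"])),
        Reaction("nrf2_synthesis", products=[("Nrf2", 1)],
                 rate_law=constant_flux(k["k_nrf2_syn"])),
        Reaction("nrf2_import",
                 reactants=[("Nrf2", 1)], products=[("Nrf2n", 1)],
                 rate_law=mass_action(k["k_nrf2_import"])),
        Reaction("nrf2n_degradation", reactants=[("Nrf2n", 1)],
                 rate_law=mass_action(k["k_nrf2n_deg"])),
        Reaction("maf_binding",
                 reactants=[("Nrf2n", 1), ("Maf", 1)], products=[("NM", 1)],
                 rate_law=mass_action(k["k_maf_bind"])),
        Reaction("maf_unbinding",
                 reactants=[("NM", 1)], products=[("Nrf2n", 1), ("Maf", 1)],
                 rate_law=mass_action(k["k_maf_unbind"])),
    ]
    if maf_turnover:
        reactions += [
            Reaction("maf_synthesis", products=[("Maf", 1)],
                     rate_law=constant_flux(k.get("k_maf_syn", 0.0))),
            Reaction("maf_degradation", reactants=[("Maf", 1)],
                     rate_law=mass_action(k.get("k_maf_deg", 0.0))),
        ]
    for enz in ENZYMES:
        # ARE-driven synthesis, saturating in the nuclear Nrf2.Maf complex.
        reactions.append(Reaction(
            ENZYME_SYNTHESIS_IDS[enz],
            reactants=[("NM", 1)], products=[("NM", 1), (enz, 1)],
            rate_law=michaelis_menten(k[f"k_syn_{enz}"], k["K_A"], "NM")))
        reactions.append(Reaction(
            f"{enz}_degradation", reactants=[(enz, 1)],
            rate_law=mass_action(k["k_enz_deg"])))

    net = ReactionNetwork(config.name, species, reactions)
    findings = validate_network(net)
    if findings:
        raise NetworkConfigError("antioxidant network invalid: " + "; ".join(findings))
    return net


def nrf2_axis_steady_state(constants: Mapping[str, float],
                           keap1_total: float,
                           maf_total: float,
                           h2o2: float) -> dict[str, float]:
    """Exact steady state of the Nrf2 axis and the enzyme panel.

    Solves the cytosolic Nrf2 balance (synthesis = Keap1-routed degradation +
    nuclear import) by monotone bracketing, then propagates through nuclear
    import, Maf binding (with Maf conservation) and the saturating ARE
    synthesis law.  Used as the fast inner model of effect-constant fitting
    and as an independent cross-check of the integrated ODE solution.
    """
    k = constants
    phi = k["k_nrf2_syn"]
    D = k["k_keap1_unbind"] + k["k_oxidative_release"] * h2o2 + k["k_nrf2_deg_keap1"]
    kf, kdeg, kimp = k["k_keap1_bind"], k["k_nrf2_deg_keap1"], k["k_nrf2_import"]

    def kn_of(n: float) -> float:
        return kf * keap1_total * n / (kf * n + D)

    def residual(n: float) -> float:
        return phi - kdeg * kn_of(n) - kimp * n

    n_hi = phi / kimp
    if residual(n_hi) > 0:  # pragma: no cover - defensive; residual(n_hi) <= 0 always
        n_free = n_hi
    else:
        n_free = brentq(residual, 0.0, n_hi, xtol=1e-14, rtol=1e-14)
    kn = kn_of(n_free)
    nn = kimp * n_free / k["k_nrf2n_deg"]
    keq = k["k_maf_bind"] / k["k_maf_unbind"]
    nm = keq * nn * maf_total / (1.0 + keq * nn)
    g = nm / (k["K_A"] + nm)
    out = {"Nrf2": n_free, "KN": kn, "Keap1": keap1_total - kn,
           "Nrf2n": nn, "NM": nm, "Maf": maf_total - nm, "activation": g}
    for enz in ENZYMES:
        out[enz] = k[f"k_syn_{enz}"] * g / k["k_enz_deg"]
    return out


def couple_models(ros: ReactionNetwork, antiox: ReactionNetwork,
                  mode: str = "independent",
                  ) -> tuple[ReactionNetwork, dict]:
    """Join the two pathway models into one network.

    mode="independent": disjoint union; colliding species ids from the
    antioxidant network are prefixed ("antiox__") and reported in the
    returned diagnostics.  This matches the published per-pathway biomarker
    reporting.

    mode="shared_h2o2": the ROS-model H2O2 pool and the antioxidant-model
    basal H2O2i are merged into the single dynamic H2O2 pool, and the
    enzymes produced by the ARE axis (CAT, SOD, GPx) replace the fixed
    enzyme pools of the ROS model, coupling oxidant load to the adaptive
    antioxidant response.
    """
    if mode not in ("independent", "shared_h2o2"):
        raise ValueError(f"unknown coupling mode {mode!r}")
    merge_map: dict[str, str] = {}
    if mode == "shared_h2o2":
        # the ROS model names its (small, fixed) GPx pool "GPr"
        for sid, target in (("H2O2i", "H2O2"), ("CAT", "CAT"),
                            ("SOD", "SOD"), ("GPx", "GPr")):
            if target not in {s.id for s in ros.species}:
                raise NetworkConfigError(
                    f"shared coupling requires species {target!r} in the ROS model")
            merge_map[sid] = target
        if "H2O2i" not in {s.id for s in antiox.species}:
            raise NetworkConfigError("antioxidant model lacks an H2O2i pool")

    combined = ros.copy()
    ros_ids = {s.id for s in combined.species}
    renames: dict[str, str] = {}
    for sp in antiox.species:
        if sp.id in merge_map:
            target = combined.get_species(merge_map[sp.id])
            # the ARE-produced enzyme pool supersedes the fixed one
            if sp.id != "H2O2i":
                target.constant = False
            renames[sp.id] = target.id
            continue
        new_id = sp.id
        if new_id in ros_ids:
            new_id = f"antiox__{sp.id}"
            renames[sp.id] = new_id
        sp2 = Species(new_id, sp.display_name, sp.initial_concentration,
                      sp.constant, sp.sink)
        combined.species.append(sp2)
        ros_ids.add(new_id)

    def rn(sid: str) -> str:
        return renames.get(sid, sid)

    existing_rxn = {r.id for r in combined.reactions}
    for rxn in antiox.reactions:
        law = rxn.resolved_rate_law()
        new_law = dc_replace(
            law,
            parameters=dict(law.parameters),
            species_orders=(None if law.species_orders is None
                            else [(rn(s), o) for s, o in law.species_orders]),
            substrate=(None if law.substrate is None else rn(law.substrate)),
        )
        combined.reactions.append(Reaction(
            id=rxn.id if rxn.id not in existing_rxn else f"antiox__{rxn.id}",
            reactants=[(rn(s), c) for s, c in rxn.reactants],
            products=[(rn(s), c) for s, c in rxn.products],
            modifiers=[rn(s) for s in rxn.modifiers],
            rate_law=new_law,
        ))

    combined.name = f"oxidative_stress_{mode}"
    findings = validate_network(combined)
    if findings:
        raise NetworkConfigError("coupled network invalid: " + "; ".join(findings))
    diagnostics = {"mode": mode, "renamed": renames,
                   "merged": list(merge_map) if merge_map else [],
                   "n_species": len(combined.species)}
    return combined, diagnostics


def _first_order_degradation_rate(net: ReactionNetwork, enzyme: str
                                  ) -> float | None:
    """k of a pure first-order degradation reaction for the enzyme, if any."""
    try:
        rxn = net.get_reaction(f"{enzyme}_degradation")
    except KeyError:
        return None
    law = rxn.resolved_rate_law()
    if law.form == "mass_action" and law.species_orders == [(enzyme, 1)] \
            and rxn.reactants == [(enzyme, 1)] and not rxn.products:
        return law.parameters["k"]
    return None


def _synthesis_reaction(net: ReactionNetwork, enzyme: str) -> Reaction:
    for rid in (ENZYME_SYNTHESIS_IDS.get(enzyme), f"{enzyme}_synthesis"):
        if rid is None:
            continue
        try:
            return net.get_reaction(rid)
        except KeyError:
            continue
    raise NetworkConfigError(f"no synthesis reaction found for enzyme {enzyme!r}")


def calibrate_baselines(network: ReactionNetwork,
                        targets: BiomarkerPanel | Mapping[str, float],
                        free_constants: Iterable[str] | None = None,
                        tolerance: float = 1e-3,
                        max_iter: int = 5) -> ParameterSet:
    """Set per-enzyme synthesis rates so the control run hits the baselines.

    For a synthesis flux linear in its rate constant with first-order
    degradation, the steady state is proportional to k_syn, so the closed
    form k_syn' = k_syn * target / current_steady_state is exact (and
    reduces to k_syn = k_deg * target when the activation factor is 1).  The
    closed-form step is applied first and iterated — a deterministic
    fixed-point that converges in one step for this model family; residual
    misfit above ``tolerance`` after ``max_iter`` passes raises with the
    best-achieved residuals.

    Returns the updated constants {f"k_syn_{enzyme}": value}.
    """
    from .simulate import SimulationSettings, detect_steady_state, integrate

    if isinstance(targets, BiomarkerPanel):
        name_map = {"cat": "CAT", "ho1": "HO1", "sod": "SOD", "gpx": "GPx"}
        targets = {name_map[k]: v for k, v in targets.as_dict().items()
                   if k in name_map}
    targets = dict(targets)
    for enz, val in targets.items():
        if val <= 0:
            raise ValueError(f"target for {enz} must be strictly positive")
    if free_constants is None:
        free_constants = [f"k_syn_{e}" for e in targets]
    free_constants = list(free_constants)

    net = network.copy()
    result = ParameterSet()

    # Closed form first: constant-flux synthesis with sole first-order
    # degradation gives k_syn = k_deg * target exactly, no simulation needed.
    remaining = {}
    for enz, target in targets.items():
        syn = _synthesis_reaction(net, enz)
        k_deg = _first_order_degradation_rate(net, enz)
        if syn.rate_law.form == "constant_flux" and k_deg is not None \
                and f"k_syn_{enz}" in free_constants:
            syn.rate_law.parameters["k"] = k_deg * target
            result[f"k_syn_{enz}"] = k_deg * target
        else:
            remaining[enz] = target
    if not remaining:
        return result
    targets = remaining

    residuals: dict[str, float] = {}
    for _ in range(max_iter):
        sim = integrate(net, SimulationSettings())
        _, state = detect_steady_state(sim)
        residuals = {e: abs(state[e] - t) / t for e, t in targets.items()}
        if all(r < tolerance for r in residuals.values()):
            break
        for enz, target in targets.items():
            name = f"k_syn_{enz}"
            if name not in free_constants:
                continue
            rxn = _synthesis_reaction(net, enz)
            key = "Vmax" if "Vmax" in rxn.rate_law.parameters else "k"
            current = state[enz]
            if current <= 0:
                raise NetworkConfigError(
                    f"enzyme {enz} has zero steady state; cannot rescale synthesis")
            rxn.rate_law.parameters[key] *= target / current
            result[name] = rxn.rate_law.parameters[key]
    else:
        raise RuntimeError(f"calibration did not converge; residuals {residuals}")
    for enz in targets:
        rxn = _synthesis_reaction(net, enz)
        key = "Vmax" if "Vmax" in rxn.rate_law.parameters else "k"
        result[f"k_syn_{enz}"] = rxn.rate_law.parameters[key]
    return result
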