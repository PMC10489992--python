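"""SBML Level 3 export/import of reaction networks.

The mapping is lossless for this package's rate-law vocabulary: kinetic laws
are written as explicit formulas with local parameters (k; Vmax/Km;
Vmax/Km/hill_n), and the law form is reconstructed on import from the local
parameter names and the formula structure.  Round-trips preserve species,
initial concentrations and the stoichiometry matrix exactly.
"""

from __future__ import annotations

import libsbml

from .network import (
    NetworkConfigError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
)

__all__ = ["write_sbml", "read_sbml"]

_SINK_NOTE = ('<body xmlns="http://www.w3.org/1999/xhtml">'
              "<p>sink species (bookkeeping accumulator)</p></body>")


def _formula(rxn: Reaction) -> str:
    law = rxn.resolved_rate_law()
    if law.form == "constant_flux":
        return "k"
    if law.form == "mass_action":
        parts = ["k"]
        for sid, order in law.species_orders or []:
            parts.append(sid if order == 1 else f"{sid}^{order:g}")
        return " * ".join(parts)
    s = law.substrate
    if law.form == "michaelis_menten":
        return f"Vmax * {s} / (Km + {s})"
    if law.form == "hill":
        return f"Vmax * {s}^hill_n / (Km^hill_n + {s}^hill_n)"
    raise NetworkConfigError(f"cannot export rate-law form {law.form!r}")


def write_sbml(network: ReactionNetwork, path: str | None = None) -> str:
    """Serialise to an SBML L3V2 string (and optionally write it to path)."""
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(network.name.replace(" ", "_"))
    model.setName(network.name)
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    comp.setConstant(True)
    comp.setSpatialDimensions(3)

    for sp in network.species:
        s = model.createSpecies()
        s.setId(sp.id)
        s.setName(sp.display_name)
        s.setCompartment("cell")
        s.setInitialConcentration(sp.initial_concentration)
        s.setConstant(bool(sp.constant))
        s.setBoundaryCondition(bool(sp.constant))
        s.setHasOnlySubstanceUnits(False)
        if sp.sink:
            s.setNotes(_SINK_NOTE)

    for rxn in network.reactions:
        law = rxn.resolved_rate_law()
        r = model.createReaction()
        r.setId(rxn.id)
        r.setReversible(False)
        for sid, coef in rxn.reactants:
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        for sid, coef in rxn.products:
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        modifiers = set(rxn.modifiers)
        # species in the rate law but not consumed/produced must be modifiers
        consumed = {s for s, _ in rxn.reactants} | {s for s, _ in rxn.products}
        modifiers |= set(law.referenced_species()) - consumed
        for sid in sorted(modifiers):
            ref = r.createModifier()
            ref.setSpecies(sid)
        kl = r.createKineticLaw()
        math = libsbml.parseL3Formula(_formula(rxn))
        if math is None:
            raise NetworkConfigError(f"bad formula for reaction {rxn.id!r}")
        kl.setMath(math)
        for pname, pval in law.parameters.items():
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(pval)

    if doc.checkInternalConsistency() > 0:  # pragma: no cover - sanity guard
        errs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        if errs:
            raise NetworkConfigError("SBML export inconsistent: " + "; ".join(errs))
    text = libsbml.writeSBMLToString(doc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _collect_orders(node: "libsbml.ASTNode", params: set[str],
                    orders: dict[str, float]) -> None:
    t = node.getType()
    if t == libsbml.AST_TIMES:
        for i in range(node.getNumChildren()):
            _collect_orders(node.getChild(i), params, orders)
    elif t == libsbml.AST_NAME:
        name = node.getName()
        if name not in params:
            orders[name] = orders.get(name, 0.0) + 1.0
    elif t in (libsbml.AST_POWER, libsbml.AST_FUNCTION_POWER):
        base, exp = node.getChild(0), node.getChild(1)
        name = base.getName()
        if name is not None and name not in params:
            orders[name] = orders.get(name, 0.0) + exp.getValue()
    # numeric literals contribute nothing


def _collect_names(node: "libsbml.ASTNode", params: set[str],
                   names: set[str]) -> None:
    if node.getType() == libsbml.AST_NAME:
        name = node.getName()
        if name not in params:
            names.add(name)
    for i in range(node.getNumChildren()):
        _collect_names(node.getChild(i), params, names)


def _law_from_kinetics(kl: "libsbml.KineticLaw") -> RateLaw:
    params = {kl.getLocalParameter(i).getId(): kl.getLocalParameter(i).getValue()
              for i in range(kl.getNumLocalParameters())}
    pnames = set(params)
    math = kl.getMath()
    symbols: set[str] = set()
    if math is not None:
        _collect_names(math, pnames, symbols)
    if "Vmax" in params:
        if len(symbols) != 1:
            raise NetworkConfigError(
                f"saturating law needs exactly one substrate symbol, got {symbols}")
        substrate = symbols.pop()
        if "hill_n" in params:
            return RateLaw("hill", params, substrate=substrate)
        return RateLaw("michaelis_menten", params, substrate=substrate)
    if not symbols:
        return RateLaw("constant_flux", params)
    # mass action: the formula is the pure product k * prod(species^order)
    orders: dict[str, float] = {}
    _collect_orders(math, pnames, orders)
    return RateLaw("mass_action", params, species_orders=sorted(orders.items()))


def read_sbml(source: str) -> ReactionNetwork:
    """Parse an SBML string or file path back into a ReactionNetwork."""
    if "<sbml" in source:
        doc = libsbml.readSBMLFromString(source)
    else:
        doc = libsbml.readSBMLFromFile(source)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage() for i in range(doc.getNumErrors())]
        raise NetworkConfigError("SBML parse failed: " + "; ".join(msgs))
    model = doc.getModel()
    if model is None:
        raise NetworkConfigError("SBML document contains no model")

    species = []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        species.append(Species(
            id=s.getId(),
            display_name=s.getName() or s.getId(),
            initial_concentration=(s.getInitialConcentration()
                                   if s.isSetInitialConcentration() else 0.0),
            constant=bool(s.getConstant() or s.getBoundaryCondition()),
            sink="sink species" in (s.getNotesString() or ""),
        ))

    reactions = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        law = _law_from_kinetics(r.getKineticLaw())
        reactions.append(Reaction(
            id=r.getId(),
            reactants=[(r.getReactant(j).getSpecies(),
                        r.getReactant(j).getStoichiometry())
                       for j in range(r.getNumReactants())],
            products=[(r.getProduct(j).getSpecies(),
                       r.getProduct(j).getStoichiometry())
                      for j in range(r.getNumProducts())],
            modifiers=[r.getModifier(j).getSpecies()
                       for j in range(r.getNumModifiers())],
            rate_law=law,
        ))
    return ReactionNetwork(model.getName() or model.getId(), species, reactions)
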