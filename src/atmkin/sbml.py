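"""SBML Level 3 export of the instantiated two-site model.

Writes a self-contained SBML L3V2 document: the template species are
duplicated into the ``damaged_site`` and ``undamaged_site`` compartments,
the controls (DSB, ROS, r) become parameters with rate rules, gate factors
become parameters with assignment rules, and shuttling becomes explicit
transport reactions (including the MRN-enhanced recruitment term).

The document is produced directly with :mod:`xml.etree.ElementTree`
(species/reactions/rules plus hand-built MathML); it targets SBML core only,
without units.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .controls import AgentProtocol
from .network import Gate, ReactionNetwork
from .params import Parameters
from .simulator import ShuttlingSpec

__all__ = ["export_sbml", "sbml_document"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"

_SITE = {"d": "damaged_site", "u": "undamaged_site"}


# --- tiny MathML builder ---------------------------------------------------


def _math(expr) -> ET.Element:
    root = ET.Element(f"{{{MATHML_NS}}}math")
    root.append(_expr(expr))
    return root


def _expr(e) -> ET.Element:
    ns = f"{{{MATHML_NS}}}"
    if isinstance(e, (int, float)):
        el = ET.Element(ns + "cn")
        el.text = repr(float(e))
        return el
    if isinstance(e, str):
        el = ET.Element(ns + "ci")
        el.text = f" {e} "
        return el
    op, *args = e
    if op == "time":
        el = ET.Element(ns + "csymbol")
        el.set("encoding", "text")
        el.set("definitionURL", TIME_URL)
        el.text = " t "
        return el
    if op == "piecewise":
        # ("piecewise", value_if, cond, value_else)
        val_if, cond, val_else = args
        pw = ET.Element(ns + "piecewise")
        piece = ET.SubElement(pw, ns + "piece")
        piece.append(_expr(val_if))
        piece.append(_expr(cond))
        other = ET.SubElement(pw, ns + "otherwise")
        other.append(_expr(val_else))
        return pw
    apply_el = ET.Element(ns + "apply")
    ET.SubElement(apply_el, ns + op)
    for a in args:
        apply_el.append(_expr(a))
    return apply_el


def _times(*args):
    flat = [a for a in args if a is not None]
    if len(flat) == 1:
        return flat[0]
    return ("times", *flat)


# --- document assembly -----------------------------------------------------


def _gate_param_id(gate: Gate, site: str) -> str:
    if gate.kind == "relaxation":
        return f"gate_rel_h{gate.h:g}_{site}".replace(".", "_")
    return f"gate_{gate.kind}_K{gate.K:g}_{site}".replace(".", "_")


def _gate_expr(gate: Gate, site: str):
    r = "r0" if site == "d" else "r1"
    ros = "ROS0" if site == "d" else "ROS1"
    if gate.kind == "relaxation":
        return ("power", r, gate.h)
    if gate.kind == "ros":
        return ("divide", ros, ("plus", gate.K, ros))
    dsb = "DSB" if site == "d" else 0.0  # no breaks at the undamaged site
    if site == "u":
        return 0.0
    return ("divide", dsb, ("plus", gate.K, dsb))


def sbml_document(
    network: ReactionNetwork,
    shuttling: ShuttlingSpec,
    params: Parameters,
    protocol: AgentProtocol = AgentProtocol("IR", 1.0, 1.0),
) -> ET.ElementTree:
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {
        "id": network.name.replace("-", "_"),
        "name": network.name,
    })

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for cid in _SITE.values():
        ET.SubElement(comps, f"{{{SBML_NS}}}compartment", {
            "id": cid, "constant": "true", "size": "1",
            "spatialDimensions": "3",
        })

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for site in ("d", "u"):
        for s in network.species:
            ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
                "id": f"{s.id}__{site}",
                "name": s.name,
                "compartment": _SITE[site],
                "initialAmount": repr(float(s.initial_amount)),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false",
                "constant": "false",
            })

    pars_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")

    def par(pid: str, value: float, constant: bool) -> None:
        ET.SubElement(pars_el, f"{{{SBML_NS}}}parameter", {
            "id": pid,
            "value": repr(float(value)),
            "constant": "true" if constant else "false",
        })

    for pid in ("DSB", "ROS0", "ROS1", "r0", "r1"):
        par(pid, 0.0, constant=False)
    p = params.as_dict()
    for pid in ("dsb_yield", "k_repair", "k_ros_prod", "k_ros_decay",
                "k_rel_dsb", "k_rel_pkap", "k_cond_kap"):
        par(pid, p[pid], constant=True)
    par("DR", protocol.dose_rate, constant=True)
    par("T_exposure", protocol.exposure_time, constant=True)
    par("k_mrn", shuttling.k_mrn, constant=True)
    par("K_dsb_sensor", shuttling.K_dsb, constant=True)

    # distinct gates become assignment-rule parameters
    gate_ids: dict[str, Gate] = {}
    for rxn in network.reactions:
        for gate in rxn.rate_law.gates:
            for site in ("d", "u"):
                gid = _gate_param_id(gate, site)
                if gid not in gate_ids:
                    gate_ids[gid] = (gate, site)
    for gid in gate_ids:
        par(gid, 0.0, constant=False)

    rules_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfRules")
    for gid, (gate, site) in gate_ids.items():
        rule = ET.SubElement(rules_el, f"{{{SBML_NS}}}assignmentRule",
                             {"variable": gid})
        rule.append(_math(_gate_expr(gate, site)))

    def rate_rule(variable: str, expr) -> None:
        rule = ET.SubElement(rules_el, f"{{{SBML_NS}}}rateRule",
                             {"variable": variable})
        rule.append(_math(expr))

    pulse = ("piecewise", "DR", ("lt", ("time",), "T_exposure"), 0.0)
    dsb_prod = _times("dsb_yield", pulse) if protocol.makes_dsb else 0.0
    rate_rule("DSB", ("minus", dsb_prod, _times("k_repair", "DSB")))
    ros_prod = _times("k_ros_prod", pulse) if protocol.makes_ros else 0.0
    rate_rule("ROS0", ("minus", ros_prod, _times("k_ros_decay", "ROS0")))
    rate_rule("ROS1", ("minus", ros_prod, _times("k_ros_decay", "ROS1")))
    rate_rule(
        "r0",
        ("minus",
         _times(("plus", _times("k_rel_dsb", "DSB"),
                 _times("k_rel_pkap", "pKAP1__d")),
                ("minus", 1.0, "r0")),
         _times("k_cond_kap", "KAP1__d", "r0")),
    )
    rate_rule(
        "r1",
        ("minus",
         _times(_times("k_rel_pkap", "pKAP1__u"), ("minus", 1.0, "r1")),
         _times("k_cond_kap", "KAP1__u", "r1")),
    )

    rxns_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")

    def add_reaction(rid, reactants, products, modifiers, math_expr):
        r_el = ET.SubElement(rxns_el, f"{{{SBML_NS}}}reaction", {
            "id": rid, "reversible": "false",
        })
        if reactants:
            lo = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfReactants")
            for sid, n in reactants:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference", {
                    "species": sid, "stoichiometry": str(n),
                    "constant": "true",
                })
        if products:
            lo = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfProducts")
            for sid, n in products:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference", {
                    "species": sid, "stoichiometry": str(n),
                    "constant": "true",
                })
        if modifiers:
            lo = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfModifiers")
            for sid in modifiers:
                ET.SubElement(lo, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": sid})
        kl = ET.SubElement(r_el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math(math_expr))

    for site in ("d", "u"):
        for rxn in network.reactions:
            law = rxn.rate_law
            factors = []
            if law.form == "mass_action":
                factors.append(law.k)
                for sp, n in rxn.reactants.items():
                    sid = f"{sp}__{site}"
                    factors.append(("power", sid, n) if n != 1 else sid)
            else:
                (sub,) = rxn.reactants
                sid = f"{sub}__{site}"
                factors.append(
                    ("divide", _times(law.vmax, sid), ("plus", law.km, sid))
                )
            mod_species = []
            for mod in rxn.modifiers:
                if mod.startswith("@"):
                    weights = network.groups[mod[1:]]
                    terms = [
                        _times(w, f"{sp}__{site}") for sp, w in weights.items()
                    ]
                    factors.append(("plus", *terms))
                    mod_species.extend(f"{sp}__{site}" for sp in weights)
                else:
                    factors.append(f"{mod}__{site}")
                    mod_species.append(f"{mod}__{site}")
            for gate in law.gates:
                factors.append(_gate_param_id(gate, site))
            add_reaction(
                f"{rxn.id}__{site}",
                [(f"{sp}__{site}", n) for sp, n in rxn.reactants.items()],
                [(f"{sp}__{site}", n) for sp, n in rxn.products.items()],
                mod_species,
                _times(*factors),
            )

    mrn_factor = ("plus", 1.0,
                  ("divide",
                   _times("k_mrn", "MRN__d", "DSB"),
                   ("plus", "K_dsb_sensor", "DSB")))
    for s in network.species:
        k_out = shuttling.k_out.get(s.id, 0.0)
        k_in = shuttling.k_in.get(s.id, 0.0)
        if k_out > 0:
            add_reaction(f"sh_out__{s.id}", [(f"{s.id}__d", 1)],
                         [(f"{s.id}__u", 1)], [],
                         _times(k_out, f"{s.id}__d"))
        if k_in > 0:
            expr = _times(k_in, f"{s.id}__u")
            mods = []
            if s.id in shuttling.mrn_enhanced:
                expr = _times(expr, mrn_factor)
                mods = ["MRN__d"]
            add_reaction(f"sh_in__{s.id}", [(f"{s.id}__u", 1)],
                         [(f"{s.id}__d", 1)], mods, expr)

    return ET.ElementTree(sbml)


def export_sbml(
    network: ReactionNetwork,
    shuttling: ShuttlingSpec,
    params: Parameters,
    path,
    protocol: AgentProtocol = AgentProtocol("IR", 1.0, 1.0),
) -> None:
    tree = sbml_document(network, shuttling, params, protocol)
    ET.indent(tree)
    tree.write(Path(path), xml_declaration=True, encoding="UTF-8")
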