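"""The reference ATM-activation reaction network.

The network is a single-compartment template instantiated by the simulator at
the DNA-damaged site and the undamaged site.  Its backbone is the
ATM:Tip60 holoenzyme: ATM associates stably with Tip60, so the pair is
bookkept as one entity whose state space is the product of

* dimer vs monomer (inactive dimer, kinase-active monomer),
* PP2A bound / free and Ser1981-autophosphorylated or not (dimers),
* phosphorylated / acetylated or not (monomers),
* the Tip60 face: ATF2-inhibited (``A``), free (``F``) or engaged on
  H3K9me3 (``H``), where H3K9me3 engagement both activates the HAT and
  tethers the holoenzyme to chromatin.

Activation proceeds by two routes.  The *initiative* route is purely
physical: local chromatin relaxation (gate on ``r``) dissociates
unphosphorylated dimers into active monomers.  The *primary* route is
chemical: ROS strips PP2A so the dimer keeps its autophosphorylation, active
ATM releases ATF2 from the Tip60 face, the free face binds H3K9me3 in relaxed
chromatin, and the in-cis acetylated phospho-dimer dissociates into
fully active acetyl-phospho monomers.  Phospho-dimers alone are *partially*
active: they phosphorylate p53/Chk2/MDM2/NBS1 but not H2AX or KAP-1.
"""

from __future__ import annotations

from typing import Mapping

from .network import (
    ConfigurationError,
    Gate,
    Reaction,
    ReactionNetwork,
    Species,
    mass_action,
    michaelis_menten,
)
from .params import Parameters

__all__ = [
    "FACES",
    "build_atm_network",
    "dimer_id",
    "monomer_id",
    "KINASE_ANY",
    "KINASE_FULL",
    "PATM_DIMER_IDS",
    "MONOMER_IDS",
]

FACES = ("A", "F", "H")  # Tip60 face: ATF2-bound, free, H3K9me3-bound
_FACE_NAME = {"A": "Tip60:ATF2", "F": "Tip60 free", "H": "Tip60:H3K9me3"}

KINASE_ANY = "kinase_any"    # partially + fully active ATM (p53/Chk2-class substrates)
KINASE_FULL = "kinase_full"  # fully active ATM monomers only (H2AX, KAP-1)


def dimer_id(pp2a: bool, phos: bool, face: str) -> str:
    parts = ["ATM_dim"]
    if pp2a:
        parts.append("pp2a")
    if phos:
        parts.append("p")
    parts.append(face)
    return "_".join(parts)


def monomer_id(phos: bool, acetyl: bool, face: str) -> str:
    parts = ["ATM_mon"]
    if phos:
        parts.append("p")
    if acetyl:
        parts.append("ac")
    parts.append(face)
    return "_".join(parts)


# dimer states kept in the model: resting PP2A-bound, its basal
# autophosphorylate, the ROS-released phospho-dimer, and the bare dimer
# produced by monomer re-association.  (PP2A-bound + phospho is the basal
# cycle intermediate; it is catalytically silent while PP2A is attached.)
_DIMER_STATES = [(True, False), (True, True), (False, True), (False, False)]
_MONOMER_STATES = [(p, a) for p in (False, True) for a in (False, True)]

PATM_DIMER_IDS = tuple(
    dimer_id(pp2a, phos, f)
    for (pp2a, phos) in _DIMER_STATES
    if phos
    for f in FACES
)
MONOMER_IDS = tuple(
    monomer_id(p, a, f) for (p, a) in _MONOMER_STATES for f in FACES
)


class _ParamView(dict):
    """Dict raising a configuration error naming the consumer on missing keys."""

    consumer = "species roster"

    def __missing__(self, key):
        raise ConfigurationError(
            f"{self.consumer}: missing parameter {key!r}"
        )


def _get(params: Mapping[str, float], key: str, rxn: str) -> float:
    try:
        return float(params[key])
    except KeyError:
        raise ConfigurationError(
            f"reaction {rxn!r}: missing rate parameter {key!r}"
        ) from None


def _species_roster(p: Mapping[str, float]) -> list[Species]:
    sp: list[Species] = []

    def holo_comp(n: int, pp2a: bool, face: str) -> dict[str, int]:
        comp = {"ATM": n, "Tip60": n}
        if pp2a:
            comp["PP2A"] = n
        if face == "A":
            comp["ATF2"] = n
        if face == "H":
            comp["H3K9me3"] = n
        return comp

    k_dephos = p["k_pp2a_dephos"]
    basal_p = p["init_atm"] * p["k_auto"] / k_dephos if k_dephos > 0 else 0.0
    dimer_init = {
        (True, False, "A"): p["init_atm"],
        (True, True, "A"): basal_p,
    }
    for pp2a, phos in _DIMER_STATES:
        for f in FACES:
            tag = []
            if pp2a:
                tag.append("PP2A-bound")
            if phos:
                tag.append("pSer1981")
            label = ", ".join(tag) if tag else "bare"
            sp.append(
                Species(
                    dimer_id(pp2a, phos, f),
                    f"ATM dimer ({label}, {_FACE_NAME[f]})",
                    "phospho" if phos else "dimer",
                    "chromatin-fixed" if f == "H" else "shuttling",
                    dimer_init.get((pp2a, phos, f), 0.0),
                    holo_comp(2, pp2a, f),
                )
            )
    for phos, ac in _MONOMER_STATES:
        for f in FACES:
            tag = []
            if phos:
                tag.append("pSer1981")
            if ac:
                tag.append("acetyl")
            label = ", ".join(tag) if tag else "plain"
            sp.append(
                Species(
                    monomer_id(phos, ac, f),
                    f"ATM monomer ({label}, {_FACE_NAME[f]})",
                    "acetyl-phospho" if (phos and ac) else "monomer",
                    "chromatin-fixed" if f == "H" else "shuttling",
                    0.0,
                    holo_comp(1, False, f),
                )
            )

    def simple(sid, name, form, mobility, init, comp):
        sp.append(Species(sid, name, form, mobility, init, comp))

    md_unbind = p["k_md_unbind"]
    mdm2_p53 = (
        p["k_md_bind"] * p["init_mdm2"] * p["init_p53"] / md_unbind
        if md_unbind > 0
        else 0.0
    )
    simple("ATF2", "ATF2 (free)", "free", "shuttling", p["init_atf2"], {"ATF2": 1})
    simple("pATF2", "phospho-ATF2", "phospho", "shuttling", 0.0, {"ATF2": 1})
    simple("H3K9me3", "H3K9me3 (exposed)", "free", "chromatin-fixed", 0.0,
           {"H3K9me3": 1})
    simple("HP1b_H3K9me3", "HP1beta/H3K9me3", "complex", "chromatin-fixed",
           p["init_hp1_h3"], {"HP1b": 1, "H3K9me3": 1})
    simple("HP1b", "HP1beta (displaced)", "free", "shuttling", 0.0, {"HP1b": 1})
    simple("pHP1b", "phospho-HP1beta", "phospho", "shuttling", 0.0, {"HP1b": 1})
    simple("KAP1", "KAP-1", "free", "shuttling", p["init_kap1"], {"KAP1": 1})
    simple("pKAP1", "phospho-KAP-1", "phospho", "shuttling", 0.0, {"KAP1": 1})
    simple("p53", "p53", "free", "shuttling", p["init_p53"], {"p53": 1})
    simple("pp53", "phospho-p53", "phospho", "shuttling", 0.0, {"p53": 1})
    simple("MDM2", "MDM2", "free", "shuttling", p["init_mdm2"], {"MDM2": 1})
    simple("pMDM2", "phospho-MDM2", "phospho", "shuttling", 0.0, {"MDM2": 1})
    simple("MDM2_p53", "MDM2/p53 complex", "complex", "shuttling", mdm2_p53,
           {"MDM2": 1, "p53": 1})
    simple("CHK2", "Chk2", "free", "shuttling", p["init_chk2"], {"Chk2": 1})
    simple("pCHK2", "phospho-Chk2", "phospho", "shuttling", 0.0, {"Chk2": 1})
    simple("NBS1", "NBS1", "free", "shuttling", p["init_nbs1"], {"NBS1": 1})
    simple("pNBS1", "phospho-NBS1", "phospho", "shuttling", 0.0, {"NBS1": 1})
    simple("H2AX", "H2AX", "free", "chromatin-fixed", p["init_h2ax"], {"H2AX": 1})
    simple("gH2AX", "gamma-H2AX", "phospho", "chromatin-fixed", 0.0, {"H2AX": 1})
    simple("PP2A", "PP2A (free)", "free", "shuttling", p["init_pp2a"], {"PP2A": 1})
    simple("CAV1", "Caveolin-1", "free", "shuttling", p["init_cav1"], {"Cav1": 1})
    simple("PP2A_CAV1", "PP2A/Caveolin-1", "complex", "shuttling", 0.0,
           {"PP2A": 1, "Cav1": 1})
    simple("CK2", "CK2 (constitutively active)", "free", "global",
           p["init_ck2"], {"CK2": 1})
    simple("MRN", "MRN complex", "free", "shuttling", p["init_mrn"], {"MRN": 1})
    return sp


def build_atm_network(params: Parameters | Mapping[str, float]) -> ReactionNetwork:
    """Build the reference ATM-activation network from a parameter set.

    Raises :class:`ConfigurationError` naming the reaction if a rate constant
    is missing, and :class:`ValidationError` if one is negative.
    """
    p = params.as_dict() if isinstance(params, Parameters) else dict(params)

    relax = Gate("relaxation", h=_get(p, "gate_h", "relaxation gates"))
    ros = Gate("ros", K=_get(p, "K_ros", "ROS gates"))

    rxns: list[Reaction] = []

    def add(rid, reactants, products, law, modifiers=()):
        rxns.append(Reaction(rid, reactants, products, law, tuple(modifiers)))

    for f in FACES:
        d_pp2a = dimer_id(True, False, f)
        d_pp2a_p = dimer_id(True, True, f)
        d_p = dimer_id(False, True, f)
        d_bare = dimer_id(False, False, f)
        m_plain = monomer_id(False, False, f)
        # (a) initiative monomerization: relaxation breaks the dimer interface
        add(f"ini_pp2a_{f}", {d_pp2a: 1}, {m_plain: 2, "PP2A": 2},
            mass_action(_get(p, "k_mono_init", f"ini_pp2a_{f}"), [relax]))
        add(f"ini_{f}", {d_bare: 1}, {m_plain: 2},
            mass_action(_get(p, "k_mono_init", f"ini_{f}"), [relax]))
        # (b) ROS-gated PP2A release (keeps the autophosphorylation) + reverses
        add(f"pp2a_rel_{f}", {d_pp2a: 1}, {d_p: 1, "PP2A": 2},
            mass_action(_get(p, "k_pp2a_release", f"pp2a_rel_{f}"), [ros]))
        add(f"pp2a_rel_p_{f}", {d_pp2a_p: 1}, {d_p: 1, "PP2A": 2},
            mass_action(_get(p, "k_pp2a_release", f"pp2a_rel_p_{f}"), [ros]))
        add(f"auto_{f}", {d_pp2a: 1}, {d_pp2a_p: 1},
            mass_action(_get(p, "k_auto", f"auto_{f}")))
        add(f"pp2a_deph_{f}", {d_pp2a_p: 1}, {d_pp2a: 1},
            mass_action(_get(p, "k_pp2a_dephos", f"pp2a_deph_{f}")))
        add(f"pp2a_bind_p_{f}", {d_p: 1, "PP2A": 2}, {d_pp2a: 1},
            mass_action(_get(p, "k_pp2a_rebind", f"pp2a_bind_p_{f}")))
        add(f"pp2a_bind_{f}", {d_bare: 1, "PP2A": 2}, {d_pp2a: 1},
            mass_action(_get(p, "k_pp2a_rebind", f"pp2a_bind_{f}")))
        # monomer re-association closes the cycle after the stimulus decays
        add(f"dimerize_{f}", {m_plain: 2}, {d_bare: 1},
            mass_action(_get(p, "k_dimerize", f"dimerize_{f}")))

    # (c)+(d) Tip60-face transitions, for every holoenzyme state
    face_states = [
        (dimer_id(pp2a, phos, "A"), dimer_id(pp2a, phos, "F"),
         dimer_id(pp2a, phos, "H"), 2)
        for pp2a, phos in _DIMER_STATES
    ] + [
        (monomer_id(ph, ac, "A"), monomer_id(ph, ac, "F"),
         monomer_id(ph, ac, "H"), 1)
        for ph, ac in _MONOMER_STATES
    ]
    for s_a, s_f, s_h, n in face_states:
        add(f"atf2_rel__{s_a}", {s_a: 1}, {s_f: 1, "pATF2": n},
            mass_action(_get(p, "k_atf2_release", f"atf2_rel__{s_a}")),
            ["@" + KINASE_ANY])
        add(f"atf2_bind__{s_f}", {s_f: 1, "ATF2": n}, {s_a: 1},
            mass_action(_get(p, "k_atf2_rebind", f"atf2_bind__{s_f}")))
        add(f"h3_bind__{s_f}", {s_f: 1, "H3K9me3": n}, {s_h: 1},
            mass_action(_get(p, "k_h3_bind", f"h3_bind__{s_f}"), [relax]))
        add(f"h3_unbind__{s_h}", {s_h: 1}, {s_f: 1, "H3K9me3": n},
            mass_action(_get(p, "k_h3_unbind", f"h3_unbind__{s_h}")))

    # (f) acetylation in cis on the H3K9me3-engaged face; primary monomerization
    for ph in (False, True):
        add(f"acetyl__{monomer_id(ph, False, 'H')}",
            {monomer_id(ph, False, "H"): 1}, {monomer_id(ph, True, "H"): 1},
            mass_action(_get(p, "k_acetyl", "acetyl")))
    for ph in (False, True):
        for f in FACES:
            add(f"deacetyl__{monomer_id(ph, True, f)}",
                {monomer_id(ph, True, f): 1}, {monomer_id(ph, False, f): 1},
                mass_action(_get(p, "k_deacetyl", "deacetyl")))
    for ac in (False, True):
        for f in FACES:
            add(f"mon_deph__{monomer_id(True, ac, f)}",
                {monomer_id(True, ac, f): 1}, {monomer_id(False, ac, f): 1},
                mass_action(_get(p, "k_mon_dephos", "mon_deph")))
    add("prim_mono", {dimer_id(False, True, "H"): 1},
        {monomer_id(True, True, "H"): 2},
        mass_action(_get(p, "k_mono_prim", "prim_mono")))

    # (e) CK2 displaces HP1beta from H3K9me3 in relaxed chromatin
    add("hp1_disp", {"HP1b_H3K9me3": 1}, {"pHP1b": 1, "H3K9me3": 1},
        mass_action(_get(p, "k_hp1_disp", "hp1_disp"), [relax]), ["CK2"])
    add("hp1_bind", {"HP1b": 1, "H3K9me3": 1}, {"HP1b_H3K9me3": 1},
        mass_action(_get(p, "k_hp1_rebind", "hp1_bind")))
    add("hp1_deph", {"pHP1b": 1}, {"HP1b": 1},
        mass_action(_get(p, "k_hp1_dephos", "hp1_deph")))

    # ROS sequesters PP2A on Caveolin-1
    add("cav_bind", {"PP2A": 1, "CAV1": 1}, {"PP2A_CAV1": 1},
        mass_action(_get(p, "k_cav_bind", "cav_bind"), [ros]))
    add("cav_unbind", {"PP2A_CAV1": 1}, {"PP2A": 1, "CAV1": 1},
        mass_action(_get(p, "k_cav_unbind", "cav_unbind")))

    # (g) substrate phosphorylation by the kinase pools
    for rid, sub, prod, key, pool in [
        ("phos_p53", "p53", "pp53", "k_p53", KINASE_ANY),
        ("phos_chk2", "CHK2", "pCHK2", "k_chk2", KINASE_ANY),
        ("phos_mdm2", "MDM2", "pMDM2", "k_mdm2", KINASE_ANY),
        ("phos_nbs1", "NBS1", "pNBS1", "k_nbs1", KINASE_ANY),
        ("phos_h2ax", "H2AX", "gH2AX", "k_h2ax", KINASE_FULL),
        ("phos_kap1", "KAP1", "pKAP1", "k_kap1", KINASE_FULL),
    ]:
        add(rid, {sub: 1}, {prod: 1}, mass_action(_get(p, key, rid)), ["@" + pool])

    # (h) reversion of every phospho-form
    add("deph_p53", {"pp53": 1}, {"p53": 1},
        michaelis_menten(_get(p, "v_p53_dephos", "deph_p53"),
                         _get(p, "km_p53_dephos", "deph_p53")))
    add("deph_chk2", {"pCHK2": 1}, {"CHK2": 1},
        michaelis_menten(_get(p, "v_chk2_dephos", "deph_chk2"),
                         _get(p, "km_chk2_dephos", "deph_chk2")))
    for rid, sub, prod, key in [
        ("deph_mdm2", "pMDM2", "MDM2", "k_mdm2_dephos"),
        ("deph_nbs1", "pNBS1", "NBS1", "k_nbs1_dephos"),
        ("deph_h2ax", "gH2AX", "H2AX", "k_h2ax_dephos"),
        ("deph_kap1", "pKAP1", "KAP1", "k_kap1_dephos"),
        ("deph_atf2", "pATF2", "ATF2", "k_atf2_dephos"),
    ]:
        add(rid, {sub: 1}, {prod: 1}, mass_action(_get(p, key, rid)))

    # MDM2 sequesters unphosphorylated p53
    add("md_bind", {"MDM2": 1, "p53": 1}, {"MDM2_p53": 1},
        mass_action(_get(p, "k_md_bind", "md_bind")))
    add("md_unbind", {"MDM2_p53": 1}, {"MDM2": 1, "p53": 1},
        mass_action(_get(p, "k_md_unbind", "md_unbind")))

    # kinase pools: dimers carry two kinase domains, monomers one.
    # PP2A-bound phospho-dimers are excluded (PP2A occludes the substrate
    # site); plain monomers are included (monomeric ATM is kinase-active
    # even when unphosphorylated).
    groups = {
        KINASE_ANY: {
            **{dimer_id(False, True, f): 2.0 for f in FACES},
            **{m: 1.0 for m in MONOMER_IDS},
        },
        KINASE_FULL: {m: 1.0 for m in MONOMER_IDS},
    }
    return ReactionNetwork(
        _species_roster(_ParamView(p)), rxns, groups, name="atm-reference"
    )
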