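"""Model parameters.

All quantities are dimensionless (amounts, rates and times alike); the
defaults are order 0.1-10 and are documented in ``docs/methods.md``.  Every
value can be overridden from a run configuration or programmatically via
:meth:`Parameters.with_overrides`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

from .network import ValidationError

__all__ = ["Parameters", "default_parameters"]


@dataclass(frozen=True)
class Parameters:
    # --- ATM holoenzyme core -------------------------------------------
    k_mono_init: float = 0.5      # initiative dimer -> 2 monomers (relaxation-gated)
    k_mono_prim: float = 2.0      # pATM dimer (Tip60 on H3K9me3) -> 2 ap-monomers
    k_dimerize: float = 5.0       # 2 plain monomers -> dimer
    k_auto: float = 0.1           # basal autophosphorylation of the PP2A-bound dimer
    k_pp2a_dephos: float = 2.0    # bound PP2A erases the basal autophosphorylation
    k_pp2a_release: float = 2.0   # ROS-gated PP2A release with autophosphorylation
    k_pp2a_rebind: float = 1.0    # PP2A rebinding (with dephosphorylation)
    k_cav_bind: float = 1.0       # ROS-gated PP2A sequestration by Caveolin-1
    k_cav_unbind: float = 0.5
    # --- Tip60 face / acetylation --------------------------------------
    k_atf2_release: float = 2.0   # active-ATM-catalysed ATF2 phosphorylation/release
    k_atf2_rebind: float = 0.5
    k_atf2_dephos: float = 0.2
    k_h3_bind: float = 2.0        # Tip60 face binds H3K9me3 (relaxation-gated)
    k_h3_unbind: float = 0.2
    k_acetyl: float = 2.0         # in-cis acetylation of the monomer (H3 face)
    k_deacetyl: float = 0.2
    k_mon_dephos: float = 0.2
    # --- HP1beta / H3K9me3 ---------------------------------------------
    k_hp1_disp: float = 2.0       # CK2-modified, relaxation-gated displacement
    k_hp1_rebind: float = 0.5
    k_hp1_dephos: float = 0.2
    # --- substrate phosphorylation (kinase pools as modifiers) ---------
    k_p53: float = 1.0
    k_chk2: float = 1.0
    k_mdm2: float = 0.5
    k_nbs1: float = 0.5
    k_h2ax: float = 1.0
    k_kap1: float = 0.5
    # --- reversion / dephosphorylation ----------------------------------
    v_p53_dephos: float = 0.3     # Michaelis-Menten phosphatase on p-p53
    km_p53_dephos: float = 0.5
    v_chk2_dephos: float = 0.3
    km_chk2_dephos: float = 0.5
    k_mdm2_dephos: float = 0.2
    k_nbs1_dephos: float = 0.2
    k_h2ax_dephos: float = 0.2
    k_kap1_dephos: float = 1.0
    # --- MDM2/p53 binding ------------------------------------------------
    k_md_bind: float = 1.0
    k_md_unbind: float = 1.0
    # --- gates -----------------------------------------------------------
    gate_h: float = 2.0           # relaxation gate = clip(r,0,1)**gate_h
    K_ros: float = 0.3            # ROS half-saturation of the PP2A-release gate
    # --- controls: DSB / ROS / relaxation dynamics ----------------------
    dsb_yield: float = 30.0       # DSBs per unit dose
    k_repair: float = 0.1         # first-order DSB repair (ATM-independent NHEJ)
    K_repair_atm: float = 0.1     # half-saturation of optional ATM-dependent repair
    k_ros_prod: float = 1.0
    k_ros_decay: float = 0.2
    k_rel_dsb: float = 0.5        # DSB-driven relaxation (damaged site only)
    k_rel_pkap: float = 1.0       # pKAP-1-driven relaxation (both sites)
    k_cond_kap: float = 0.3       # KAP-1-driven recondensation
    # --- shuttling -------------------------------------------------------
    k_sh: float = 0.5             # symmetric baseline exchange of mobile species
    k_sh_pkap: float = 5.0        # pKAP-1 spreads fast through the nucleus
    k_mrn: float = 4.0            # MRN recruitment enhancement amplitude
    K_dsb: float = 5.0            # DSB half-saturation of the MRN sensor
    # --- initial amounts (per site) --------------------------------------
    init_atm: float = 1.0         # resting PP2A-bound holoenzyme dimer
    init_pp2a: float = 0.5        # free PP2A
    init_cav1: float = 0.5
    init_atf2: float = 0.5        # free (unbound) ATF2
    init_hp1_h3: float = 1.0      # HP1beta/H3K9me3 heterochromatin complex
    init_kap1: float = 1.0
    init_p53: float = 0.5
    init_mdm2: float = 0.5
    init_chk2: float = 1.0
    init_nbs1: float = 0.5
    init_h2ax: float = 1.0
    init_ck2: float = 0.5
    init_mrn: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v >= 0):
                raise ValidationError(f"parameter {f.name!r} must be >= 0, got {v!r}")

    def with_overrides(self, overrides: Mapping[str, float]) -> "Parameters":
        """Return a copy with the named parameters replaced.

        Unknown names raise :class:`ConfigurationError`-style errors naming
        the offending key, so configuration typos never pass silently.
        """
        known = {f.name for f in fields(self)}
        bad = sorted(set(overrides) - known)
        if bad:
            raise ValidationError(f"unknown parameter(s): {', '.join(bad)}")
        return replace(self, **{k: float(v) for k, v in overrides.items()})

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def default_parameters() -> Parameters:
    """The reference parameter set."""
    return Parameters()
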