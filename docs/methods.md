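# atmkin — methods

## Scope and assumptions

`atmkin` is a deterministic (ODE) kinetic model of ATM activation after
exposure to DSB- and/or ROS-producing agents, focused on heterochromatin. It
makes the following structural assumptions:

* ATM is inactive as a dimer and kinase-active as a monomer; the monomer is
  active even when unphosphorylated, and the autophosphorylated dimer is only
  *partially* active (it phosphorylates p53, Chk2, MDM2 and NBS1 but not
  H2AX or KAP-1). Ser1981 stands in for the full set of autophosphorylation
  sites.
* ATM and Tip60 form a stable complex. The holoenzyme is bookkept as one
  entity whose sub-states are tracked combinatorially (below); there are no
  ATM–Tip60 binding/unbinding reactions.
* Chromatin state per site is summarised by a single relaxation rate
  `r ∈ [0, 1]`; 0 is fully compact, 1 fully relaxed. Reactions that require
  access to chromatin (Tip60·H3K9me3 engagement, CK2 phosphorylation of
  HP1β, the physical dimer-splitting effect of relaxation) carry a
  multiplicative gate `g(r) = r^h`.
* ROS↔DSB positive feedback is deliberately omitted, as are additional
  phosphorylation sites, euchromatin-specific behaviour, stochasticity, and
  spatial focus structure.

## State space

One compartment template holds 48 species. The ATM:Tip60 holoenzyme
contributes 24:

* **dimers** (12): PP2A-bound × Ser1981-phospho (the reachable combinations:
  resting PP2A-bound, its basal autophosphorylate, the ROS-released
  phospho-dimer, and the bare dimer formed by monomer re-association) × the
  Tip60 face, which is ATF2-inhibited (`A`), free (`F`) or engaged on
  H3K9me3 (`H`).
* **monomers** (12): phospho × acetyl × the same three Tip60 faces.

`H`-face states are tethered to the nucleosome and cannot shuttle. The
remaining 24 species are free/phospho forms of ATF2, HP1β, KAP-1, p53 (plus
the MDM2·p53 complex), MDM2, Chk2, NBS1, H2AX (chromatin-fixed), exposed
H3K9me3 and the HP1β·H3K9me3 complex (chromatin-fixed), PP2A, Caveolin-1 and
the PP2A·Caveolin-1 complex, CK2 (constitutively active, global), and MRN.

The full simulated state is `[X0 | X1 | DSB, ROS0, ROS1, r0, r1]` — 101
variables. Every species carries a protomer composition map; the resulting
14 conservation vectors (ATM/Tip60, PP2A, ATF2, H3K9me3, HP1β, KAP-1, p53,
MDM2, Chk2, NBS1, H2AX, Cav-1, CK2, MRN) exactly span the left null space of
the stoichiometric matrix and are monitored as an integration invariant.

## Reactions

Reversible steps are stored as two irreversible reactions. The main groups
(one compartment template; ~94 reactions):

* **Initiative monomerization** — unphosphorylated dimers split into two
  plain monomers, gated by `r^h` (PP2A is released in the same event).
* **PP2A/ROS branch** — the resting dimer basally autophosphorylates and
  bound PP2A erases it; under ROS (saturating gate `ROS/(K_ros+ROS)`) PP2A
  is released, leaving the partially active phospho-dimer; PP2A rebinding
  (second order in PP2A) reverses it. ROS additionally sequesters free PP2A
  on Caveolin-1.
* **Tip60 face transitions** — active ATM (kinase pool, below) releases
  pATF2 from the `A` face; the free face binds exposed H3K9me3 under the
  relaxation gate; both steps reverse. Applied uniformly to all holoenzyme
  states (dimers consume/release 2 ATF2 or H3K9me3, monomers 1).
* **Acetylation and primary monomerization** — the `H`-face Tip60 acetylates
  its own ATM in cis; the phospho-dimer with an engaged `H` face splits into
  two acetyl-phospho (fully active) monomers. Deacetylation, monomer
  dephosphorylation and re-dimerization of plain monomers close the cycle.
* **HP1β displacement** — CK2 (modifier) phosphorylates HP1β off H3K9me3,
  gated by relaxation ("CK2 is always active but cannot reach the histone in
  compact chromatin"); HP1β rebinds after dephosphorylation.
* **Substrate phosphorylation** — mass action in the substrate times a
  *kinase pool*: `kinase_any` (phospho-dimers weighted 2 for their two
  kinase domains, plus all monomers) phosphorylates p53, Chk2, MDM2, NBS1;
  `kinase_full` (monomers only) phosphorylates H2AX and KAP-1. Pools enter
  the rate law as a weighted sum — the one extension beyond plain
  modifier-product kinetics, chosen over duplicating each substrate reaction
  per catalytic species.
* **Reversion** — every phospho-form decays first order (p-p53 and p-Chk2
  via a saturable Michaelis–Menten phosphatase) so the system returns to its
  pre-stimulus equilibrium.

## Control dynamics

```
dDSB/dt = dsb_yield·DR·[t<T]·[agent produces DSBs] − k_repair·DSB
dROSi/dt = k_ros_prod·DR·[t<T]·[agent produces ROS] − k_ros_decay·ROSi
dr0/dt  = (k_rel_dsb·DSB + k_rel_pkap·pKAP1_0)·(1−r0) − k_cond_kap·KAP1_0·r0
dr1/dt  = (k_rel_pkap·pKAP1_1)·(1−r1) − k_cond_kap·KAP1_1·r1
```

The `(1−r)`/`r` factors guarantee `r ∈ [0, 1]` without clipping. The DSB
driver acts only at the damaged site; the undamaged site relaxes only
through pKAP-1 that has physically shuttled there (no action at a distance).
An oxidant produces no DSBs, hence no relaxation and no full activation —
the mechanistic source of the partial/full distinction. DSB repair is
ATM-independent first order by default; an optional mode scales repair by a
saturating function of total active monomer. ROS is treated as global (both
sites follow identical dynamics).

Shuttling is symmetric first-order exchange for all mobile species
(`k_sh`), fast for pKAP-1 (`k_sh_pkap`, it "spreads rapidly"), zero for
chromatin-fixed species, with ATM-containing mobile species receiving the
MRN sensor enhancement on recruitment into the damaged site:
`k_in · (1 + k_mrn·MRN·DSB/(K_dsb + DSB))`. The factor saturates in DSB, so
the per-break benefit of the sensor declines at high damage loads; in
absolute terms the with-MRN advantage does not shrink with dose under this
functional form — the *per-dose* benefit does, and that is the property the
test suite asserts.

## Parameters

All parameters are dimensionless, order 0.1–10, declared in
`atmkin.params.Parameters` with inline comments, and overridable everywhere
(config file, CLI `--set`, `with_overrides`). No fitted published table
exists for this system; the defaults were chosen once so that the canonical
qualitative phenotypes hold simultaneously:

* `dsb_yield = 30` — breaks per unit dose, the model's one quantitative
  anchor (~30 DSB/Gy); `k_repair = 0.1` so repair completes within the
  t = 100 horizon.
* `k_rel_dsb = 0.5` — with ~15 break-time-units accumulated during the unit
  exposure this relaxes the damaged site almost completely within t ≈ 1
  (the fast phase), leaving only slow pKAP-1-driven relaxation afterwards
  (the slow phase).
* Gate steepness `gate_h = 2`. With a linear gate the
  monomer → pKAP-1 → relaxation → monomerization loop is supercritical at
  zero damage (initiative flux scales like √r near r = 0 and always beats
  the condensation term, linear in r), so the activated state would be
  permanent. The quadratic gate makes the resting state attracting again;
  the loop-gain parameters (`k_kap1/k_kap1_dephos = 0.5`,
  `k_mono_init/k_dimerize = 0.1`, `k_rel_pkap = 1`, `k_cond_kap = 0.3`)
  keep the post-stimulus gain subcritical, giving transient global
  relaxation followed by slow recondensation (visible by t = 100, complete
  by t ≈ 300).
* `K_dsb = 5`, `k_mrn = 4` — the MRN sensor half-saturates at a few breaks,
  so it chiefly assists low-dose recruitment.
* Initial amounts put every protein at 0.5–1 per site; two balanced pairs
  are pre-equilibrated analytically (basal autophospho-dimer
  `= init_atm·k_auto/k_pp2a_dephos`; MDM2·p53
  `= k_md_bind·MDM2·p53/k_md_unbind`) so the shipped initial state is an
  exact fixed point of the unstimulated system (residual < 1e-8; every
  other resting flux is structurally zero because its reactants, gates or
  kinase pools are zero at rest).

## Numerics

* Stiff-capable implicit integration (`scipy.integrate.solve_ivp`, BDF) with
  `rtol = 1e-6`, `atol = 1e-9`; the integration is split at the exposure end
  `t = T` (the source terms are discontinuous there) and `T` is inserted
  into the output grid.
* The right-hand side is compiled to vectorised numpy (per-reaction index
  arrays, a modifier-pool matrix, mask-multiplied gate factors). A naive
  per-reaction pure-Python evaluator serves as an independent oracle in the
  tests (relative agreement < 1e-12 at random states).
* Inside the RHS, gate inputs are clamped to their domains and control
  feedback amounts floored at zero so tiny solver undershoots cannot
  produce negative fluxes; trajectories stay above −1e-6.
* Conservation: every moiety total (summed over both sites) stays constant
  along trajectories to well within 10× the integrator tolerance.
* Degenerate inputs: zero-rate parameters are allowed (the corresponding
  balanced initial amounts fall back to zero); empty exposure (`DR = 0` or
  `T = 0`) reduces to the sham fixed point; knockouts are implemented as
  zeroed initial amounts (`atm_null`, `mrn_null`).

## Readouts and classification

A scenario run is condensed to peak/time-of-peak/fold-change of eight
readouts (phospho-ATM dimer, active monomer, p-p53, p-Chk2, γH2AX, p-KAP-1,
r0, r1), with baseline taken at t = 0 of the pre-equilibrated state. Fold
changes are regularised as `(peak+ε)/(baseline+ε)` with `ε = 1e-6` because
most phospho-readouts have an exactly zero resting baseline (the
phospho-ATM dimer does not: the basal autophosphorylation cycle keeps a
small resting level, which is what makes its fold change informative).
Classification: *full* if the active monomer is elevated more than 2-fold,
*partial* if only the phospho-dimer is, *none* otherwise. The factor 2 is
not derived from data and is configurable.

## What the scenarios do and do not show

The shipped scenarios reproduce the canonical qualitative kinetics: DSB/ROS
pulse shapes, biphasic relaxation, recondensation after repair, global
(undamaged-site) relaxation, partial activation under pure oxidative
stress, full activation under IR and bleomycin (identical by construction at
matched dose), and dose-monotone peak activation. Because all quantities are
dimensionless and the rate constants are plausible rather than fitted,
agreement is qualitative: timing and amplitudes are not calibrated to any
specific cell line, absolute concentrations are arbitrary, and none of the
outputs should be read as predictions of measured blot intensities.

## Known limitations

* Single rectangular exposure pulse; no fractionation schedules.
* No ROS↔DSB feedback, hence none of the bistability it could produce.
* Heterochromatin only; the euchromatin variant would need a different
  baseline `r` and possibly an always-open H3K9me3 pool.
* The SBML export targets SBML L3 core only (no units, no annotations) and
  freezes one protocol into the rate rules; it is written by a minimal
  built-in XML emitter, not libsbml.
* `conserved_moieties` returns protomer-derived vectors when composition
  metadata is present; for bare networks it falls back to an exact rational
  left-null-space basis and reports only its nonnegative members.
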