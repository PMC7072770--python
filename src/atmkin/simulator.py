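"""Two-site assembly and numerical integration.

The full state vector is ``[X0, X1, DSB, ROS0, ROS1, r0, r1]`` where ``X0``
and ``X1`` are the template species at the damaged and undamaged site.  The
dynamics are

    dX0/dt = S R0(X0; r0, ROS0, DSB) - SH(X0, X1)
    dX1/dt = S R1(X1; r1, ROS1)      + SH(X0, X1)
    du/dt  = F(u, v; X)

with ``S`` the stoichiometric matrix, ``R`` the flux vector, ``SH`` the
antisymmetric shuttling term and ``F`` the control dynamics of
:mod:`atmkin.controls`.  Shuttling of ATM-containing species into the damaged
site is enhanced by the MRN sensor by a factor
``1 + k_mrn * MRN * DSB / (K_dsb + DSB)``, which saturates in DSB (so the
per-break benefit of the sensor fades at high damage loads).

The right-hand side is compiled to vectorised numpy operations; a naive
per-reaction evaluation lives in :func:`atmkin.network.reaction_fluxes` and
serves as its independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .controls import AgentProtocol, ControlState, agent_dose_rate
from .network import (
    ReactionNetwork,
    ValidationError,
    stoichiometric_matrix,
)
from .params import Parameters

__all__ = [
    "ShuttlingSpec",
    "SolverOptions",
    "SimulationResult",
    "AssemblyError",
    "IntegrationError",
    "reference_shuttling",
    "assemble_rhs",
    "shuttling_fluxes",
    "simulate",
    "steady_state_residual",
    "state_variable_names",
    "build_initial_state",
]

CONTROL_NAMES = ("DSB", "ROS0", "ROS1", "r0", "r1")


class AssemblyError(Exception):
    """Network and shuttling specification do not fit together."""


class IntegrationError(Exception):
    """Solver failure; carries the last successful time and state."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


@dataclass(frozen=True)
class ShuttlingSpec:
    """Per-species exchange rates between the two sites.

    ``k_out`` moves damaged -> undamaged, ``k_in`` the reverse; species in
    ``mrn_enhanced`` get ``k_in`` multiplied by the saturating MRN/DSB factor.
    Chromatin-fixed species must have both rates zero.
    """

    k_out: Mapping[str, float]
    k_in: Mapping[str, float]
    mrn_enhanced: frozenset = frozenset()
    k_mrn: float = 0.0
    K_dsb: float = 1.0
    mrn_species: str | None = "MRN"

    def enhancement(self, mrn: float, dsb: float) -> float:
        """MRN recruitment factor, increasing and saturating in DSB."""
        if self.k_mrn == 0.0:
            return 1.0
        dsb = max(dsb, 0.0)
        return 1.0 + self.k_mrn * max(mrn, 0.0) * dsb / (self.K_dsb + dsb)


def reference_shuttling(network: ReactionNetwork, params: Parameters) -> ShuttlingSpec:
    """Shuttling rates for the reference model.

    All mobile species exchange with the slow symmetric baseline ``k_sh``;
    pKAP-1 spreads fast (``k_sh_pkap``); chromatin-fixed and global species do
    not move.  ATM-containing mobile species additionally receive the
    MRN-enhanced recruitment to the damaged site.
    """
    k_out: dict[str, float] = {}
    k_in: dict[str, float] = {}
    enhanced = set()
    for s in network.species:
        if s.mobility != "shuttling":
            k_out[s.id] = k_in[s.id] = 0.0
            continue
        k = params.k_sh_pkap if s.id == "pKAP1" else params.k_sh
        k_out[s.id] = k_in[s.id] = k
        if s.composition.get("ATM", 0) > 0:
            enhanced.add(s.id)
    return ShuttlingSpec(
        k_out=k_out,
        k_in=k_in,
        mrn_enhanced=frozenset(enhanced),
        k_mrn=params.k_mrn,
        K_dsb=params.K_dsb,
    )


@dataclass(frozen=True)
class SolverOptions:
    method: str = "BDF"
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = np.inf


def state_variable_names(network: ReactionNetwork) -> list[str]:
    """Published, stable ordering of the full state vector."""
    return (
        [f"{s.id}@damaged" for s in network.species]
        + [f"{s.id}@undamaged" for s in network.species]
        + list(CONTROL_NAMES)
    )


def build_initial_state(
    network: ReactionNetwork, controls: ControlState | None = None
) -> np.ndarray:
    """Initial full state: the template amounts at both sites + controls."""
    x = network.initial_amounts()
    c = controls or ControlState()
    return np.concatenate([x, x, [c.dsb, c.ros0, c.ros1, c.r0, c.r1]])


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------


class _CompiledFluxes:
    """Vectorised flux evaluator for one compartment template."""

    def __init__(self, network: ReactionNetwork):
        n, nr = network.n_species, network.n_reactions
        idx = network.index
        max_slots = max(
            (len(r.reactants) for r in network.reactions), default=1
        )
        # reactant slots; unused slots point at a padded entry equal to 1
        self.slot_idx = np.full((max_slots, nr), n, dtype=int)
        self.slot_exp = np.zeros((max_slots, nr))
        self.k = np.zeros(nr)
        self.is_mm = np.zeros(nr, dtype=bool)
        self.vmax = np.zeros(nr)
        self.km = np.ones(nr)
        self.mm_sub = np.zeros(nr, dtype=int)
        self.has_mod = np.zeros(nr, dtype=bool)
        self.mod_matrix = np.zeros((nr, n))
        self.extra_mods: list[tuple[int, list[str]]] = []
        self.g_rel = np.zeros(nr, dtype=bool)
        self.g_rel_h = np.ones(nr)
        self.g_ros = np.zeros(nr, dtype=bool)
        self.g_ros_K = np.ones(nr)
        self.g_dsb = np.zeros(nr, dtype=bool)
        self.g_dsb_K = np.ones(nr)
        self.network = network
        for j, rxn in enumerate(network.reactions):
            law = rxn.rate_law
            if law.form == "mass_action":
                self.k[j] = law.k
                for s_no, (sp, st) in enumerate(rxn.reactants.items()):
                    self.slot_idx[s_no, j] = idx[sp]
                    self.slot_exp[s_no, j] = st
            else:
                self.is_mm[j] = True
                (sub,) = rxn.reactants
                self.mm_sub[j] = idx[sub]
                self.vmax[j] = law.vmax
                self.km[j] = law.km
            mods = list(rxn.modifiers)
            if len(mods) == 1:
                self.has_mod[j] = True
                m = mods[0]
                if m.startswith("@"):
                    for sp, w in network.groups[m[1:]].items():
                        self.mod_matrix[j, idx[sp]] += w
                else:
                    self.mod_matrix[j, idx[m]] += 1.0
            elif len(mods) > 1:
                self.extra_mods.append((j, mods))
            for gate in law.gates:
                if gate.kind == "relaxation":
                    self.g_rel[j] = True
                    self.g_rel_h[j] = gate.h
                elif gate.kind == "ros":
                    self.g_ros[j] = True
                    self.g_ros_K[j] = gate.K
                else:
                    self.g_dsb[j] = True
                    self.g_dsb_K[j] = gate.K

    def __call__(self, x: np.ndarray, r: float, ros: float, dsb: float) -> np.ndarray:
        xp = np.append(x, 1.0)
        flux = self.k * np.prod(xp[self.slot_idx] ** self.slot_exp, axis=0)
        if self.is_mm.any():
            s = x[self.mm_sub]
            flux = np.where(self.is_mm, self.vmax * s / (self.km + s), flux)
        if self.has_mod.any():
            mods = self.mod_matrix @ x
            flux = flux * np.where(self.has_mod, mods, 1.0)
        for j, mods in self.extra_mods:
            for m in mods:
                flux[j] *= self.network.modifier_value(m, x)
        if self.g_rel.any():
            rc = min(max(r, 0.0), 1.0)
            flux = flux * np.where(self.g_rel, rc**self.g_rel_h, 1.0)
        if self.g_ros.any():
            rosc = max(ros, 0.0)
            flux = flux * np.where(self.g_ros, rosc / (self.g_ros_K + rosc), 1.0)
        if self.g_dsb.any():
            dsbc = max(dsb, 0.0)
            flux = flux * np.where(self.g_dsb, dsbc / (self.g_dsb_K + dsbc), 1.0)
        return flux


def _shuttling_vectors(
    network: ReactionNetwork, shuttling: ShuttlingSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int | None]:
    missing = [s.id for s in network.species if s.id not in shuttling.k_out
               or s.id not in shuttling.k_in]
    if missing:
        raise AssemblyError(
            f"shuttling specification does not cover species: {missing}"
        )
    extra = sorted(
        (set(shuttling.k_out) | set(shuttling.k_in)) - set(network.index)
    )
    if extra:
        raise AssemblyError(f"shuttling names unknown species: {extra}")
    k_out = np.array([shuttling.k_out[s.id] for s in network.species])
    k_in = np.array([shuttling.k_in[s.id] for s in network.species])
    for s in network.species:
        if s.mobility != "shuttling" and (
            shuttling.k_out[s.id] != 0 or shuttling.k_in[s.id] != 0
        ):
            raise AssemblyError(
                f"species {s.id!r} is not mobile but has nonzero shuttling rates"
            )
    enhanced = np.array(
        [s.id in shuttling.mrn_enhanced for s in network.species], dtype=bool
    )
    mrn_idx = (
        network.index.get(shuttling.mrn_species)
        if shuttling.mrn_species
        else None
    )
    return k_out, k_in, enhanced, mrn_idx


def shuttling_fluxes(
    network: ReactionNetwork,
    x0: np.ndarray,
    x1: np.ndarray,
    controls: ControlState,
    shuttling: ShuttlingSpec,
) -> np.ndarray:
    """Net per-species transfer *into* the damaged site.

    ``transfer[s] = k_in_eff(s) * X1[s] - k_out(s) * X0[s]`` — antisymmetric
    by construction: whatever leaves one site arrives at the other.
    """
    k_out, k_in, enhanced, mrn_idx = _shuttling_vectors(network, shuttling)
    mrn = float(x0[mrn_idx]) if mrn_idx is not None else 0.0
    factor = shuttling.enhancement(mrn, controls.dsb)
    k_in_eff = np.where(enhanced, k_in * factor, k_in)
    return k_in_eff * np.asarray(x1, float) - k_out * np.asarray(x0, float)


def assemble_rhs(
    network: ReactionNetwork,
    shuttling: ShuttlingSpec,
    protocol: AgentProtocol,
    params: Parameters,
    repair_mode: str = "independent",
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the full two-site derivative function ``f(t, y)``.

    The returned callable is pure; ``repair_mode="atm"`` switches DSB repair
    to the optional ATM-dependent form (rate scaled by a saturating function
    of total active-ATM monomer).
    """
    if repair_mode not in ("independent", "atm"):
        raise ValidationError(f"unknown repair mode {repair_mode!r}")
    n = network.n_species
    S = stoichiometric_matrix(network).astype(float)
    fluxes = _CompiledFluxes(network)
    k_out, k_in, enhanced, mrn_idx = _shuttling_vectors(network, shuttling)
    kap_idx = network.index.get("KAP1")
    pkap_idx = network.index.get("pKAP1")
    monomer_idx = np.array(
        [i for i, s in enumerate(network.species)
         if s.form in ("monomer", "acetyl-phospho") and s.composition.get("ATM")],
        dtype=int,
    )
    makes_dsb, makes_ros = protocol.makes_dsb, protocol.makes_ros

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        x0 = y[:n]
        x1 = y[n : 2 * n]
        dsb, ros0, ros1, r0, r1 = y[2 * n : 2 * n + 5]
        dsb_c = max(dsb, 0.0)

        R0 = fluxes(x0, r0, ros0, dsb_c)
        R1 = fluxes(x1, r1, ros1, 0.0)
        dx0 = S @ R0
        dx1 = S @ R1

        mrn = float(x0[mrn_idx]) if mrn_idx is not None else 0.0
        k_in_eff = np.where(
            enhanced, k_in * shuttling.enhancement(mrn, dsb_c), k_in
        )
        transfer = k_in_eff * x1 - k_out * x0
        dx0 += transfer
        dx1 -= transfer

        dr_now = agent_dose_rate(protocol, t)
        repair = params.k_repair * dsb
        if repair_mode == "atm":
            act = float(x0[monomer_idx].sum() + x1[monomer_idx].sum())
            act = max(act, 0.0)
            repair *= act / (params.K_repair_atm + act)
        d_dsb = (params.dsb_yield * dr_now if makes_dsb else 0.0) - repair
        ros_prod = params.k_ros_prod * dr_now if makes_ros else 0.0
        d_ros0 = ros_prod - params.k_ros_decay * ros0
        d_ros1 = ros_prod - params.k_ros_decay * ros1

        kap0 = max(float(x0[kap_idx]), 0.0) if kap_idx is not None else 0.0
        kap1_ = max(float(x1[kap_idx]), 0.0) if kap_idx is not None else 0.0
        pkap0 = max(float(x0[pkap_idx]), 0.0) if pkap_idx is not None else 0.0
        pkap1_ = max(float(x1[pkap_idx]), 0.0) if pkap_idx is not None else 0.0
        d_r0 = (params.k_rel_dsb * dsb_c + params.k_rel_pkap * pkap0) * (
            1.0 - r0
        ) - params.k_cond_kap * kap0 * r0
        d_r1 = (params.k_rel_pkap * pkap1_) * (1.0 - r1) - (
            params.k_cond_kap * kap1_ * r1
        )
        return np.concatenate([dx0, dx1, [d_dsb, d_ros0, d_ros1, d_r0, d_r1]])

    return rhs


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Dense trajectories on a fixed grid, with solver metadata."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_vars)
    names: list[str]
    protocol: AgentProtocol
    options: SolverOptions
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.names)}

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self._index[name]]

    def species_total(self, sid: str) -> np.ndarray:
        """Amount of one template species summed over both sites."""
        return self.series(f"{sid}@damaged") + self.series(f"{sid}@undamaged")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: (time, site, variable, value); dimensionless units."""
        records = []
        for i, name in enumerate(self.names):
            if "@" in name:
                var, site = name.split("@")
            else:
                var, site = name, "control"
            records.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "site": site,
                        "variable": var,
                        "value": self.values[:, i],
                    }
                )
            )
        return pd.concat(records, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def simulate(
    network: ReactionNetwork,
    shuttling: ShuttlingSpec,
    protocol: AgentProtocol,
    params: Parameters,
    y0: np.ndarray | None = None,
    t_span: tuple[float, float] = (0.0, 100.0),
    n_points: int = 501,
    options: SolverOptions | None = None,
    repair_mode: str = "independent",
) -> SimulationResult:
    """Integrate the two-site system with a stiff-capable implicit method.

    The integration is split at the exposure end ``T`` (the source terms are
    discontinuous there) and ``T`` is inserted into the output grid.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t0 < t1:
        raise ValidationError(f"empty time span {t_span}")
    if y0 is None:
        y0 = build_initial_state(network)
    y0 = np.asarray(y0, dtype=float)
    n_expected = 2 * network.n_species + 5
    if y0.shape != (n_expected,):
        raise AssemblyError(
            f"initial state has length {y0.shape[0]}, expected {n_expected}"
        )
    if np.any(y0[: 2 * network.n_species] < 0):
        raise ValidationError("initial species amounts must be >= 0")
    opts = options or SolverOptions()
    rhs = assemble_rhs(network, shuttling, protocol, params, repair_mode)

    grid = np.linspace(t0, t1, int(n_points))
    T = protocol.exposure_time
    breaks = [t0]
    if t0 < T < t1 and protocol.dose_rate > 0 and protocol.agent != "none":
        grid = np.union1d(grid, [T])
        breaks.append(T)
    breaks.append(t1)

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    stats = {"nfev": 0, "njev": 0, "segments": len(breaks) - 1}
    y_cur = y0
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg = grid[(grid >= a) & (grid <= b)]
        if seg[0] != a:
            seg = np.insert(seg, 0, a)
        if seg[-1] != b:
            seg = np.append(seg, b)
        sol = solve_ivp(
            rhs,
            (a, b),
            y_cur,
            method=opts.method,
            t_eval=seg,
            rtol=opts.rtol,
            atol=opts.atol,
            max_step=opts.max_step,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed at t={sol.t[-1] if len(sol.t) else a}: "
                f"{sol.message}",
                t_last=float(sol.t[-1]) if len(sol.t) else a,
                y_last=sol.y[:, -1] if sol.y.size else y_cur,
            )
        stats["nfev"] += int(sol.nfev)
        stats["njev"] += int(getattr(sol, "njev", 0) or 0)
        keep = slice(1, None) if times else slice(None)
        times.append(sol.t[keep])
        states.append(sol.y[:, keep].T)
        y_cur = sol.y[:, -1]

    return SimulationResult(
        times=np.concatenate(times),
        values=np.vstack(states),
        names=state_variable_names(network),
        protocol=protocol,
        options=opts,
        stats=stats,
    )


def steady_state_residual(
    network: ReactionNetwork,
    shuttling: ShuttlingSpec,
    params: Parameters,
    state: np.ndarray | None = None,
) -> float:
    """Max |dy/dt| at a state under the sham (no-stimulus) protocol.

    Certifies that the shipped initial condition is a fixed point of the
    unstimulated system.
    """
    if state is None:
        state = build_initial_state(network)
    rhs = assemble_rhs(network, shuttling, AgentProtocol(), params)
    return float(np.max(np.abs(rhs(0.0, np.asarray(state, dtype=float)))))
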