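"""External control dynamics: DSB induction/repair, ROS, chromatin relaxation.

The controls ``u = (DSB, r0, ROS0, r1, ROS1)`` drive the reaction network
through the gate factors and evolve by their own ODEs ``du/dt = F(u, v; X)``,
where ``v`` is the damaging-agent protocol (a rectangular dose pulse) and the
feedback from the molecular state ``X`` enters through KAP-1/pKAP-1 (and,
optionally, active ATM for ATM-dependent repair).

Design of the relaxation law: with the relaxation rate ``r`` in [0, 1]
(0 = fully compact heterochromatin, 1 = fully relaxed),

    dr/dt = (k_rel_dsb * DSB * [damaged site] + k_rel_pkap * pKAP1) * (1 - r)
            - k_cond_kap * KAP1 * r

The (1 - r) / r factors make the bounds invariant without clipping: both
drivers vanish at r = 1 and condensation vanishes at r = 0.  The DSB term
acts only at the damaged site (the immediate, ATM-independent response);
pKAP-1 produced by active ATM drives relaxation wherever it has spread.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import ValidationError
from .params import Parameters

__all__ = [
    "AGENTS",
    "AgentProtocol",
    "ControlState",
    "agent_dose_rate",
    "dsb_dynamics",
    "ros_dynamics",
    "relaxation_dynamics",
]

AGENTS = ("IR", "BLM", "oxidant", "none")
_DSB_AGENTS = frozenset({"IR", "BLM"})
_ROS_AGENTS = frozenset({"IR", "BLM", "oxidant"})


@dataclass(frozen=True)
class AgentProtocol:
    """A rectangular exposure: dose rate ``DR`` for ``t`` in [0, T).

    IR and bleomycin produce both DSBs and ROS (bleomycin is radiomimetic);
    an oxidant produces ROS only, hence no DSBs and no damage-driven
    chromatin relaxation.
    """

    agent: str = "none"
    dose_rate: float = 0.0
    exposure_time: float = 0.0

    def __post_init__(self) -> None:
        if self.agent not in AGENTS:
            raise ValidationError(
                f"unknown agent {self.agent!r}; expected one of {AGENTS}"
            )
        if self.dose_rate < 0 or self.exposure_time < 0:
            raise ValidationError("dose_rate and exposure_time must be >= 0")

    @property
    def makes_dsb(self) -> bool:
        return self.agent in _DSB_AGENTS

    @property
    def makes_ros(self) -> bool:
        return self.agent in _ROS_AGENTS


@dataclass(frozen=True)
class ControlState:
    """Driving variables: DSB count (damaged site), ROS and r per site."""

    dsb: float = 0.0
    ros0: float = 0.0
    ros1: float = 0.0
    r0: float = 0.0
    r1: float = 0.0

    def __post_init__(self) -> None:
        if self.dsb < 0 or self.ros0 < 0 or self.ros1 < 0:
            raise ValidationError("DSB and ROS levels must be >= 0")
        if not (0 <= self.r0 <= 1 and 0 <= self.r1 <= 1):
            raise ValidationError("relaxation rates must lie in [0, 1]")


def agent_dose_rate(protocol: AgentProtocol, t: float) -> float:
    """Instantaneous dose rate: DR during the exposure window, 0 after."""
    if 0 <= t < protocol.exposure_time:
        return protocol.dose_rate
    return 0.0


def dsb_dynamics(
    t: float,
    dsb: float,
    protocol: AgentProtocol,
    params: Parameters,
    active_atm: float | None = None,
) -> float:
    """d(DSB)/dt: dose-proportional induction minus repair.

    Induction is ``dsb_yield * DR`` while the pulse is on, for DSB-producing
    agents only.  Default repair is first-order (ATM-independent NHEJ);
    passing ``active_atm`` switches to the ATM-dependent mode in which the
    repair rate scales with a saturating function of active ATM.
    """
    if dsb < 0:
        raise ValidationError(f"DSB count must be >= 0, got {dsb}")
    production = 0.0
    if protocol.makes_dsb:
        production = params.dsb_yield * agent_dose_rate(protocol, t)
    repair = params.k_repair * dsb
    if active_atm is not None:
        repair *= active_atm / (params.K_repair_atm + active_atm)
    return production - repair


def ros_dynamics(t: float, ros: float, protocol: AgentProtocol,
                 params: Parameters) -> float:
    """d(ROS)/dt: dose-proportional production minus first-order removal.

    ROS is global: the same law applies at both sites.
    """
    if ros < 0:
        raise ValidationError(f"ROS level must be >= 0, got {ros}")
    production = 0.0
    if protocol.makes_ros:
        production = params.k_ros_prod * agent_dose_rate(protocol, t)
    return production - params.k_ros_decay * ros


def relaxation_dynamics(
    r: float,
    dsb: float,
    kap1: float,
    pkap1: float,
    site: str,
    params: Parameters,
) -> float:
    """dr/dt with guaranteed invariance of [0, 1] (see module docstring)."""
    if not (0.0 <= r <= 1.0):
        raise ValidationError(f"relaxation rate must lie in [0, 1], got {r}")
    if dsb < 0 or kap1 < 0 or pkap1 < 0:
        raise ValidationError("DSB and KAP-1 amounts must be >= 0")
    if site not in ("damaged", "undamaged"):
        raise ValidationError(f"unknown site {site!r}")
    drive = params.k_rel_pkap * pkap1
    if site == "damaged":
        drive += params.k_rel_dsb * dsb
    return drive * (1.0 - r) - params.k_cond_kap * kap1 * r
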