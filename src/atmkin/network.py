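"""Reaction-network core: species, reactions, rate laws, stoichiometry.

A :class:`ReactionNetwork` is a single-compartment *template*: the simulator
instantiates it once per chromatin site (damaged / undamaged) and couples the
two copies by shuttling.  Rate laws are mass action or Michaelis–Menten,
optionally multiplied by bounded *gate* factors driven by the external
controls (chromatin relaxation rate ``r``, ROS level, DSB count).

Species carry a ``composition`` map counting how many protomers of each
conserved protein moiety (ATM, Tip60, KAP1, ...) they contain; every reaction
must balance these counts, which yields the conservation laws used as a
structural test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Gate",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "SiteControls",
    "Diagnostic",
    "NetworkError",
    "ConfigurationError",
    "ValidationError",
    "mass_action",
    "michaelis_menten",
    "relaxation_gate",
    "ros_gate",
    "dsb_gate",
    "stoichiometric_matrix",
    "reaction_fluxes",
    "conserved_moieties",
    "validate_network",
]

FORMS = ("free", "dimer", "monomer", "complex", "phospho", "acetyl-phospho")
MOBILITIES = ("shuttling", "chromatin-fixed", "global")
GATE_KINDS = ("relaxation", "ros", "dsb")


class NetworkError(Exception):
    """Base class for model-definition problems."""


class ConfigurationError(NetworkError):
    """A required parameter is missing (names the offending reaction)."""


class ValidationError(NetworkError):
    """A supplied value violates a model invariant (e.g. negative rate)."""


def _frozen(mapping: Mapping) -> Mapping:
    return MappingProxyType(dict(mapping))


@dataclass(frozen=True)
class Species:
    """One molecular state of the compartment template.

    ``composition`` counts conserved protomers, e.g. an ATM holoenzyme dimer
    has ``{"ATM": 2, "Tip60": 2, ...}``.  ``mobility`` controls shuttling:
    chromatin-fixed species (nucleosome marks and anything tethered to them)
    never move between sites.
    """

    id: str
    name: str
    form: str
    mobility: str
    initial_amount: float
    composition: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValidationError(f"species {self.id!r}: unknown form {self.form!r}")
        if self.mobility not in MOBILITIES:
            raise ValidationError(
                f"species {self.id!r}: unknown mobility {self.mobility!r}"
            )
        if not (self.initial_amount >= 0):
            raise ValidationError(
                f"species {self.id!r}: initial amount must be >= 0, "
                f"got {self.initial_amount}"
            )
        object.__setattr__(self, "composition", _frozen(self.composition))

    def __eq__(self, other) -> bool:  # MappingProxy lacks __eq__ symmetry with dict
        if not isinstance(other, Species):
            return NotImplemented
        return (
            self.id == other.id
            and self.name == other.name
            and self.form == other.form
            and self.mobility == other.mobility
            and self.initial_amount == other.initial_amount
            and dict(self.composition) == dict(other.composition)
        )

    def __hash__(self) -> int:
        return hash(self.id)


@dataclass(frozen=True)
class Gate:
    """Multiplicative control factor in [0, 1].

    kinds:
      * ``relaxation`` — ``clip(r, 0, 1) ** h``; zero in compact chromatin
        (r = 0), one when fully relaxed (r = 1).
      * ``ros`` — ``ROS / (K + ROS)``, saturating in the ROS level.
      * ``dsb`` — ``DSB / (K + DSB)``, saturating in the break count.
    """

    kind: str
    h: float = 1.0
    K: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise ValidationError(f"unknown gate kind {self.kind!r}")
        if self.h < 0 or self.K < 0:
            raise ValidationError(f"gate {self.kind}: parameters must be >= 0")

    def __call__(self, controls: "SiteControls") -> float:
        if self.kind == "relaxation":
            r = min(max(controls.r, 0.0), 1.0)
            return r**self.h
        if self.kind == "ros":
            ros = max(controls.ros, 0.0)
            return ros / (self.K + ros)
        dsb = max(controls.dsb, 0.0)
        return dsb / (self.K + dsb)


def relaxation_gate(h: float = 1.0) -> Gate:
    return Gate("relaxation", h=h)


def ros_gate(K: float) -> Gate:
    return Gate("ros", K=K)


def dsb_gate(K: float) -> Gate:
    return Gate("dsb", K=K)


@dataclass(frozen=True)
class RateLaw:
    """Mass-action (``k``) or Michaelis–Menten (``vmax``, ``km``) kinetics.

    Mass action:        flux = k * prod(reactant ** stoich) * modifiers * gates
    Michaelis–Menten:   flux = vmax * [S] / (km + [S]) * modifiers * gates
    (the MM substrate is the reaction's single reactant).
    """

    form: str
    k: float | None = None
    vmax: float | None = None
    km: float | None = None
    gates: tuple[Gate, ...] = ()

    def __post_init__(self) -> None:
        if self.form == "mass_action":
            if self.k is None or self.k < 0:
                raise ValidationError("mass_action law requires k >= 0")
        elif self.form == "michaelis_menten":
            if self.vmax is None or self.vmax < 0 or self.km is None or self.km < 0:
                raise ValidationError("michaelis_menten law requires vmax, km >= 0")
        else:
            raise ValidationError(f"unknown rate-law form {self.form!r}")
        object.__setattr__(self, "gates", tuple(self.gates))


def mass_action(k: float, gates: Iterable[Gate] = ()) -> RateLaw:
    return RateLaw("mass_action", k=k, gates=tuple(gates))


def michaelis_menten(vmax: float, km: float, gates: Iterable[Gate] = ()) -> RateLaw:
    return RateLaw("michaelis_menten", vmax=vmax, km=km, gates=tuple(gates))


@dataclass(frozen=True)
class Reaction:
    """An irreversible reaction (reversible pairs are stored as two of these).

    ``modifiers`` are species ids, or group ids prefixed with ``@``; a group's
    value is the weighted sum of its member amounts (kinase pools).  Modifiers
    multiply the flux but are not consumed.
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_law: RateLaw
    modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for side, name in ((self.reactants, "reactant"), (self.products, "product")):
            for sp, n in side.items():
                if not (isinstance(n, (int, np.integer)) and n >= 1):
                    raise ValidationError(
                        f"reaction {self.id!r}: {name} stoichiometry for "
                        f"{sp!r} must be a positive integer, got {n!r}"
                    )
        if self.rate_law.form == "michaelis_menten" and len(self.reactants) != 1:
            raise ValidationError(
                f"reaction {self.id!r}: Michaelis-Menten requires one reactant"
            )
        object.__setattr__(self, "reactants", _frozen(self.reactants))
        object.__setattr__(self, "products", _frozen(self.products))
        object.__setattr__(self, "modifiers", tuple(self.modifiers))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Reaction):
            return NotImplemented
        return (
            self.id == other.id
            and dict(self.reactants) == dict(other.reactants)
            and dict(self.products) == dict(other.products)
            and self.rate_law == other.rate_law
            and self.modifiers == other.modifiers
        )

    def __hash__(self) -> int:
        return hash(self.id)


@dataclass(frozen=True)
class SiteControls:
    """Control variables seen by one compartment: (r, ROS, DSB)."""

    r: float = 0.0
    ros: float = 0.0
    dsb: float = 0.0


class ReactionNetwork:
    """Ordered species + reactions + modifier groups for one compartment."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        groups: Mapping[str, Mapping[str, float]] | None = None,
        name: str = "model",
    ) -> None:
        self.name = name
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.groups = {g: dict(w) for g, w in (groups or {}).items()}
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate species ids: {dup}")
        self.index = {s.id: i for i, s in enumerate(self.species)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_by_id(self, sid: str) -> Species:
        return self.species[self.index[sid]]

    def initial_amounts(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def moiety_names(self) -> list[str]:
        names: list[str] = []
        for s in self.species:
            for m in s.composition:
                if m not in names:
                    names.append(m)
        return names

    def modifier_value(self, mod: str, state: np.ndarray) -> float:
        """Amount of a modifier: a species, or an ``@group`` weighted sum."""
        if mod.startswith("@"):
            weights = self.groups[mod[1:]]
            return float(
                sum(w * state[self.index[sp]] for sp, w in weights.items())
            )
        return float(state[self.index[mod]])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.name == other.name
            and self.species == other.species
            and self.reactions == other.reactions
            and self.groups == other.groups
        )

    def __repr__(self) -> str:
        return (
            f"<ReactionNetwork {self.name!r}: {self.n_species} species, "
            f"{self.n_reactions} reactions>"
        )


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer species x reactions matrix, column = products - reactants."""
    S = np.zeros((network.n_species, network.n_reactions), dtype=int)
    for j, rxn in enumerate(network.reactions):
        for sp, n in rxn.reactants.items():
            S[network.index[sp], j] -= n
        for sp, n in rxn.products.items():
            S[network.index[sp], j] += n
    return S


def reaction_fluxes(
    network: ReactionNetwork,
    state: np.ndarray,
    controls: SiteControls = SiteControls(),
) -> np.ndarray:
    """Evaluate all reaction fluxes at a nonnegative state.

    This is the straightforward (per-reaction) evaluation; the simulator
    compiles a vectorised equivalent for speed.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValidationError(
            f"state has length {state.shape}, expected {network.n_species}"
        )
    if np.any(state < 0):
        bad = network.species[int(np.argmin(state))].id
        raise ValidationError(f"negative amount for species {bad!r}")
    R = np.empty(network.n_reactions)
    for j, rxn in enumerate(network.reactions):
        law = rxn.rate_law
        if law.form == "mass_action":
            flux = law.k
            for sp, n in rxn.reactants.items():
                flux *= state[network.index[sp]] ** n
        else:
            (sub,) = rxn.reactants
            s = state[network.index[sub]]
            flux = law.vmax * s / (law.km + s) if (law.km + s) > 0 else 0.0
        for mod in rxn.modifiers:
            flux *= network.modifier_value(mod, state)
        for gate in law.gates:
            flux *= gate(controls)
        R[j] = flux
    return R


def _composition_vectors(network: ReactionNetwork) -> dict[str, np.ndarray]:
    vecs: dict[str, np.ndarray] = {}
    for m in network.moiety_names():
        c = np.zeros(network.n_species, dtype=int)
        for i, s in enumerate(network.species):
            c[i] = s.composition.get(m, 0)
        vecs[m] = c
    return vecs


def _rational_left_nullspace(S: np.ndarray) -> list[np.ndarray]:
    """Exact left-null-space basis of an integer matrix via fraction RREF."""
    A = [[Fraction(int(v)) for v in row] for row in S.T]  # solve A c = 0
    n = S.shape[0]
    m = len(A)
    # Gauss-Jordan elimination over Q
    pivots: list[int] = []
    r = 0
    for c in range(n):
        piv = next((i for i in range(r, m) if A[i][c] != 0), None)
        if piv is None:
            continue
        A[r], A[piv] = A[piv], A[r]
        inv = A[r][c]
        A[r] = [v / inv for v in A[r]]
        for i in range(m):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [vi - f * vr for vi, vr in zip(A[i], A[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fcol in free:
        v = [Fraction(0)] * n
        v[fcol] = Fraction(1)
        for i, pc in enumerate(pivots):
            v[pc] = -A[i][fcol]
        den = 1
        for x in v:
            den = den * x.denominator // np.gcd(den, x.denominator)
        iv = np.array([int(x * den) for x in v], dtype=int)
        if np.all(iv <= 0):
            iv = -iv
        basis.append(iv)
    return basis


def conserved_moieties(network: ReactionNetwork) -> list[dict]:
    """Conservation vectors c with c.T @ S = 0.

    When species carry ``composition`` metadata the vectors are the protomer
    counts per conserved protein (weights 2 on dimer forms etc.), verified
    against the stoichiometric matrix; duplicated vectors (e.g. two proteins
    locked in the same complexes everywhere) are reported once with a joint
    name.  Without composition metadata, an exact rational left-null-space
    basis is returned (unnamed).
    """
    S = stoichiometric_matrix(network)
    comp = _composition_vectors(network)
    if comp:
        out: list[dict] = []
        for m, c in comp.items():
            if np.any(c.T @ S != 0):
                raise ValidationError(
                    f"moiety {m!r} is not conserved by the reaction list"
                )
            for entry in out:
                if np.array_equal(entry["vector"], c):
                    entry["moiety"] = entry["moiety"] + "/" + m
                    break
            else:
                out.append({"moiety": m, "vector": c})
        return out
    return [
        {"moiety": None, "vector": v}
        for v in _rational_left_nullspace(S)
        if np.all(v >= 0) and np.any(v > 0)
    ]


@dataclass(frozen=True)
class Diagnostic:
    code: str
    subject: str
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.subject}: {self.message}"


def _reachable_species(network: ReactionNetwork) -> set[str]:
    have = {s.id for s in network.species if s.initial_amount > 0}
    changed = True
    while changed:
        changed = False
        for rxn in network.reactions:
            need = set(rxn.reactants)
            for mod in rxn.modifiers:
                if mod.startswith("@"):
                    members = set(network.groups.get(mod[1:], {}))
                    if members and not (members & have):
                        need.add(next(iter(members - have)))
                elif mod in network.index:
                    need.add(mod)
            if need <= have:
                new = set(rxn.products) - have
                if new:
                    have |= new
                    changed = True
    return have


def validate_network(network: ReactionNetwork) -> list[Diagnostic]:
    """Structural diagnostics; the shipped reference model reports none.

    Checks: dangling species references, protomer (moiety) imbalance,
    negative rate parameters, and species unreachable from the initial
    support.  Returns a list of findings; empty means valid.
    """
    out: list[Diagnostic] = []
    known = set(network.index)
    for gname, weights in network.groups.items():
        for sp in weights:
            if sp not in known:
                out.append(
                    Diagnostic(
                        "dangling-reference",
                        f"group {gname}",
                        f"references unknown species {sp!r}",
                    )
                )
    for rxn in network.reactions:
        for sp in list(rxn.reactants) + list(rxn.products):
            if sp not in known:
                out.append(
                    Diagnostic(
                        "dangling-reference",
                        rxn.id,
                        f"references unknown species {sp!r}",
                    )
                )
        for mod in rxn.modifiers:
            if mod.startswith("@"):
                if mod[1:] not in network.groups:
                    out.append(
                        Diagnostic(
                            "dangling-reference",
                            rxn.id,
                            f"references unknown group {mod!r}",
                        )
                    )
            elif mod not in known:
                out.append(
                    Diagnostic(
                        "dangling-reference",
                        rxn.id,
                        f"references unknown modifier {mod!r}",
                    )
                )
        law = rxn.rate_law
        params = [p for p in (law.k, law.vmax, law.km) if p is not None]
        if any(p < 0 for p in params):
            out.append(
                Diagnostic("negative-parameter", rxn.id, "rate parameter < 0")
            )
        # protomer balance over every moiety present in the participants
        if all(sp in known for sp in list(rxn.reactants) + list(rxn.products)):
            moieties: set[str] = set()
            for sp in list(rxn.reactants) + list(rxn.products):
                moieties |= set(network.species_by_id(sp).composition)
            for m in moieties:
                lhs = sum(
                    n * network.species_by_id(sp).composition.get(m, 0)
                    for sp, n in rxn.reactants.items()
                )
                rhs = sum(
                    n * network.species_by_id(sp).composition.get(m, 0)
                    for sp, n in rxn.products.items()
                )
                if lhs != rhs:
                    out.append(
                        Diagnostic(
                            "protomer-imbalance",
                            rxn.id,
                            f"moiety {m!r}: {lhs} on the left, {rhs} on the right",
                        )
                    )
    if not any(d.code == "dangling-reference" for d in out):
        reachable = _reachable_species(network)
        for s in network.species:
            if s.id not in reachable:
                out.append(
                    Diagnostic(
                        "unreachable-species",
                        s.id,
                        "not producible from the initial support",
                    )
                )
    return out
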