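"""Structure of the reaction network: stoichiometry, fluxes, conservation."""

import numpy as np
import pytest
import sympy
from hypothesis import given, strategies as st

from atmkin import (
    ConfigurationError,
    Gate,
    Reaction,
    ReactionNetwork,
    SiteControls,
    Species,
    ValidationError,
    build_atm_network,
    conserved_moieties,
    default_parameters,
    mass_action,
    reaction_fluxes,
    stoichiometric_matrix,
    validate_network,
)
from atmkin.reference import FACES, MONOMER_IDS, dimer_id, monomer_id


def _toy(reactions, species_ids, initial=1.0):
    species = [
        Species(s, s, "free", "shuttling", initial, {}) for s in species_ids
    ]
    return ReactionNetwork(species, reactions, name="toy")


# --- stoichiometric matrix -------------------------------------------------


@pytest.mark.parametrize(
    "reactants,products,expected",
    [
        ({"A": 1}, {"B": 1}, [-1, 1, 0]),
        ({"A": 1, "B": 1}, {"C": 1}, [-1, -1, 1]),
    ],
)
def test_stoichiometry_column_is_products_minus_reactants(
    reactants, products, expected
):
    net = _toy([Reaction("r", reactants, products, mass_action(1.0))],
               ["A", "B", "C"])
    S = stoichiometric_matrix(net)
    assert S[:, 0].tolist() == expected


def test_monomerization_column_minus_one_dimer_plus_two_monomers(network):
    """The initiative reaction splits one dimer into two monomers."""
    S = stoichiometric_matrix(network)
    j = [r.id for r in network.reactions].index("ini_pp2a_A")
    col = S[:, j]
    assert col[network.index[dimer_id(True, False, "A")]] == -1
    assert col[network.index[monomer_id(False, False, "A")]] == 2
    assert col[network.index["PP2A"]] == 2


# --- fluxes ----------------------------------------------------------------


def test_mass_action_flux_hand_value():
    """A + B -> C with k=2, [A]=1, [B]=3 gives flux 2*1*3 = 6."""
    net = _toy([Reaction("r", {"A": 1, "B": 1}, {"C": 1}, mass_action(2.0))],
               ["A", "B", "C"])
    R = reaction_fluxes(net, np.array([1.0, 3.0, 0.0]))
    assert R[0] == pytest.approx(6.0)


def test_zero_state_gives_zero_fluxes(network):
    R = reaction_fluxes(network, np.zeros(network.n_species))
    assert np.all(R == 0.0)


def test_zero_reactant_annihilates_flux(network, rng):
    state = rng.uniform(0.1, 2.0, network.n_species)
    for j, rxn in enumerate(network.reactions):
        zeroed = state.copy()
        zeroed[network.index[next(iter(rxn.reactants))]] = 0.0
        R = reaction_fluxes(net := network, zeroed, SiteControls(0.5, 0.5, 5.0))
        assert R[j] == 0.0


def test_fluxes_nonnegative_at_random_states(network, rng):
    for _ in range(20):
        state = rng.uniform(0.0, 3.0, network.n_species)
        controls = SiteControls(
            r=rng.uniform(0, 1), ros=rng.uniform(0, 2), dsb=rng.uniform(0, 40)
        )
        assert np.all(reaction_fluxes(network, state, controls) >= 0.0)


def test_negative_amount_rejected(network):
    state = np.zeros(network.n_species)
    state[0] = -0.1
    with pytest.raises(ValidationError, match="negative"):
        reaction_fluxes(network, state)


def test_relaxation_gated_fluxes_zero_in_compact_chromatin(network, rng):
    """At r = 0 every relaxation-gated reaction is silent; at r = 1 the gate
    is fully open (flux equals the ungated product)."""
    state = rng.uniform(0.5, 1.5, network.n_species)
    gated = [
        j for j, r in enumerate(network.reactions)
        if any(g.kind == "relaxation" for g in r.rate_law.gates)
    ]
    assert gated
    closed = reaction_fluxes(network, state, SiteControls(r=0.0))
    assert np.all(closed[gated] == 0.0)
    open_ = reaction_fluxes(network, state, SiteControls(r=1.0))
    assert np.all(open_[gated] > 0.0)


@given(
    r=st.floats(0, 1),
    ros=st.floats(0, 1e6),
    dsb=st.floats(0, 1e9),
    h=st.floats(0.5, 4),
    K=st.floats(1e-3, 10),
)
def test_gate_factors_bounded_in_unit_interval(r, ros, dsb, h, K):
    c = SiteControls(r=r, ros=ros, dsb=dsb)
    for gate in (Gate("relaxation", h=h), Gate("ros", K=K), Gate("dsb", K=K)):
        assert 0.0 <= gate(c) <= 1.0


@given(a=st.floats(0, 50), b=st.floats(0, 50), other=st.floats(0, 10))
def test_mass_action_flux_monotone_in_reactant(a, b, other):
    net = _toy([Reaction("r", {"A": 1, "B": 2}, {"C": 1}, mass_action(1.3))],
               ["A", "B", "C"])
    lo, hi = sorted([a, b])
    f_lo = reaction_fluxes(net, np.array([lo, other, 0.0]))[0]
    f_hi = reaction_fluxes(net, np.array([hi, other, 0.0]))[0]
    assert f_lo <= f_hi


# --- conservation laws -----------------------------------------------------


def test_moieties_span_left_nullspace(network, stoich):
    """Independent oracle: the rational left null space of S (sympy) has the
    same dimension as the moiety list, and every moiety vector lies in it."""
    nullspace = sympy.Matrix(stoich.T).nullspace()
    moieties = conserved_moieties(network)
    assert len(nullspace) == len(moieties)
    basis = sympy.Matrix.hstack(*nullspace)
    for m in moieties:
        c = sympy.Matrix(m["vector"])
        assert basis.row_join(c).rank() == basis.rank()
        assert not np.any(m["vector"] @ stoich)


def test_atm_moiety_counts_two_protomers_per_dimer(network, stoich):
    """The ATM conservation vector weights dimers 2, monomers 1, and its
    support is exactly the ATM-containing species."""
    (atm,) = [m for m in conserved_moieties(network) if "ATM" in m["moiety"]]
    c = atm["vector"]
    for i, s in enumerate(network.species):
        expected = 2 if s.id.startswith("ATM_dim") else (
            1 if s.id.startswith("ATM_mon") else 0
        )
        assert c[i] == expected, s.id
    assert not np.any(c @ stoich)


def test_protomer_balance_every_reaction(network):
    for rxn in network.reactions:
        moieties = set()
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
            assert lhs == rhs, (rxn.id, m)


def test_toy_interconversion_moiety():
    """A <-> B conserves A+B; an open system A -> 0 conserves nothing of A."""
    closed = _toy(
        [
            Reaction("f", {"A": 1}, {"B": 1}, mass_action(1.0)),
            Reaction("b", {"B": 1}, {"A": 1}, mass_action(1.0)),
        ],
        ["A", "B"],
    )
    vecs = [m["vector"].tolist() for m in conserved_moieties(closed)]
    assert vecs == [[1, 1]]
    open_net = _toy([Reaction("out", {"A": 1}, {}, mass_action(1.0))], ["A"])
    assert conserved_moieties(open_net) == []


# --- model scale and validation -------------------------------------------


def test_reference_network_is_clean(network):
    assert validate_network(network) == []


def test_validate_reports_dangling_reference():
    net = _toy([Reaction("r", {"A": 1}, {"ghost": 1}, mass_action(1.0))], ["A"])
    diags = validate_network(net)
    assert [d.code for d in diags] == ["dangling-reference"]
    assert "ghost" in diags[0].message


def test_validate_reports_protomer_imbalance():
    """An ATM dimer cannot split into a single monomer."""
    species = [
        Species("dim", "dimer", "dimer", "shuttling", 1.0, {"ATM": 2}),
        Species("mon", "monomer", "monomer", "shuttling", 0.0, {"ATM": 1}),
    ]
    net = ReactionNetwork(
        species,
        [Reaction("split", {"dim": 1}, {"mon": 1}, mass_action(1.0))],
    )
    diags = validate_network(net)
    assert any(d.code == "protomer-imbalance" for d in diags)


def test_validate_reports_unreachable_species():
    species = [
        Species("A", "A", "free", "shuttling", 1.0, {}),
        Species("B", "B", "free", "shuttling", 0.0, {}),
        Species("orphan", "orphan", "free", "shuttling", 0.0, {}),
    ]
    net = ReactionNetwork(
        species, [Reaction("r", {"A": 1}, {"B": 1}, mass_action(1.0))]
    )
    assert [d.subject for d in validate_network(net)] == ["orphan"]


def test_missing_rate_parameter_names_the_reaction():
    incomplete = default_parameters().as_dict()
    del incomplete["k_mono_init"]
    with pytest.raises(ConfigurationError, match="k_mono_init"):
        build_atm_network(incomplete)


def test_negative_parameter_rejected():
    with pytest.raises(ValidationError, match="k_p53"):
        default_parameters().with_overrides({"k_p53": -1.0})
    with pytest.raises(ValidationError):
        mass_action(-2.0)


def test_monomer_roster_covers_all_faces(network):
    assert len(MONOMER_IDS) == 12
    assert {m.rsplit("_", 1)[1] for m in MONOMER_IDS} == set(FACES)
    for m in MONOMER_IDS:
        assert m in network.index
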