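"""Assembled RHS vs a brute-force oracle, conservation, analytic limits."""

import numpy as np
import pytest
from scipy.linalg import expm

from atmkin import (
    AgentProtocol,
    AssemblyError,
    ControlState,
    Reaction,
    ReactionNetwork,
    ShuttlingSpec,
    SolverOptions,
    Species,
    agent_dose_rate,
    assemble_rhs,
    build_initial_state,
    conserved_moieties,
    mass_action,
    shuttling_fluxes,
    simulate,
    steady_state_residual,
)

SHAM = AgentProtocol()
IR = AgentProtocol("IR", 1.0, 1.0)


# --- independent oracle: plain-python accumulation, no matrix algebra ------


def naive_rhs(network, shuttling, protocol, params, t, y):
    n = network.n_species
    dy = [0.0] * (2 * n + 5)
    dsb, ros0, ros1, r0, r1 = (float(v) for v in y[2 * n : 2 * n + 5])

    def gate_value(gate, r, ros, dsb_site):
        if gate.kind == "relaxation":
            return min(max(r, 0.0), 1.0) ** gate.h
        if gate.kind == "ros":
            return max(ros, 0.0) / (gate.K + max(ros, 0.0))
        return max(dsb_site, 0.0) / (gate.K + max(dsb_site, 0.0))

    for offset, (r, ros, dsb_site) in (
        (0, (r0, ros0, dsb)),
        (n, (r1, ros1, 0.0)),
    ):
        amounts = {s.id: float(y[offset + i]) for i, s in enumerate(network.species)}
        for rxn in network.reactions:
            law = rxn.rate_law
            if law.form == "mass_action":
                flux = law.k
                for sp, st in rxn.reactants.items():
                    flux *= amounts[sp] ** st
            else:
                (sub,) = rxn.reactants
                flux = law.vmax * amounts[sub] / (law.km + amounts[sub])
            for mod in rxn.modifiers:
                if mod.startswith("@"):
                    flux *= sum(
                        w * amounts[sp]
                        for sp, w in network.groups[mod[1:]].items()
                    )
                else:
                    flux *= amounts[mod]
            for gate in law.gates:
                flux *= gate_value(gate, r, ros, dsb_site)
            for sp, st in rxn.reactants.items():
                dy[offset + network.index[sp]] -= st * flux
            for sp, st in rxn.products.items():
                dy[offset + network.index[sp]] += st * flux

    for i, s in enumerate(network.species):
        k_in = shuttling.k_in[s.id]
        if s.id in shuttling.mrn_enhanced and shuttling.k_mrn:
            mrn = float(y[network.index[shuttling.mrn_species]])
            k_in *= 1.0 + shuttling.k_mrn * mrn * dsb / (shuttling.K_dsb + dsb)
        move = k_in * float(y[n + i]) - shuttling.k_out[s.id] * float(y[i])
        dy[i] += move
        dy[n + i] -= move

    dr_now = agent_dose_rate(protocol, t)
    dy[2 * n] = (
        params.dsb_yield * dr_now if protocol.makes_dsb else 0.0
    ) - params.k_repair * dsb
    prod = params.k_ros_prod * dr_now if protocol.makes_ros else 0.0
    dy[2 * n + 1] = prod - params.k_ros_decay * ros0
    dy[2 * n + 2] = prod - params.k_ros_decay * ros1
    kap0 = float(y[network.index["KAP1"]])
    kap1 = float(y[n + network.index["KAP1"]])
    pkap0 = float(y[network.index["pKAP1"]])
    pkap1 = float(y[n + network.index["pKAP1"]])
    dy[2 * n + 3] = (
        params.k_rel_dsb * dsb + params.k_rel_pkap * pkap0
    ) * (1 - r0) - params.k_cond_kap * kap0 * r0
    dy[2 * n + 4] = (params.k_rel_pkap * pkap1) * (
        1 - r1
    ) - params.k_cond_kap * kap1 * r1
    return np.array(dy)


def random_state(network, rng):
    n = network.n_species
    y = np.empty(2 * n + 5)
    y[: 2 * n] = rng.uniform(0.0, 2.0, 2 * n)
    y[2 * n] = rng.uniform(0.0, 40.0)  # DSB
    y[2 * n + 1 : 2 * n + 3] = rng.uniform(0.0, 2.0, 2)  # ROS
    y[2 * n + 3 :] = rng.uniform(0.0, 1.0, 2)  # r
    return y


def test_assembled_rhs_matches_bruteforce_oracle(network, shuttling, params, rng):
    rhs = assemble_rhs(network, shuttling, IR, params)
    for t in (0.3, 5.0):
        for _ in range(100):
            y = random_state(network, rng)
            fast = rhs(t, y)
            slow = naive_rhs(network, shuttling, IR, params, t, y)
            scale = np.maximum(np.abs(slow), 1.0)
            assert np.max(np.abs(fast - slow) / scale) < 1e-12


def test_zero_state_sham_gives_zero_derivative(network, shuttling, params):
    rhs = assemble_rhs(network, shuttling, SHAM, params)
    y = np.zeros(2 * network.n_species + 5)
    assert np.all(rhs(0.0, y) == 0.0)


def test_symmetric_state_has_no_net_shuttling(network, shuttling, params, rng):
    """With equal amounts, symmetric rates and the MRN term off, SH = 0."""
    x = rng.uniform(0.0, 2.0, network.n_species)
    spec = ShuttlingSpec(
        k_out=dict(shuttling.k_out), k_in=dict(shuttling.k_in), k_mrn=0.0
    )
    net_flux = shuttling_fluxes(network, x, x, ControlState(dsb=10.0), spec)
    assert np.all(net_flux == 0.0)


def test_chromatin_fixed_species_never_shuttle(network, shuttling, rng):
    x0 = rng.uniform(0.0, 2.0, network.n_species)
    x1 = rng.uniform(0.0, 2.0, network.n_species)
    flux = shuttling_fluxes(network, x0, x1, ControlState(dsb=5.0), shuttling)
    for i, s in enumerate(network.species):
        if s.mobility != "shuttling":
            assert flux[i] == 0.0


def test_mrn_enhancement_saturates(shuttling):
    """As DSB grows the recruitment factor approaches 1 + k_mrn*MRN, so the
    per-break sensor effect (factor-1)/DSB is decreasing."""
    mrn = 0.5
    plateau = 1.0 + shuttling.k_mrn * mrn
    assert shuttling.enhancement(mrn, 1e9) == pytest.approx(plateau, rel=1e-6)
    dsbs = [1.0, 5.0, 50.0, 500.0]
    factors = [shuttling.enhancement(mrn, d) for d in dsbs]
    assert factors == sorted(factors)
    per_break = [(f - 1.0) / d for f, d in zip(factors, dsbs)]
    assert per_break == sorted(per_break, reverse=True)


def test_shipped_initial_state_is_fixed_point(network, shuttling, params):
    assert steady_state_residual(network, shuttling, params) < 1e-8


def test_sham_trajectories_stay_constant(sham_outcome):
    result, _ = sham_outcome
    drift = np.max(np.abs(result.values - result.values[0]), axis=0)
    assert np.max(drift) < 10 * (
        result.options.rtol * np.max(np.abs(result.values[0])) +
        result.options.atol
    )


def test_residual_positive_off_equilibrium(network, shuttling, params):
    n = network.n_species
    # free PP2A together with a phospho-ATM dimer: rebinding flux is active
    y = build_initial_state(network)
    y[network.index["ATM_dim_p_A"]] = 0.3
    assert steady_state_residual(network, shuttling, params, y) > 0.0
    # relaxed chromatin with the HP1beta/H3K9me3 complex intact: CK2 acts
    y = build_initial_state(network)
    y[2 * n + 3] = 0.5  # r0
    assert steady_state_residual(network, shuttling, params, y) > 0.0


def test_linear_chain_matches_matrix_exponential(params):
    """A -> B -> C with no gates follows the closed-form linear solution."""
    k1, k2 = 0.7, 0.3
    species = [
        Species("A", "A", "free", "shuttling", 2.0, {"X": 1}),
        Species("B", "B", "free", "shuttling", 0.0, {"X": 1}),
        Species("C", "C", "free", "shuttling", 0.0, {"X": 1}),
    ]
    net = ReactionNetwork(
        species,
        [
            Reaction("r1", {"A": 1}, {"B": 1}, mass_action(k1)),
            Reaction("r2", {"B": 1}, {"C": 1}, mass_action(k2)),
        ],
        name="chain",
    )
    spec = ShuttlingSpec(
        k_out={s: 0.0 for s in "ABC"}, k_in={s: 0.0 for s in "ABC"}
    )
    result = simulate(
        net, spec, SHAM, params, t_span=(0.0, 10.0), n_points=41,
        options=SolverOptions(rtol=1e-9, atol=1e-12),
    )
    K = np.array([[-k1, 0, 0], [k1, -k2, 0], [0, k2, 0]])
    x0 = np.array([2.0, 0.0, 0.0])
    for i, t in enumerate(result.times):
        expected = expm(K * t) @ x0
        np.testing.assert_allclose(result.values[i, :3], expected, atol=1e-7)
        np.testing.assert_allclose(result.values[i, 3:6], expected, atol=1e-7)


def test_moiety_totals_conserved_along_ir_trajectory(
    network, ir_outcome, params
):
    result, _ = ir_outcome
    n = network.n_species
    x0 = result.values[:, :n]
    x1 = result.values[:, n : 2 * n]
    for m in conserved_moieties(network):
        total = x0 @ m["vector"] + x1 @ m["vector"]
        tol = 10 * (result.options.rtol * abs(total[0]) + result.options.atol)
        assert np.max(np.abs(total - total[0])) < tol, m["moiety"]


def test_no_meaningful_negative_amounts(ir_outcome):
    result, _ = ir_outcome
    assert result.values.min() > -1e-6


def test_exposure_end_is_on_the_output_grid(ir_outcome):
    result, _ = ir_outcome
    assert np.any(result.times == result.protocol.exposure_time)
    assert np.all(np.diff(result.times) > 0)


def test_grid_refinement_convergence(network, shuttling, params):
    """Halving the tolerances moves the endpoint by < 1e-4 relative."""
    kwargs = dict(t_span=(0.0, 40.0), n_points=81)
    coarse = simulate(network, shuttling, IR, params, **kwargs)
    fine = simulate(
        network, shuttling, IR, params,
        options=SolverOptions(rtol=5e-7, atol=5e-10), **kwargs
    )
    a, b = coarse.values[-1], fine.values[-1]
    rel = np.linalg.norm(a - b) / np.linalg.norm(b)
    assert rel < 1e-4


def test_shuttling_must_cover_every_species(network, params, shuttling):
    incomplete = ShuttlingSpec(
        k_out={"KAP1": 0.5}, k_in={"KAP1": 0.5}
    )
    with pytest.raises(AssemblyError, match="does not cover"):
        assemble_rhs(network, incomplete, SHAM, params)


def test_fixed_species_with_rates_is_an_assembly_error(network, params, shuttling):
    bad_out = dict(shuttling.k_out)
    bad_out["H2AX"] = 1.0  # chromatin-fixed
    bad = ShuttlingSpec(k_out=bad_out, k_in=dict(shuttling.k_in))
    with pytest.raises(AssemblyError, match="H2AX"):
        assemble_rhs(network, bad, SHAM, params)
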