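"""Network structure, mass balances and ACP-pool conservation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lipidflux.model import (
    ACP_SPECIES,
    REACTIONS,
    SPECIES,
    ConfigurationError,
    FixedInputs,
    Inhibitor,
    ReactionKinetics,
    baseline_state_vector,
    reaction_index,
    reaction_rates,
    species_index,
    time_derivatives,
    total_acp,
)


def test_stoichiometry_conserves_acp_pool(model):
    acp_rows = [species_index(s) for s in ACP_SPECIES]
    col_sums = model.stoichiometry[acp_rows, :].sum(axis=0)
    assert np.all(col_sums == 0)


def test_zero_state_gives_zero_rates(model):
    rates = reaction_rates(np.zeros(len(SPECIES)), model)
    assert np.all(rates == 0.0)


def test_rates_nonnegative_for_random_states(model, rng):
    for _ in range(50):
        state = rng.uniform(0, 50, size=len(SPECIES))
        assert np.all(reaction_rates(state, model) >= 0.0)


def test_acc_rate_hand_evaluated_toy():
    """ACC with unit parameters at A = H = 1: v = 1·(1/2)·(1/2) = 0.25."""
    kinetics = []
    for rid in REACTIONS:
        two_substrate = rid in (
            "ACC", "ELONG_C16", "ELONG_C18", "PLSB_C16", "PLSB_C18", "PLSC"
        )
        kinetics.append(
            ReactionKinetics(
                reaction_id=rid,
                vmax=1.0,
                km_a=1.0,
                km_b=1.0 if two_substrate else None,
                ki_ppgpp=1.0 if rid.startswith("PLSB") else None,
            )
        )
    from lipidflux.model import PathwayModel

    toy = PathwayModel(
        kinetics=tuple(kinetics),
        fixed=FixedInputs(acetyl_coa=1.0, g3p=1.0, c16_1_acp=1.0, ppgpp=0.0),
        acp_total=6.0,
    )
    state = np.ones(len(SPECIES))
    rates = reaction_rates(state, toy)
    assert rates[reaction_index("ACC")] == pytest.approx(0.25)
    # single-substrate chain step at half-saturation
    assert rates[reaction_index("CDSA")] == pytest.approx(0.5)


def test_acp_derivative_sum_is_zero(model, rng):
    for _ in range(25):
        state = rng.uniform(0, 30, size=len(SPECIES))
        deriv = time_derivatives(state, model)
        acp_rows = [species_index(s) for s in ACP_SPECIES]
        assert deriv[acp_rows].sum() == pytest.approx(0.0, abs=1e-10)


def test_total_acp_values():
    assert total_acp(np.zeros(len(SPECIES))) == 0.0
    assert total_acp(np.ones(len(SPECIES))) == 6.0


def test_total_acp_invariant_along_trajectory(model):
    x0 = baseline_state_vector() * 1.5  # off-steady-state start
    sol = solve_ivp(
        lambda t, y: time_derivatives(y, model),
        (0, 500.0),
        x0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        t_eval=np.linspace(0, 500, 40),
    )
    totals = sol.y[: len(ACP_SPECIES)].sum(axis=0)
    assert np.max(np.abs(totals / totals[0] - 1.0)) <= 1e-6


def test_vmax_homogeneity_of_network_rates(model, rng):
    state = rng.uniform(0.5, 20, size=len(SPECIES))
    doubled = model.with_vmax_factors({r: 2.0 for r in REACTIONS})
    assert np.allclose(
        reaction_rates(state, doubled), 2.0 * reaction_rates(state, model)
    )


def test_ppgpp_scales_only_plsb_rates(model, rng):
    state = rng.uniform(0.5, 20, size=len(SPECIES))
    base = reaction_rates(state, model)
    inhibited = reaction_rates(state, model.with_fixed(ppgpp=10.0))  # = Ki
    for i, rid in enumerate(REACTIONS):
        if rid.startswith("PLSB"):
            assert inhibited[i] == pytest.approx(base[i] / 2.0)
        else:
            assert inhibited[i] == pytest.approx(base[i])


def test_duplicate_or_missing_reactions_rejected(model):
    from lipidflux.model import PathwayModel

    with pytest.raises(ConfigurationError):
        PathwayModel(kinetics=model.kinetics[:-1], fixed=model.fixed, acp_total=10.0)


def test_inhibitors_restricted_to_acc():
    with pytest.raises(ConfigurationError):
        ReactionKinetics(
            reaction_id="FABZ",
            vmax=1.0,
            km_a=1.0,
            inhibitors=(Inhibitor("c16_acp", 1.0),),
        )
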