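"""Steady-state solving, pathway fluxes and Vmax scans."""

import numpy as np
import pytest

from lipidflux.model import baseline_state_vector, total_acp
from lipidflux.steady_state import (
    NotConvergedError,
    SteadyStateResult,
    find_steady_state,
    pathway_fluxes,
    scan_vmax,
)


def test_baseline_is_a_fixed_point(model, baseline_ss):
    assert baseline_ss.converged
    assert baseline_ss.residual <= 1e-9
    # starting exactly at the steady state returns the same state
    again = find_steady_state(model, init=baseline_ss.state)
    assert np.allclose(again.state, baseline_ss.state, rtol=1e-8)


def test_steady_state_conserves_acp(model, baseline_ss):
    assert total_acp(baseline_ss.state) == pytest.approx(model.acp_total, rel=1e-9)


def test_chain_species_closed_form(model, baseline_ss):
    """For a species drained by one MM reaction carrying flux J:
    x* = Km * J / (Vmax - J) — checked for CDP-DAG (consumed by PssA)."""
    flux = baseline_ss.flux_by_reaction
    kin = model.kinetics_by_id["PSSA"]
    j = flux["PSSA"]
    expected = kin.km_a * j / (kin.vmax - j)
    assert baseline_ss.concentrations["cdp_dag"] == pytest.approx(expected, rel=1e-8)


def test_steady_state_flux_balance(baseline_ss):
    flux = baseline_ss.flux_by_reaction
    # PL chain: PE output equals total PlsB input
    assert flux["PSD"] == pytest.approx(
        flux["PLSB_C16"] + flux["PLSB_C18"], rel=1e-8
    )
    # branch point: elongation inflow = saturated-path + LPS outflow
    assert flux["ELONG_C14OH"] == pytest.approx(
        flux["FABZ"] + flux["LPXC"], rel=1e-8
    )
    # malonyl balance: production = all malonyl-consuming reactions
    assert flux["ACC"] == pytest.approx(
        flux["ELONG_C14OH"] + flux["ELONG_C16"] + flux["ELONG_C18"], rel=1e-8
    )


def test_pathway_fluxes_accessor(baseline_ss):
    pe, lps = pathway_fluxes(baseline_ss)
    assert pe == pytest.approx(baseline_ss.flux_by_reaction["PSD"])
    assert lps == pytest.approx(baseline_ss.flux_by_reaction["LPXC"])


def test_pathway_fluxes_requires_convergence(model, baseline_ss):
    bad = SteadyStateResult(
        model=model,
        state=baseline_ss.state,
        fluxes=baseline_ss.fluxes,
        converged=False,
        residual=1.0,
    )
    with pytest.raises(NotConvergedError):
        pathway_fluxes(bad)


def test_integration_and_root_refinement_agree(model, baseline_ss):
    """Oracle equivalence on the default model: a long plain integration
    (no root refinement) lands on the refined solver's answer."""
    from scipy.integrate import solve_ivp

    from lipidflux.model import time_derivatives

    x0 = baseline_state_vector() * np.linspace(0.5, 1.4, 10)  # perturbed start
    x0 *= model.acp_total / total_acp(x0)
    sol = solve_ivp(
        lambda t, y: time_derivatives(y, model),
        (0, 1e6),
        x0,
        method="LSODA",
        rtol=1e-12,
        atol=1e-13,
    )
    quiesced = sol.y[:, -1]
    assert np.allclose(quiesced, baseline_ss.state, rtol=1e-6)


def test_scan_identity_at_factor_one(model, baseline_ss):
    scan = scan_vmax(model, "PLSB", [1.0])
    assert scan.pe_flux[0] == pytest.approx(baseline_ss.pe_flux, rel=1e-8)
    assert scan.lps_flux[0] == pytest.approx(baseline_ss.lps_flux, rel=1e-8)


def test_scan_rejects_unknown_target(model):
    with pytest.raises(ValueError):
        scan_vmax(model, "NOT_A_REACTION", [1.0, 2.0])


def test_pe_flux_monotone_in_plsb_and_acetyl_coa(model):
    factors = np.exp2(np.linspace(-2, 2, 9))  # 16-fold span
    for target in ("PLSB", "acetyl_coa"):
        scan = scan_vmax(model, target, factors)
        assert scan.converged.all()
        assert np.all(np.diff(scan.pe_flux[np.argsort(scan.factors)]) >= -1e-9)


def test_fixed_c16_1_acp_does_not_move_fluxes(model, baseline_ss):
    scan = scan_vmax(model, "c16_1_acp", [0.25, 1.0, 4.0])
    assert scan.converged.all()
    assert np.max(np.abs(scan.pe_flux / baseline_ss.pe_flux - 1.0)) < 0.05
    assert np.max(np.abs(scan.lps_flux / baseline_ss.lps_flux - 1.0)) < 0.05
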