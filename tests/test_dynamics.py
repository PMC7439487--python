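"""Perturbation time courses: ppGpp steps, event handling, depletion order."""

import numpy as np
import pytest

from lipidflux.dynamics import Event, depletion_order, simulate_timecourse
from lipidflux.model import ACP_SPECIES


def test_empty_schedule_stays_at_steady_state(model):
    traj = simulate_timecourse(model, events=(), t_end=30.0, dt=1.0)
    assert np.max(np.abs(traj.normalized - 1.0)) <= 1e-6


def test_event_validation():
    with pytest.raises(ValueError):
        Event(0.0, "not_an_input", 1.0)
    with pytest.raises(ValueError):
        Event(0.0, "ppgpp", -1.0)
    from lipidflux.dynamics import _normalize_schedule

    with pytest.raises(ValueError):  # times must increase strictly
        _normalize_schedule([(5.0, "ppgpp", 1.0), (5.0, "ppgpp", 2.0)])


def test_event_outside_grid_rejected(model):
    with pytest.raises(ValueError):
        simulate_timecourse(model, events=[(-1.0, "ppgpp", 10.0)], t_end=10.0)
    with pytest.raises(ValueError):
        simulate_timecourse(model, events=[(20.0, "ppgpp", 10.0)], t_end=10.0)


@pytest.fixture(scope="module")
def ppgpp_step(model):
    # saturating step: 10x the PlsB inhibition constant
    return simulate_timecourse(
        model, events=[(5.0, "ppgpp", 100.0)], t_end=120.0, dt=0.5
    )


def test_acp_conserved_along_perturbation(model, ppgpp_step):
    totals = ppgpp_step.concentrations[:, : len(ACP_SPECIES)].sum(axis=1)
    assert np.max(np.abs(totals / totals[0] - 1.0)) <= 1e-6


def test_ppgpp_step_cascade(ppgpp_step):
    """PlsB inhibition: long-chain acyl-ACP accumulates, feedback on ACC
    depletes malonyl-ACP, and PE flux drops below its pre-step level."""
    final = -1
    assert ppgpp_step.series("c16_acp", normalized=True)[final] > 1.5
    assert ppgpp_step.series("c18_acp", normalized=True)[final] > 1.5
    assert ppgpp_step.series("malonyl_acp", normalized=True)[final] < 0.5
    pe = ppgpp_step.flux_series("PSD")
    pre = pe[ppgpp_step.times < 5.0].mean()
    assert pe[final] < pre


def test_pl_intermediates_deplete_in_pathway_order(ppgpp_step):
    order = depletion_order(ppgpp_step, ["ps", "lpa", "cdp_dag", "pa"], 0.5)
    names = [name for name, _ in order]
    assert names == ["lpa", "pa", "cdp_dag", "ps"]
    times = [t for _, t in order]
    assert all(t is not None for t in times)
    assert times == sorted(times)


def test_depletion_order_constructed_fixture(model):
    """Hand-built trajectories return their known crossing times in order."""
    from lipidflux.dynamics import Trajectories
    from lipidflux.model import REACTIONS, SPECIES

    times = np.linspace(0.0, 10.0, 101)
    conc = np.ones((len(times), len(SPECIES)))
    # species 'lpa' crosses 0.5 at t = 2, 'ps' at t = 7 (linear ramps)
    i_lpa = SPECIES.index("lpa")
    i_ps = SPECIES.index("ps")
    conc[:, i_lpa] = np.clip(1.0 - times / 4.0, 0.0, None)
    conc[:, i_ps] = np.clip(1.0 - (times - 3.0) / 8.0, 0.0, None)
    traj = Trajectories(
        times=times,
        concentrations=conc,
        fluxes=np.zeros((len(times), len(REACTIONS))),
        baseline=np.ones(len(SPECIES)),
        events=(),
    )
    order = depletion_order(traj, ["ps", "lpa", "holo_acp"], threshold=0.5)
    assert order[0][0] == "lpa" and order[0][1] == pytest.approx(2.0, abs=0.06)
    assert order[1][0] == "ps" and order[1][1] == pytest.approx(7.0, abs=0.06)
    assert order[2] == ("holo_acp", None)


def test_no_crossings_for_constant_trajectories(model):
    traj = simulate_timecourse(model, events=(), t_end=10.0, dt=1.0)
    order = depletion_order(traj, ["lpa", "ps"], threshold=0.5)
    assert all(t is None for _, t in order)


def test_zero_ppgpp_event_matches_steady_state(model, baseline_ss):
    """An explicit ppGpp step to 0 is a no-op: trajectories sit on the
    steady state the solver found."""
    traj = simulate_timecourse(
        model, events=[(2.0, "ppgpp", 0.0)], t_end=20.0, dt=1.0
    )
    assert np.allclose(traj.concentrations, baseline_ss.state, rtol=1e-6)
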