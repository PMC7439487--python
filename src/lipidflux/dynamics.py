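"""Dynamic perturbation simulations: ppGpp steps and acetyl-CoA shifts.

A perturbation is a schedule of step changes to the fixed boundary inputs
(ppGpp, acetyl-CoA, G3P, C16:1-ACP). The simulator integrates the ODE
system piecewise between events with a stiff-capable integrator and exact
restarts at each event time, starting from a converged steady state of the
pre-event model. ppGpp magnitudes are naturally expressed in multiples of
the PlsB inhibition constant Ki; the model takes the concentration directly
in µM (the default Ki is 10 µM).

The characteristic response to a saturating ppGpp step mirrors the pathway
logic: PlsB inhibition lets the long-chain acyl-ACPs (C16:0, C18:0)
accumulate, their feedback on ACC shuts down malonyl-ACP synthesis, and the
phospholipid intermediates drain out in pathway order (LPA first, then PA,
CDP-DAG, PS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    REACTIONS,
    SPECIES,
    PathwayModel,
    reaction_rates,
    species_index,
    time_derivatives,
)
from .steady_state import find_steady_state

__all__ = [
    "Event",
    "EventSchedule",
    "Trajectories",
    "simulate_timecourse",
    "depletion_order",
]

_FIXED_FIELDS = ("acetyl_coa", "g3p", "c16_1_acp", "ppgpp")


@dataclass(frozen=True)
class Event:
    """A step change of one fixed boundary input at a given time (min)."""

    time: float
    input_id: str
    value: float

    def __post_init__(self) -> None:
        if self.input_id not in _FIXED_FIELDS:
            raise ValueError(
                f"unknown fixed input {self.input_id!r}; one of {_FIXED_FIELDS}"
            )
        if self.value < 0:
            raise ValueError("event value must be >= 0")


def _normalize_schedule(events) -> tuple[Event, ...]:
    out = []
    for ev in events:
        if isinstance(ev, Event):
            out.append(ev)
        else:
            t, name, value = ev
            out.append(Event(float(t), str(name), float(value)))
    times = [ev.time for ev in out]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("event times must be strictly increasing")
    return tuple(out)


#: An event schedule is a sequence of Event (or (time, input, value) tuples).
EventSchedule = tuple[Event, ...]


@dataclass(frozen=True)
class Trajectories:
    """Time courses of concentrations and fluxes with baseline normalisation.

    ``normalized`` divides each species by its pre-first-event mean (the
    initial value when no samples precede the first event), following the
    convention of plotting perturbation responses relative to a pre-shift
    average of 1.
    """

    times: np.ndarray
    concentrations: np.ndarray  # (n_times, n_species)
    fluxes: np.ndarray  # (n_times, n_reactions)
    baseline: np.ndarray  # per-species pre-event mean
    events: EventSchedule

    @property
    def normalized(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.concentrations / self.baseline

    def series(self, species: str, normalized: bool = False) -> np.ndarray:
        col = species_index(species)
        return (self.normalized if normalized else self.concentrations)[:, col]

    def flux_series(self, reaction: str) -> np.ndarray:
        return self.fluxes[:, REACTIONS.index(reaction)]

    def to_frame(self):
        """Tidy frame: one row per (time, species)."""
        import pandas as pd

        norm = self.normalized
        frames = []
        for i, name in enumerate(SPECIES):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "species": name,
                        "value": self.concentrations[:, i],
                        "normalized": norm[:, i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate_timecourse(
    model: PathwayModel,
    events=(),
    t_end: float = 60.0,
    dt: float = 0.5,
    init: np.ndarray | None = None,
    t_start: float = 0.0,
) -> Trajectories:
    """Integrate the pathway through a schedule of boundary-input steps.

    The initial state defaults to the converged steady state of the
    pre-event model, so an empty schedule yields flat trajectories. Events
    must fall inside [t_start, t_end).
    """
    schedule = _normalize_schedule(events)
    if dt <= 0 or t_end <= t_start:
        raise ValueError("need dt > 0 and t_end > t_start")
    for ev in schedule:
        if ev.time < t_start:
            raise ValueError(f"event at t={ev.time} precedes grid start {t_start}")
        if ev.time >= t_end:
            raise ValueError(f"event at t={ev.time} is beyond t_end={t_end}")

    if init is None:
        ss = find_steady_state(model)
        if not ss.converged:
            raise RuntimeError("pre-event model has no converged steady state")
        init = ss.state
    init = np.asarray(init, dtype=float)

    times = np.arange(t_start, t_end + dt / 2, dt)
    conc = np.empty((len(times), len(SPECIES)))
    current_model = model
    state = init.copy()
    t_now = t_start
    filled = 0
    boundaries = [ev.time for ev in schedule] + [float(times[-1])]
    segments = []
    for ev, t_next in zip((None, *schedule), boundaries):
        if ev is not None:
            current_model = current_model.with_fixed(**{ev.input_id: ev.value})
        segments.append((current_model, t_now, t_next))
        t_now = t_next

    for seg_model, t0, t1 in segments:
        mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
        t_eval = times[mask]
        if t1 > t0:
            sol = solve_ivp(
                lambda t, y: time_derivatives(y, seg_model),
                (t0, t1),
                state,
                method="LSODA",
                t_eval=t_eval if len(t_eval) else None,
                rtol=1e-10,
                atol=1e-12,
                dense_output=False,
            )
            if len(t_eval):
                conc[np.where(mask)[0]] = np.maximum(sol.y.T, 0.0)
                filled += len(t_eval)
            state = np.maximum(sol.y[:, -1], 0.0)
        elif len(t_eval):
            conc[np.where(mask)[0]] = np.maximum(state, 0.0)
            filled += len(t_eval)

    # fluxes are evaluated under the model in force at each time point
    flux = np.empty((len(times), len(REACTIONS)))
    for seg_model, t0, t1 in segments:
        mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
        for i in np.where(mask)[0]:
            flux[i] = reaction_rates(conc[i], seg_model)

    t_first_event = schedule[0].time if schedule else None
    if t_first_event is not None and np.any(times < t_first_event):
        baseline = conc[times < t_first_event].mean(axis=0)
    else:
        baseline = init.copy()
    return Trajectories(
        times=times,
        concentrations=conc,
        fluxes=flux,
        baseline=baseline,
        events=schedule,
    )


def depletion_order(
    traj: Trajectories,
    species: list[str] | tuple[str, ...],
    threshold: float = 0.5,
) -> list[tuple[str, float | None]]:
    """Order species by when they first fall below a fraction of baseline.

    Crossing times are linearly interpolated between grid points. Species
    that never cross are listed last with ``None`` in place of a time.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    crossings: list[tuple[str, float | None]] = []
    norm = traj.normalized
    for sp in species:
        if traj.baseline[species_index(sp)] <= 0:
            raise ValueError(f"species {sp!r} has nonpositive baseline")
        y = norm[:, species_index(sp)]
        below = np.where(y < threshold)[0]
        if len(below) == 0:
            crossings.append((sp, None))
            continue
        k = below[0]
        if k == 0:
            t_cross = float(traj.times[0])
        else:
            t0, t1 = traj.times[k - 1], traj.times[k]
            y0, y1 = y[k - 1], y[k]
            t_cross = float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))
        crossings.append((sp, t_cross))
    crossed = [c for c in crossings if c[1] is not None]
    uncrossed = [c for c in crossings if c[1] is None]
    crossed.sort(key=lambda c: c[1])
    return crossed + uncrossed
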