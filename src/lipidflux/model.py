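"""Kinetic model of E. coli fatty-acid, phospholipid and LPS synthesis.

The network is a deliberately reduced version of the saturated fatty-acid
elongation cycle and the downstream phospholipid (PL) chain:

* ACC (lumped with FabD) loads holo-ACP with a malonyl group from
  acetyl-CoA; it is competitively inhibited by the long-chain products
  C16:0-ACP and C18:0-ACP (end-product feedback).
* Lumped elongation converts malonyl-ACP to the branch-point species
  C14:0-OH-ACP (3-hydroxy-myristoyl-ACP), which either continues down the
  saturated pathway (lumped FabZ/FabI) or is drained into LPS synthesis
  (lumped LpxA/LpxC, releasing holo-ACP).
* Further elongation to C16:0- and C18:0-ACP consumes malonyl-ACP and
  releases holo-ACP.
* PlsB acylates sn-glycerol-3-phosphate (G3P) with C16:0- or C18:0-ACP to
  produce LPA; LPA is converted through PA, CDP-DAG and PS to the PE sink
  (PlsC, CdsA, PssA, Psd). ppGpp acts as a posttranslational inhibitor of
  both PlsB reactions.

Every reaction is an irreversible one- or two-substrate Michaelis-Menten
rate law, optionally with competitive inhibitors on the first substrate
site. The six ACP-carrying species (holo, malonyl, C14:0-OH, C14:0, C16:0,
C18:0) form a closed, conserved pool by construction; G3P, acetyl-CoA,
C16:1-ACP (the PlsC acyl donor) and ppGpp are fixed boundary species.

Concentrations are in µM, rates in µM·min⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "ACP_SPECIES",
    "REACTIONS",
    "FixedInputs",
    "Inhibitor",
    "ReactionKinetics",
    "PathwayModel",
    "competitive_mm_rate",
    "two_substrate_mm_rate",
    "reaction_rates",
    "time_derivatives",
    "total_acp",
    "default_model",
]

#: Dynamic species, in state-vector order.
SPECIES: tuple[str, ...] = (
    "holo_acp",
    "malonyl_acp",
    "c14_oh_acp",
    "c14_acp",
    "c16_acp",
    "c18_acp",
    "lpa",
    "pa",
    "cdp_dag",
    "ps",
)

#: The six ACP-carrying species whose sum is conserved.
ACP_SPECIES: tuple[str, ...] = SPECIES[:6]

#: Reaction identifiers, in rate-vector order.
REACTIONS: tuple[str, ...] = (
    "ACC",
    "ELONG_C14OH",
    "FABZ",
    "LPXC",
    "ELONG_C16",
    "ELONG_C18",
    "PLSB_C16",
    "PLSB_C18",
    "PLSC",
    "CDSA",
    "PSSA",
    "PSD",
)

_SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}
_REACTION_INDEX = {name: i for i, name in enumerate(REACTIONS)}

#: Reactions that together constitute "PlsB" for scans and control analysis
#: (a single Vmax scale factor applies to both acyl-ACP channels).
PLSB_REACTIONS: tuple[str, ...] = ("PLSB_C16", "PLSB_C18")

#: Stoichiometry (species × reactions) of the dynamic species only.
#: Boundary species (acetyl-CoA, G3P, C16:1-ACP) and the PE/LPS sinks do not
#: appear; LPXC returns holo-ACP when the acyl chain leaves for LPS.
_STOICH_SPEC: dict[str, dict[str, int]] = {
    "ACC": {"holo_acp": -1, "malonyl_acp": +1},
    "ELONG_C14OH": {"malonyl_acp": -1, "c14_oh_acp": +1},
    "FABZ": {"c14_oh_acp": -1, "c14_acp": +1},
    "LPXC": {"c14_oh_acp": -1, "holo_acp": +1},
    "ELONG_C16": {"c14_acp": -1, "malonyl_acp": -1, "c16_acp": +1, "holo_acp": +1},
    "ELONG_C18": {"c16_acp": -1, "malonyl_acp": -1, "c18_acp": +1, "holo_acp": +1},
    "PLSB_C16": {"c16_acp": -1, "lpa": +1, "holo_acp": +1},
    "PLSB_C18": {"c18_acp": -1, "lpa": +1, "holo_acp": +1},
    "PLSC": {"lpa": -1, "pa": +1},
    "CDSA": {"pa": -1, "cdp_dag": +1},
    "PSSA": {"cdp_dag": -1, "ps": +1},
    "PSD": {"ps": -1},
}


def _build_stoichiometry() -> np.ndarray:
    mat = np.zeros((len(SPECIES), len(REACTIONS)), dtype=int)
    for rxn, changes in _STOICH_SPEC.items():
        j = _REACTION_INDEX[rxn]
        for sp, coeff in changes.items():
            mat[_SPECIES_INDEX[sp], j] = coeff
    return mat


class ParameterError(ValueError):
    """A kinetic parameter violates its positivity constraint."""


class ConfigurationError(ValueError):
    """The model definition is inconsistent or incomplete."""


@dataclass(frozen=True)
class FixedInputs:
    """Boundary concentrations held constant during simulation (µM)."""

    acetyl_coa: float = 100.0
    g3p: float = 200.0
    c16_1_acp: float = 1.0
    ppgpp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("acetyl_coa", "g3p", "c16_1_acp", "ppgpp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"fixed input {name!r} must be >= 0")


@dataclass(frozen=True)
class Inhibitor:
    """Competitive inhibitor acting on a reaction's first substrate site."""

    species: str
    ki: float

    def __post_init__(self) -> None:
        if self.ki <= 0:
            raise ParameterError(f"Ki for inhibitor {self.species!r} must be > 0")


@dataclass(frozen=True)
class ReactionKinetics:
    """Michaelis-Menten parameters for one (possibly lumped) reaction.

    ``km_b`` is None for single-substrate reactions. ``ki_ppgpp`` applies
    only to the PlsB reactions and scales the whole rate by
    ``1 / (1 + ppGpp/Ki)``.
    """

    reaction_id: str
    vmax: float
    km_a: float
    km_b: float | None = None
    inhibitors: tuple[Inhibitor, ...] = ()
    ki_ppgpp: float | None = None

    def __post_init__(self) -> None:
        if self.reaction_id not in _REACTION_INDEX:
            raise ConfigurationError(f"unknown reaction id {self.reaction_id!r}")
        if self.vmax <= 0:
            raise ParameterError(f"{self.reaction_id}: vmax must be > 0")
        if self.km_a <= 0:
            raise ParameterError(f"{self.reaction_id}: km_a must be > 0")
        if self.km_b is not None and self.km_b <= 0:
            raise ParameterError(f"{self.reaction_id}: km_b must be > 0")
        if self.ki_ppgpp is not None and self.ki_ppgpp <= 0:
            raise ParameterError(f"{self.reaction_id}: ki_ppgpp must be > 0")
        if self.inhibitors and self.reaction_id != "ACC":
            raise ConfigurationError(
                f"{self.reaction_id}: acyl-ACP inhibitors are modelled on ACC only"
            )
        if self.ki_ppgpp is not None and self.reaction_id not in PLSB_REACTIONS:
            raise ConfigurationError(
                f"{self.reaction_id}: ppGpp inhibition applies to PlsB only"
            )


def competitive_mm_rate(
    vmax: float,
    s: float,
    km: float,
    inhibitors: Sequence[tuple[float, float]] = (),
) -> float:
    """Irreversible Michaelis-Menten rate with competitive inhibition.

    v = vmax * s / (km * (1 + Σ I_i/Ki_i) + s)

    Parameters
    ----------
    vmax, km : positive kinetic constants (µM·min⁻¹, µM).
    s : substrate concentration (µM, >= 0).
    inhibitors : sequence of (concentration, Ki) pairs acting competitively.
    """
    if vmax <= 0 or km <= 0:
        raise ParameterError("vmax and km must be > 0")
    if s < 0:
        raise ValueError("substrate concentration must be >= 0")
    alpha = 1.0
    for conc, ki in inhibitors:
        if ki <= 0:
            raise ParameterError("Ki must be > 0")
        if conc < 0:
            raise ValueError("inhibitor concentration must be >= 0")
        alpha += conc / ki
    return vmax * s / (km * alpha + s)


def two_substrate_mm_rate(
    vmax: float,
    a: float,
    km_a: float,
    b: float,
    km_b: float,
    inhibitors_on_a: Sequence[tuple[float, float]] = (),
) -> float:
    """Two-substrate rate with separable saturation factors.

    v = vmax * [a / (km_a*(1+ΣI/Ki) + a)] * [b / (km_b + b)]

    Competitive inhibitors act on the first substrate site only.
    """
    if vmax <= 0 or km_a <= 0 or km_b <= 0:
        raise ParameterError("vmax and Km values must be > 0")
    if a < 0 or b < 0:
        raise ValueError("substrate concentrations must be >= 0")
    first = competitive_mm_rate(vmax, a, km_a, inhibitors_on_a)
    return first * b / (km_b + b)


@dataclass(frozen=True)
class PathwayModel:
    """Reaction network, rate laws and mass balances of the pathway.

    The mechanistic analogue of a statsmodels model object: construct it
    (``default_model()`` or :func:`lipidflux.io.parse_model_config`), then
    call :meth:`steady_state`, :meth:`scan`, :meth:`control_coefficients`,
    :meth:`trends`, :meth:`robustness` or :meth:`simulate` for Results
    objects.
    """

    kinetics: tuple[ReactionKinetics, ...]
    fixed: FixedInputs = field(default_factory=FixedInputs)
    acp_total: float = 70.0
    stoichiometry: np.ndarray = field(default_factory=_build_stoichiometry)

    def __post_init__(self) -> None:
        ids = [k.reaction_id for k in self.kinetics]
        if sorted(ids) != sorted(REACTIONS):
            missing = set(REACTIONS) - set(ids)
            extra = set(ids) - set(REACTIONS)
            raise ConfigurationError(
                f"kinetics must define each reaction exactly once "
                f"(missing: {sorted(missing)}, duplicated/unknown: {sorted(extra)})"
            )
        if self.acp_total <= 0:
            raise ParameterError("acp_total must be > 0")
        acp_rows = [_SPECIES_INDEX[s] for s in ACP_SPECIES]
        col_sums = self.stoichiometry[acp_rows, :].sum(axis=0)
        if np.any(col_sums != 0):
            raise ConfigurationError("stoichiometry does not conserve the ACP pool")

    # -- plumbing ---------------------------------------------------------

    @property
    def kinetics_by_id(self) -> Mapping[str, ReactionKinetics]:
        return {k.reaction_id: k for k in self.kinetics}

    def with_vmax_factors(self, factors: Mapping[str, float]) -> "PathwayModel":
        """Return a copy with named reactions' Vmax multiplied by factors.

        The pseudo-target ``"PLSB"`` scales both PlsB channels together.
        """
        expanded: dict[str, float] = {}
        for name, f in factors.items():
            if f <= 0:
                raise ParameterError(f"Vmax factor for {name!r} must be > 0")
            if name == "PLSB":
                for rxn in PLSB_REACTIONS:
                    expanded[rxn] = expanded.get(rxn, 1.0) * f
            elif name in _REACTION_INDEX:
                expanded[name] = expanded.get(name, 1.0) * f
            else:
                raise ConfigurationError(f"unknown scan target {name!r}")
        new_kin = tuple(
            replace(k, vmax=k.vmax * expanded.get(k.reaction_id, 1.0))
            for k in self.kinetics
        )
        return replace(self, kinetics=new_kin)

    def with_fixed(self, **values: float) -> "PathwayModel":
        return replace(self, fixed=replace(self.fixed, **values))

    # -- rate laws --------------------------------------------------------

    def reaction_rates(self, state: np.ndarray) -> np.ndarray:
        return reaction_rates(state, self)

    def time_derivatives(self, state: np.ndarray) -> np.ndarray:
        return time_derivatives(state, self)

    # -- analysis front-ends (implemented in sibling modules) -------------

    def steady_state(self, init=None, tol: float = 1e-9, t_max: float = 1e6):
        from .steady_state import find_steady_state

        return find_steady_state(self, init=init, tol=tol, t_max=t_max)

    def scan(self, target: str, factors: Sequence[float], **kw):
        from .steady_state import scan_vmax

        return scan_vmax(self, target, factors, **kw)

    def control_coefficients(self, delta: float = 0.01):
        from .steady_state import flux_control_coefficients

        return flux_control_coefficients(self, delta=delta)

    def trends(self, driver: str = "PLSB", factors: Sequence[float] | None = None):
        from .steady_state import predict_trends

        return predict_trends(self, driver=driver, factors=factors)

    def robustness(self, fold_range: float = 4.0, n_samples: int = 100, seed: int = 0):
        from .steady_state import robustness_analysis

        return robustness_analysis(
            self, fold_range=fold_range, n_samples=n_samples, seed=seed
        )

    def simulate(self, events=(), t_end: float = 60.0, dt: float = 0.5, init=None):
        from .dynamics import simulate_timecourse

        return simulate_timecourse(self, events=events, t_end=t_end, dt=dt, init=init)


def _inhibitor_pairs(
    kin: ReactionKinetics, state: np.ndarray
) -> list[tuple[float, float]]:
    return [(state[_SPECIES_INDEX[inh.species]], inh.ki) for inh in kin.inhibitors]


def reaction_rates(state: np.ndarray, model: PathwayModel) -> np.ndarray:
    """Evaluate all reaction rates at a (nonnegative) dynamic state.

    Numerical integrators may step marginally below zero; concentrations are
    floored at 0 inside the rate laws so rates stay nonnegative.
    """
    state = np.maximum(np.asarray(state, dtype=float), 0.0)
    if state.shape != (len(SPECIES),):
        raise ValueError(f"state must have shape ({len(SPECIES)},)")
    kin = model.kinetics_by_id
    fx = model.fixed
    s = {name: state[i] for name, i in _SPECIES_INDEX.items()}

    def mm(rid: str, a: float, b: float | None = None) -> float:
        k = kin[rid]
        pairs = _inhibitor_pairs(k, state)
        if b is None:
            v = competitive_mm_rate(k.vmax, a, k.km_a, pairs)
        else:
            if k.km_b is None:
                raise ConfigurationError(f"{rid}: km_b required for two substrates")
            v = two_substrate_mm_rate(k.vmax, a, k.km_a, b, k.km_b, pairs)
        if k.ki_ppgpp is not None and fx.ppgpp > 0:
            v /= 1.0 + fx.ppgpp / k.ki_ppgpp
        return v

    rates = np.empty(len(REACTIONS))
    rates[_REACTION_INDEX["ACC"]] = mm("ACC", fx.acetyl_coa, s["holo_acp"])
    rates[_REACTION_INDEX["ELONG_C14OH"]] = mm("ELONG_C14OH", s["malonyl_acp"])
    rates[_REACTION_INDEX["FABZ"]] = mm("FABZ", s["c14_oh_acp"])
    rates[_REACTION_INDEX["LPXC"]] = mm("LPXC", s["c14_oh_acp"])
    rates[_REACTION_INDEX["ELONG_C16"]] = mm("ELONG_C16", s["c14_acp"], s["malonyl_acp"])
    rates[_REACTION_INDEX["ELONG_C18"]] = mm("ELONG_C18", s["c16_acp"], s["malonyl_acp"])
    rates[_REACTION_INDEX["PLSB_C16"]] = mm("PLSB_C16", s["c16_acp"], fx.g3p)
    rates[_REACTION_INDEX["PLSB_C18"]] = mm("PLSB_C18", s["c18_acp"], fx.g3p)
    rates[_REACTION_INDEX["PLSC"]] = mm("PLSC", s["lpa"], fx.c16_1_acp)
    rates[_REACTION_INDEX["CDSA"]] = mm("CDSA", s["pa"])
    rates[_REACTION_INDEX["PSSA"]] = mm("PSSA", s["cdp_dag"])
    rates[_REACTION_INDEX["PSD"]] = mm("PSD", s["ps"])
    return rates


def time_derivatives(state: np.ndarray, model: PathwayModel) -> np.ndarray:
    """d[species]/dt = stoichiometry · rates (µM·min⁻¹)."""
    return model.stoichiometry @ reaction_rates(state, model)


def total_acp(state: np.ndarray | Mapping[str, float]) -> float:
    """Sum of the six ACP-carrying species (conserved along trajectories)."""
    if isinstance(state, Mapping):
        return float(sum(state[s] for s in ACP_SPECIES))
    state = np.asarray(state, dtype=float)
    return float(state[: len(ACP_SPECIES)].sum())


# ---------------------------------------------------------------------------
# Default parameterization
#
# The baseline steady state is designed first and the Vmax values are derived
# from it, so the shipped concentrations are an exact fixed point (see
# scripts/calibrate_defaults.py for the construction and checks). Key regime
# choices: strong feedback of C16:0-/C18:0-ACP on ACC (I >> Ki), PlsB far
# from acyl-ACP saturation, downstream PL enzymes with ample headroom. These
# make the pathway flux scale ~ sqrt(Vmax_ACC * Vmax_PlsB), so a 4-fold Vmax
# change in either enzyme moves flux ~2-fold while the others carry almost
# no flux control.
# ---------------------------------------------------------------------------

#: Designed baseline steady-state concentrations (µM).
BASELINE_STATE: dict[str, float] = {
    "holo_acp": 60.0,
    "malonyl_acp": 2.5,
    "c14_oh_acp": 2.0,
    "c14_acp": 2.0,
    "c16_acp": 2.0,
    "c18_acp": 1.0,
    "lpa": 2.0,
    "pa": 2.0,
    "cdp_dag": 2.0,
    "ps": 2.0,
}

#: Designed baseline fluxes (µM·min⁻¹); the remaining fluxes follow from
#: steady-state balance.
BASELINE_FLUXES: dict[str, float] = {
    "ACC": 5.0,
    "ELONG_C14OH": 2.5,
    "FABZ": 2.0,
    "LPXC": 0.5,
    "ELONG_C16": 2.0,
    "ELONG_C18": 0.5,
    "PLSB_C16": 1.5,
    "PLSB_C18": 0.5,
    "PLSC": 2.0,
    "CDSA": 2.0,
    "PSSA": 2.0,
    "PSD": 2.0,
}

_DEFAULT_FIXED = FixedInputs(acetyl_coa=100.0, g3p=200.0, c16_1_acp=1.0, ppgpp=0.0)

#: Km / Ki choices for the default model (µM).
_DEFAULT_KM: dict[str, dict[str, float]] = {
    "ACC": {"km_a": 50.0, "km_b": 10.0},
    "ELONG_C14OH": {"km_a": 10.0},
    "FABZ": {"km_a": 8.0},
    "LPXC": {"km_a": 8.0},
    "ELONG_C16": {"km_a": 8.0, "km_b": 10.0},
    "ELONG_C18": {"km_a": 8.0, "km_b": 10.0},
    "PLSB_C16": {"km_a": 50.0, "km_b": 100.0},
    "PLSB_C18": {"km_a": 50.0, "km_b": 100.0},
    "PLSC": {"km_a": 10.0, "km_b": 1.0},
    "CDSA": {"km_a": 10.0},
    "PSSA": {"km_a": 10.0},
    "PSD": {"km_a": 10.0},
}

_KI_ACYL_ACP = 0.1   # µM; C16:0-/C18:0-ACP feedback on ACC (strong)
_KI_PPGPP = 10.0     # µM; posttranslational ppGpp inhibition of PlsB


def _saturation(kin_id: str, state: Mapping[str, float], fixed: FixedInputs) -> float:
    """Fractional saturation (rate / Vmax) of a default reaction at a state."""
    km = _DEFAULT_KM[kin_id]

    def f(conc: float, k: float, alpha: float = 1.0) -> float:
        return conc / (k * alpha + conc)

    if kin_id == "ACC":
        alpha = 1.0 + (state["c16_acp"] + state["c18_acp"]) / _KI_ACYL_ACP
        return f(fixed.acetyl_coa, km["km_a"], alpha) * f(state["holo_acp"], km["km_b"])
    if kin_id == "ELONG_C14OH":
        return f(state["malonyl_acp"], km["km_a"])
    if kin_id in ("FABZ", "LPXC"):
        return f(state["c14_oh_acp"], km["km_a"])
    if kin_id == "ELONG_C16":
        return f(state["c14_acp"], km["km_a"]) * f(state["malonyl_acp"], km["km_b"])
    if kin_id == "ELONG_C18":
        return f(state["c16_acp"], km["km_a"]) * f(state["malonyl_acp"], km["km_b"])
    if kin_id == "PLSB_C16":
        return f(state["c16_acp"], km["km_a"]) * f(fixed.g3p, km["km_b"])
    if kin_id == "PLSB_C18":
        return f(state["c18_acp"], km["km_a"]) * f(fixed.g3p, km["km_b"])
    if kin_id == "PLSC":
        return f(state["lpa"], km["km_a"]) * f(fixed.c16_1_acp, km["km_b"])
    if kin_id == "CDSA":
        return f(state["pa"], km["km_a"])
    if kin_id == "PSSA":
        return f(state["cdp_dag"], km["km_a"])
    if kin_id == "PSD":
        return f(state["ps"], km["km_a"])
    raise ConfigurationError(kin_id)


def default_model() -> PathwayModel:
    """The shipped baseline model (BASELINE_STATE is its exact steady state)."""
    kinetics = []
    for rid in REACTIONS:
        sat = _saturation(rid, BASELINE_STATE, _DEFAULT_FIXED)
        vmax = BASELINE_FLUXES[rid] / sat
        km = _DEFAULT_KM[rid]
        inhibitors: tuple[Inhibitor, ...] = ()
        ki_ppgpp = None
        if rid == "ACC":
            inhibitors = (
                Inhibitor("c16_acp", _KI_ACYL_ACP),
                Inhibitor("c18_acp", _KI_ACYL_ACP),
            )
        if rid in PLSB_REACTIONS:
            ki_ppgpp = _KI_PPGPP
        kinetics.append(
            ReactionKinetics(
                reaction_id=rid,
                vmax=vmax,
                km_a=km["km_a"],
                km_b=km.get("km_b"),
                inhibitors=inhibitors,
                ki_ppgpp=ki_ppgpp,
            )
        )
    acp_total = sum(BASELINE_STATE[s] for s in ACP_SPECIES)
    return PathwayModel(
        kinetics=tuple(kinetics), fixed=_DEFAULT_FIXED, acp_total=acp_total
    )


def baseline_state_vector() -> np.ndarray:
    """BASELINE_STATE as a state vector in SPECIES order."""
    return np.array([BASELINE_STATE[s] for s in SPECIES])


def state_to_dict(state: np.ndarray) -> dict[str, float]:
    state = np.asarray(state, dtype=float)
    return {name: float(state[i]) for name, i in _SPECIES_INDEX.items()}


def species_index(name: str) -> int:
    return _SPECIES_INDEX[name]


def reaction_index(name: str) -> int:
    return _REACTION_INDEX[name]
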