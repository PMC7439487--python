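"""Steady states, Vmax scans, flux control coefficients and trend curves.

The pathway output fluxes are:

* PE flux — the rate of the terminal PS decarboxylation step (Psd), equal
  at steady state to the summed PlsB flux;
* LPS flux — the rate of the lumped LpxA/LpxC drain on C14:0-OH-ACP.

Steady states are found by integrating the ODE system to quiescence and
then refining with a root solve on the derivative map, with the ACP
conservation law substituted for the holo-ACP balance (the two routes are
cross-checked in the test suite). Flux control coefficients
C^J = d ln J / d ln Vmax are computed by centred finite differences in log
space; because every rate law is homogeneous of degree 1 in its Vmax, the
coefficients obey the summation theorem Σ C^J = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import (
    ACP_SPECIES,
    PLSB_REACTIONS,
    REACTIONS,
    SPECIES,
    Inhibitor,
    PathwayModel,
    ReactionKinetics,
    baseline_state_vector,
    reaction_index,
    reaction_rates,
    species_index,
    time_derivatives,
    total_acp,
)

__all__ = [
    "SteadyStateResult",
    "ScanResult",
    "ControlCoefficients",
    "TrendCurves",
    "RobustnessReport",
    "find_steady_state",
    "pathway_fluxes",
    "scan_vmax",
    "flux_control_coefficients",
    "predict_trends",
    "robustness_analysis",
    "SCAN_TARGETS",
]

#: Valid scan targets: reaction Vmax values, the joint PlsB scale, and the
#: fixed boundary concentrations.
SCAN_TARGETS: tuple[str, ...] = REACTIONS + ("PLSB", "acetyl_coa", "g3p", "c16_1_acp")

_FIXED_TARGETS = ("acetyl_coa", "g3p", "c16_1_acp")


class NotConvergedError(RuntimeError):
    """A steady state was requested from an unconverged result."""


@dataclass(frozen=True)
class SteadyStateResult:
    """Converged concentrations and reaction fluxes of a pathway model."""

    model: PathwayModel
    state: np.ndarray
    fluxes: np.ndarray
    converged: bool
    residual: float

    @property
    def concentrations(self) -> dict[str, float]:
        return {name: float(self.state[i]) for i, name in enumerate(SPECIES)}

    @property
    def flux_by_reaction(self) -> dict[str, float]:
        return {name: float(self.fluxes[i]) for i, name in enumerate(REACTIONS)}

    @property
    def pe_flux(self) -> float:
        return float(self.fluxes[reaction_index("PSD")])

    @property
    def lps_flux(self) -> float:
        return float(self.fluxes[reaction_index("LPXC")])

    def summary(self) -> str:
        lines = ["Steady state"]
        lines.append(f"  converged: {self.converged}   residual: {self.residual:.3e} uM/min")
        lines.append(f"  PE flux:  {self.pe_flux:.6g} uM/min")
        lines.append(f"  LPS flux: {self.lps_flux:.6g} uM/min")
        lines.append(f"  total ACP: {total_acp(self.state):.6g} uM")
        lines.append("  concentrations (uM):")
        for name, value in self.concentrations.items():
            lines.append(f"    {name:<12s} {value:.6g}")
        lines.append("  fluxes (uM/min):")
        for name, value in self.flux_by_reaction.items():
            lines.append(f"    {name:<12s} {value:.6g}")
        return "\n".join(lines)


def _reduced_residual(model: PathwayModel, acp_tot: float):
    """Derivative map with holo-ACP eliminated via ACP conservation.

    Unknowns are the 9 species other than holo-ACP (clipped at 0); the
    holo-ACP balance is the linearly dependent equation that conservation
    replaces.
    """
    n_acp_free = len(ACP_SPECIES) - 1

    def assemble(z: np.ndarray) -> np.ndarray:
        z = np.maximum(z, 0.0)
        holo = acp_tot - z[:n_acp_free].sum()
        return np.concatenate(([holo], z))

    def fun(z: np.ndarray) -> np.ndarray:
        return time_derivatives(assemble(z), model)[1:]

    return fun, assemble


def find_steady_state(
    model: PathwayModel,
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    t_max: float = 1e6,
) -> SteadyStateResult:
    """Locate a steady state by integration-to-quiescence plus root refinement.

    Parameters
    ----------
    init : initial concentrations (SPECIES order); defaults to the shipped
        baseline reshaped to the model's ACP total.
    tol : residual bound max|dx/dt| (µM·min⁻¹) for convergence.
    t_max : integration horizon (min); non-convergence within it yields a
        result flagged ``converged=False`` rather than an exception.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if init is None:
        init = baseline_state_vector()
        init = init * (model.acp_total / total_acp(init)) if total_acp(init) else init
        # rescaling all species keeps ACP consistency with the model total
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise ValueError("initial concentrations must be >= 0")
    acp_tot = total_acp(init)

    fun, assemble = _reduced_residual(model, acp_tot)

    def refined(z0: np.ndarray) -> np.ndarray | None:
        sol = root(fun, z0, method="hybr", tol=1e-13)
        x = assemble(sol.x)
        if np.any(x < -1e-9):
            return None
        x = np.maximum(x, 0.0)
        if np.abs(time_derivatives(x, model)).max() <= max(tol, 1e-12):
            return x
        return None

    # Warm path: when init is already near a steady state (scan continuation),
    # the root solve alone succeeds and integration is skipped.
    x = refined(init[1:])
    if x is None:
        rhs = lambda t, y: time_derivatives(y, model)  # noqa: E731
        y = init
        t_done = 0.0
        horizon = min(1e3, t_max)
        while t_done < t_max:
            sol = solve_ivp(
                rhs, (0.0, horizon), y, method="LSODA", rtol=1e-10, atol=1e-12
            )
            y = np.maximum(sol.y[:, -1], 0.0)
            t_done += horizon
            horizon = min(horizon * 10.0, max(t_max - t_done, 0.0))
            x = refined(y[1:])
            if x is not None:
                break
            if np.abs(time_derivatives(y, model)).max() <= tol:
                x = y
                break
        if x is None:
            residual = float(np.abs(time_derivatives(y, model)).max())
            return SteadyStateResult(
                model=model,
                state=y,
                fluxes=reaction_rates(y, model),
                converged=residual <= tol,
                residual=residual,
            )
    residual = float(np.abs(time_derivatives(x, model)).max())
    return SteadyStateResult(
        model=model,
        state=x,
        fluxes=reaction_rates(x, model),
        converged=residual <= tol,
        residual=residual,
    )


def pathway_fluxes(ss: SteadyStateResult) -> tuple[float, float]:
    """(PE flux, LPS flux) of a converged steady state."""
    if not ss.converged:
        raise NotConvergedError(
            f"steady state did not converge (residual {ss.residual:.3e})"
        )
    return ss.pe_flux, ss.lps_flux


def _apply_factor(model: PathwayModel, target: str, factor: float) -> PathwayModel:
    if target in _FIXED_TARGETS:
        base = getattr(model.fixed, target)
        return model.with_fixed(**{target: base * factor})
    return model.with_vmax_factors({target: factor})


@dataclass(frozen=True)
class ScanResult:
    """Steady-state flux and concentration response to a parameter scan."""

    target: str
    factors: np.ndarray
    pe_flux: np.ndarray
    lps_flux: np.ndarray
    concentrations: np.ndarray  # (n_factors, n_species)
    converged: np.ndarray

    def concentration_curve(self, species: str) -> np.ndarray:
        return self.concentrations[:, species_index(species)]

    def to_frame(self):
        import pandas as pd

        data = {
            "target": self.target,
            "factor": self.factors,
            "pe_flux": self.pe_flux,
            "lps_flux": self.lps_flux,
            "converged": self.converged,
        }
        for i, name in enumerate(SPECIES):
            data[name] = self.concentrations[:, i]
        return pd.DataFrame(data)

    def summary(self) -> str:
        lines = [f"Vmax/concentration scan: target {self.target}"]
        lines.append(f"{'factor':>8s} {'PE flux':>12s} {'LPS flux':>12s} {'conv':>5s}")
        for f, pe, lps, c in zip(
            self.factors, self.pe_flux, self.lps_flux, self.converged
        ):
            lines.append(f"{f:8.3g} {pe:12.6g} {lps:12.6g} {str(bool(c)):>5s}")
        return "\n".join(lines)


def scan_vmax(
    model: PathwayModel,
    target: str,
    factors,
    tol: float = 1e-9,
) -> ScanResult:
    """Recompute the steady state for each multiplier of a scan target.

    ``target`` is a reaction id, ``"PLSB"`` (both acyl-ACP channels jointly)
    or a fixed boundary concentration. Points are warm-started from the
    nearest previously solved factor for speed and branch continuity.
    """
    if target not in SCAN_TARGETS:
        raise ValueError(f"unknown scan target {target!r}; one of {SCAN_TARGETS}")
    factors = np.asarray(list(factors), dtype=float)
    if np.any(factors <= 0):
        raise ValueError("scan factors must be > 0")
    # march outward from factor 1 along each branch, warm-starting each point
    # from its neighbour for speed and continuity
    idx = np.arange(len(factors))
    upward = sorted(idx[factors >= 1.0], key=lambda i: factors[i])
    downward = sorted(idx[factors < 1.0], key=lambda i: -factors[i])

    base = find_steady_state(model, tol=tol)
    n = len(factors)
    pe = np.empty(n)
    lps = np.empty(n)
    conc = np.empty((n, len(SPECIES)))
    conv = np.zeros(n, dtype=bool)
    for branch in (upward, downward):
        prev_state = base.state
        for i in branch:
            m_i = _apply_factor(model, target, factors[i])
            ss = find_steady_state(m_i, init=prev_state, tol=tol)
            pe[i], lps[i] = ss.pe_flux, ss.lps_flux
            conc[i] = ss.state
            conv[i] = ss.converged
            if ss.converged:
                prev_state = ss.state
    return ScanResult(
        target=target,
        factors=factors,
        pe_flux=pe,
        lps_flux=lps,
        concentrations=conc,
        converged=conv,
    )


@dataclass(frozen=True)
class ControlCoefficients:
    """Flux control coefficients C^J = d ln J / d ln Vmax per reaction."""

    pe: dict[str, float]
    lps: dict[str, float]
    delta: float
    missing: tuple[str, ...] = ()

    @property
    def pe_sum(self) -> float:
        return float(sum(v for v in self.pe.values() if not math.isnan(v)))

    @property
    def lps_sum(self) -> float:
        return float(sum(v for v in self.lps.values() if not math.isnan(v)))

    def lumped(self, flux: str = "pe") -> dict[str, float]:
        """Coefficients with the two PlsB channels summed into one 'PLSB'."""
        coeffs = dict(self.pe if flux == "pe" else self.lps)
        plsb = sum(coeffs.pop(r, 0.0) for r in PLSB_REACTIONS)
        coeffs["PLSB"] = plsb
        return coeffs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "reaction": list(self.pe),
                "C_pe_flux": list(self.pe.values()),
                "C_lps_flux": [self.lps[r] for r in self.pe],
            }
        )

    def summary(self) -> str:
        lines = ["Flux control coefficients (d ln J / d ln Vmax)"]
        lines.append(f"{'reaction':<12s} {'PE flux':>10s} {'LPS flux':>10s}")
        for rxn in self.pe:
            lines.append(f"{rxn:<12s} {self.pe[rxn]:>10.4f} {self.lps[rxn]:>10.4f}")
        lines.append(f"{'sum':<12s} {self.pe_sum:>10.4f} {self.lps_sum:>10.4f}")
        return "\n".join(lines)


def flux_control_coefficients(
    model: PathwayModel, delta: float = 0.01, tol: float = 1e-9
) -> ControlCoefficients:
    """Centred finite-difference control coefficients for PE and LPS flux.

    ``delta`` is the half-width of the log-space perturbation (default 1%).
    Reactions whose perturbed steady state fails to converge are reported
    as NaN and listed in ``missing``.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    base = find_steady_state(model, tol=tol)
    up, down = math.exp(delta), math.exp(-delta)
    pe: dict[str, float] = {}
    lps: dict[str, float] = {}
    missing: list[str] = []
    for rxn in REACTIONS:
        try:
            hi = find_steady_state(
                model.with_vmax_factors({rxn: up}), init=base.state, tol=tol
            )
            lo = find_steady_state(
                model.with_vmax_factors({rxn: down}), init=base.state, tol=tol
            )
        except Exception:
            hi = lo = None
        if hi is None or lo is None or not (hi.converged and lo.converged):
            pe[rxn] = lps[rxn] = float("nan")
            missing.append(rxn)
            continue
        pe[rxn] = (math.log(hi.pe_flux) - math.log(lo.pe_flux)) / (2 * delta)
        lps[rxn] = (math.log(hi.lps_flux) - math.log(lo.lps_flux)) / (2 * delta)
    return ControlCoefficients(pe=pe, lps=lps, delta=delta, missing=tuple(missing))


#: Species plotted in the concentration-trend analysis.
TREND_SPECIES: tuple[str, ...] = SPECIES

#: Drivers the trend analysis accepts.
TREND_DRIVERS: tuple[str, ...] = ("PLSB", "ACC", "acetyl_coa")


@dataclass(frozen=True)
class TrendCurves:
    """log2 concentration vs log2 PE-flux curves for one scan driver.

    Both axes are normalised to the baseline (factor 1) steady state, so
    every curve passes through (0, 0).
    """

    driver: str
    factors: np.ndarray
    log2_pe_flux: np.ndarray
    log2_concentrations: np.ndarray  # (n_factors, n_species)
    converged: np.ndarray

    def curve(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        return self.log2_pe_flux, self.log2_concentrations[:, species_index(species)]

    def slope(self, species: str) -> float:
        """Least-squares slope of log2 concentration vs log2 PE flux."""
        x, y = self.curve(species)
        ok = self.converged.astype(bool)
        x, y = x[ok], y[ok]
        denom = float(np.sum((x - x.mean()) ** 2))
        if denom == 0:
            return 0.0
        return float(np.sum((x - x.mean()) * (y - y.mean())) / denom)

    @property
    def slopes(self) -> dict[str, float]:
        return {s: self.slope(s) for s in TREND_SPECIES}

    @property
    def signs(self) -> dict[str, int]:
        """Sign of each species' trend (0 for a slope within ±1e-6)."""
        out = {}
        for s, m in self.slopes.items():
            out[s] = 0 if abs(m) < 1e-6 else (1 if m > 0 else -1)
        return out

    def to_frame(self):
        import pandas as pd

        data = {
            "driver": self.driver,
            "factor": self.factors,
            "log2_pe_flux": self.log2_pe_flux,
            "converged": self.converged,
        }
        for i, name in enumerate(SPECIES):
            data[f"log2_{name}"] = self.log2_concentrations[:, i]
        return pd.DataFrame(data)

    def summary(self) -> str:
        lines = [f"Concentration trends vs PE flux (driver: {self.driver})"]
        lines.append(f"{'species':<12s} {'slope':>9s} {'sign':>5s}")
        for sp in TREND_SPECIES:
            m = self.slope(sp)
            lines.append(f"{sp:<12s} {m:>9.4f} {self.signs[sp]:>5d}")
        return "\n".join(lines)


def predict_trends(
    model: PathwayModel,
    driver: str = "PLSB",
    factors=None,
    tol: float = 1e-9,
) -> TrendCurves:
    """Concentration-vs-flux trend curves for a PlsB/ACC/acetyl-CoA driver."""
    if driver not in TREND_DRIVERS:
        raise ValueError(f"driver must be one of {TREND_DRIVERS}")
    if factors is None:
        factors = np.exp2(np.linspace(-2.0, 2.0, 9))  # 0.25 .. 4, through 1
    factors = np.asarray(list(factors), dtype=float)
    if not (factors.min() <= 1.0 <= factors.max()):
        raise ValueError("factor grid must span the baseline factor 1")
    scan = scan_vmax(model, driver, factors, tol=tol)
    i0 = int(np.argmin(np.abs(np.log(factors))))
    pe0 = scan.pe_flux[i0]
    conc0 = scan.concentrations[i0]
    if pe0 <= 0 or np.any(conc0 <= 0):
        raise RuntimeError(
            "baseline steady state has vanished flux or concentrations; "
            "trends are undefined"
        )
    usable = scan.converged & (scan.pe_flux > 0) & np.all(
        scan.concentrations > 0, axis=1
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_pe = np.where(usable, np.log2(scan.pe_flux / pe0), np.nan)
        log2_conc = np.where(
            usable[:, None],
            np.log2(np.maximum(scan.concentrations, 1e-300) / conc0),
            np.nan,
        )
    return TrendCurves(
        driver=driver,
        factors=factors,
        log2_pe_flux=log2_pe,
        log2_concentrations=log2_conc,
        converged=usable,
    )


@dataclass(frozen=True)
class RobustnessReport:
    """Sign stability of PlsB-driven trends under global parameter noise."""

    fold_range: float
    n_samples: int
    seed: int
    baseline_signs: dict[str, int]
    sign_fraction: dict[str, float]  # fraction of samples matching baseline
    n_converged: int
    n_failed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "species": list(self.baseline_signs),
                "baseline_sign": list(self.baseline_signs.values()),
                "stable_fraction": [
                    self.sign_fraction[s] for s in self.baseline_signs
                ],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Trend-sign robustness: {self.n_samples} samples, "
            f"{self.fold_range}-fold parameter range, seed {self.seed}"
        ]
        lines.append(f"  converged samples: {self.n_converged}, failed: {self.n_failed}")
        lines.append(f"{'species':<12s} {'sign':>5s} {'stable':>8s}")
        for sp, sg in self.baseline_signs.items():
            lines.append(f"{sp:<12s} {sg:>5d} {self.sign_fraction[sp]:>8.2%}")
        return "\n".join(lines)


def _perturbed_model(model: PathwayModel, rng: np.random.Generator, span: float):
    """All kinetic parameters scaled log-uniformly within a fold-span."""

    def draw() -> float:
        return float(np.exp(rng.uniform(-0.5, 0.5) * math.log(span)))

    new_kin = []
    for k in model.kinetics:
        new_kin.append(
            ReactionKinetics(
                reaction_id=k.reaction_id,
                vmax=k.vmax * draw(),
                km_a=k.km_a * draw(),
                km_b=None if k.km_b is None else k.km_b * draw(),
                inhibitors=tuple(
                    Inhibitor(i.species, i.ki * draw()) for i in k.inhibitors
                ),
                ki_ppgpp=None if k.ki_ppgpp is None else k.ki_ppgpp * draw(),
            )
        )
    from dataclasses import replace

    return replace(model, kinetics=tuple(new_kin))


def robustness_analysis(
    model: PathwayModel,
    fold_range: float = 4.0,
    n_samples: int = 100,
    seed: int = 0,
    trend_factors=(0.5, 1.0, 2.0),
    tol: float = 1e-9,
) -> RobustnessReport:
    """Sign stability of the PlsB-driver trends under parameter variation.

    Every kinetic parameter (Vmax, Km, Ki) is independently scaled by a
    log-uniform factor within ``fold_range`` (total span; e.g. 4-fold means
    between 1/2 and 2 times its default). For each sampled parameter set the
    PlsB-driver trend signs are recomputed and compared with the baseline
    model's signs. Samples whose scans fail to converge are excluded and
    counted.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if fold_range < 1:
        raise ValueError("fold_range must be >= 1")
    rng = np.random.default_rng(seed)
    baseline = predict_trends(model, "PLSB", factors=trend_factors, tol=tol)
    base_signs = baseline.signs
    matches = {s: 0 for s in TREND_SPECIES}
    n_ok = 0
    n_fail = 0
    for _ in range(n_samples):
        m = _perturbed_model(model, rng, fold_range)
        try:
            trends = predict_trends(m, "PLSB", factors=trend_factors, tol=tol)
        except Exception:
            n_fail += 1
            continue
        if not trends.converged.all():
            n_fail += 1
            continue
        n_ok += 1
        for s, sg in trends.signs.items():
            if sg == base_signs[s]:
                matches[s] += 1
    frac = {
        s: (matches[s] / n_ok if n_ok else float("nan")) for s in TREND_SPECIES
    }
    return RobustnessReport(
        fold_range=fold_range,
        n_samples=n_samples,
        seed=seed,
        baseline_signs=base_signs,
        sign_fraction=frac,
        n_converged=n_ok,
        n_failed=n_fail,
    )
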