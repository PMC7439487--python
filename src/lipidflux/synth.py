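"""Synthetic steady-state LC/MS condition tables with planted ground truth.

The generator emulates the structure of a steady-state growth-rate series:
6 defined-media conditions spanning a 3-fold range of growth rates µ, with
2 independent biological replicate series and 3 sampling replicates each.
Growth rate is mapped to PlsB activity (the posttranslational control knob)
log-linearly so that the kinetic model's PE flux spans 2-fold while µ spans
3-fold — the empirical relationship between PL flux and growth rate. The
model's steady-state concentrations at each condition become "true" analyte
levels, which are converted to LC/MS-style counts via arbitrary per-analyte
response factors and corrupted with multiplicative lognormal noise (a
constant-CV error model appropriate for spectral counts), plus a smaller
lognormal factor shared within each biological replicate series.

Total-PE counts are emitted so that total-PE per OD declines mildly with µ
(flux spans 2-fold over a 3-fold µ range, so PE/OD ∝ flux/µ falls),
matching the observation that the PL-to-biomass ratio is higher in
slow-growing cells.

``PlantedTruth`` records the noiseless normalised series and the trend sign
of each analyte against PL flux, enabling recovery testing of the
correlation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SPECIES, PathwayModel, default_model
from .steady_state import find_steady_state

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_steady_state_dataset",
    "generate_fixture_table",
    "ANALYTE_CLASSES",
]

#: Volume basis per model species when reported as an LC/MS analyte:
#: ACP species and soluble intermediates are per cell volume (OD); PL
#: intermediates are per membrane volume (total PE).
ANALYTE_CLASSES: dict[str, str] = {
    "holo_acp": "per_od",
    "malonyl_acp": "per_od",
    "c14_oh_acp": "per_od",
    "c14_acp": "per_od",
    "c16_acp": "per_od",
    "c18_acp": "per_od",
    "lpa": "per_total_pe",
    "pa": "per_total_pe",
    "cdp_dag": "per_total_pe",
    "ps": "per_total_pe",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic steady-state growth-rate series.

    Defaults mirror the study conditions: 6 media spanning a 3-fold µ
    range, 3 sampling replicates nested in 2 biological replicate series,
    10% measurement CV and 5% biological-replicate CV.
    """

    n_conditions: int = 6
    mu_range: tuple[float, float] = (0.33, 1.0)
    n_bio: int = 2
    n_tech: int = 3
    noise_cv: float = 0.1
    bio_cv: float = 0.05
    seed: int = 0
    plsb_fold_span: float = 4.0  # PlsB Vmax factor range across the µ range
    n_null_analytes: int = 0  # flux-independent analytes for calibration tests

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.mu_range[0] <= 0 or self.mu_range[1] <= self.mu_range[0]:
            raise ValueError("mu_range must be increasing and positive")
        if self.noise_cv < 0 or self.bio_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.plsb_fold_span <= 0:
            raise ValueError("plsb_fold_span must be > 0")
        if self.n_null_analytes < 0:
            raise ValueError("n_null_analytes must be >= 0")

    @property
    def mu_grid(self) -> np.ndarray:
        lo, hi = self.mu_range
        return np.exp(np.linspace(np.log(lo), np.log(hi), self.n_conditions))

    def plsb_factor(self, mu: np.ndarray) -> np.ndarray:
        """Monotone log-linear µ → PlsB Vmax factor, centred on 1.

        The factor spans ``plsb_fold_span`` across the µ range; with the
        default 4-fold span and the shipped model (flux ∝ sqrt(PlsB Vmax)),
        PE flux spans 2-fold over the 3-fold µ range.
        """
        lo, hi = self.mu_range
        x = (np.log(np.asarray(mu, dtype=float)) - np.log(lo)) / (
            np.log(hi) - np.log(lo)
        )
        span = np.log(self.plsb_fold_span)
        return np.exp((x - 0.5) * span)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth behind a synthetic dataset (pre-noise).

    ``noiseless_r`` is the Pearson r of the noiseless normalised series
    against the noiseless log2 flux; over a handful of log-spaced conditions
    it is ~±1 for any monotone species regardless of amplitude, so it is not
    informative about detectability. ``planted_r`` is the population
    correlation the generative model implies: the noiseless r attenuated by
    the known lognormal noise variance of both the analyte series and the
    flux series. It is computed in closed form before any data are drawn and
    is the quantity recovery tests should filter on.
    """

    mu: np.ndarray
    plsb_factors: np.ndarray
    pe_flux: np.ndarray  # model PE flux per condition (µM/min)
    concentrations: pd.DataFrame  # condition × species (µM)
    normalized_log2: pd.DataFrame  # condition × analyte, basis-corrected, centred
    noiseless_r: dict[str, float]
    planted_r: dict[str, float]  # attenuated (population) correlation
    trend_sign: dict[str, int]
    response_factors: dict[str, float]

    def sign(self, analyte: str) -> int:
        return self.trend_sign[analyte]


def _log2_noise_sd(cv: float) -> float:
    """Standard deviation on the log2 scale of a lognormal factor with CV."""
    if cv == 0:
        return 0.0
    return float(np.sqrt(np.log(1.0 + cv * cv)) / np.log(2.0))


def _attenuated_r(
    r0: float, signal_sd: float, noise_sd: float, flux_sd: float, flux_noise_sd: float
) -> float:
    """Population Pearson r after additive log-scale noise on both variables."""

    def shrink(s: float, sigma: float) -> float:
        if s == 0:
            return 0.0
        return s / np.sqrt(s * s + sigma * sigma)

    return float(r0 * shrink(signal_sd, noise_sd) * shrink(flux_sd, flux_noise_sd))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit median and given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _planted_normalized(
    conc: pd.DataFrame, pe_per_od: np.ndarray
) -> pd.DataFrame:
    """Noiseless per-condition series after basis correction and centring."""
    out = {}
    for sp in SPECIES:
        values = conc[sp].to_numpy()
        if ANALYTE_CLASSES[sp] == "per_total_pe":
            values = values / pe_per_od
        logged = np.log2(values)
        out[sp] = logged - logged.mean()
    return pd.DataFrame(out, index=conc.index)


def generate_steady_state_dataset(
    spec: SyntheticSpec,
    model: PathwayModel | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a tidy synthetic condition table plus its planted truth.

    Raises if the kinetic model fails to reach a steady state at any
    condition (naming the condition).
    """
    if model is None:
        model = default_model()
    rng = np.random.default_rng(spec.seed)
    mu = spec.mu_grid
    factors = spec.plsb_factor(mu)
    conditions = [f"cond{i + 1}" for i in range(spec.n_conditions)]

    conc_rows = []
    pe_flux = np.empty(spec.n_conditions)
    prev = None
    for i, (label, f) in enumerate(zip(conditions, factors)):
        m = model.with_vmax_factors({"PLSB": float(f)})
        ss = find_steady_state(m, init=prev)
        if not ss.converged:
            raise RuntimeError(
                f"no steady state at condition {label} (PlsB factor {f:.3g})"
            )
        prev = ss.state
        pe_flux[i] = ss.pe_flux
        conc_rows.append(ss.concentrations)
    conc = pd.DataFrame(conc_rows, index=pd.Index(conditions, name="condition"))

    # total-PE signal per OD tracks flux/µ (units arbitrary)
    pe_per_od = pe_flux / mu
    planted = _planted_normalized(conc, pe_per_od)
    log2_flux = np.log2(pe_flux) - np.mean(np.log2(pe_flux))

    # effective per-point (pooled over sampling replicates) log2 noise sds
    meas_sd = _log2_noise_sd(spec.noise_cv) / np.sqrt(spec.n_tech)
    bio_sd = _log2_noise_sd(spec.bio_cv)
    flux_noise_sd = float(np.hypot(meas_sd, bio_sd))
    noise_sd = {
        sp: (
            float(np.hypot(meas_sd, bio_sd))
            if ANALYTE_CLASSES[sp] == "per_od"
            # ratio to the total-PE signal adds its measurement and
            # biological noise to the intermediate's own
            else float(np.hypot(np.sqrt(2.0) * meas_sd, np.sqrt(2.0) * bio_sd))
        )
        for sp in SPECIES
    }
    flux_sd = float(np.std(log2_flux))
    noiseless_r = {}
    planted_r = {}
    trend_sign = {}
    for sp in SPECIES:
        y = planted[sp].to_numpy()
        if np.std(y) == 0 or np.std(log2_flux) == 0:
            r0 = 0.0
        else:
            r0 = float(np.corrcoef(y, log2_flux)[0, 1])
        noiseless_r[sp] = r0
        planted_r[sp] = _attenuated_r(
            r0, float(np.std(y)), noise_sd[sp], flux_sd, flux_noise_sd
        )
        slope = float(
            np.polyfit(log2_flux, y, 1)[0]
        ) if np.std(log2_flux) else 0.0
        trend_sign[sp] = 0 if abs(slope) < 1e-9 else (1 if slope > 0 else -1)

    # null analytes: constant true level, hence independent of flux (their
    # measured correlation is pure noise; used to calibrate the false-positive
    # rate of the significance test)
    null_names = [f"null{i + 1}" for i in range(spec.n_null_analytes)]
    all_analytes = list(SPECIES) + null_names
    classes = dict(ANALYTE_CLASSES, **{a: "per_od" for a in null_names})
    true_level = {
        a: (conc[a] if a in SPECIES else pd.Series(1.0, index=conc.index))
        for a in all_analytes
    }
    for a in null_names:
        noiseless_r[a] = 0.0
        planted_r[a] = 0.0
        trend_sign[a] = 0

    response_factors = {
        sp: float(np.exp(rng.uniform(np.log(1e3), np.log(1e5))))
        for sp in all_analytes
    }
    rf_pe = float(np.exp(rng.uniform(np.log(1e3), np.log(1e5))))
    is_counts = {sp: 1.0e4 for sp in all_analytes}
    is_pe = 1.0e4

    rows = []
    for i, label in enumerate(conditions):
        for b in range(1, spec.n_bio + 1):
            bio_eps = {
                sp: _lognormal_factor(rng, spec.bio_cv) for sp in all_analytes
            }
            bio_eps_pe = _lognormal_factor(rng, spec.bio_cv)
            for t in range(1, spec.n_tech + 1):
                od = float(rng.uniform(0.25, 0.55))
                pe_counts = (
                    rf_pe * pe_per_od[i] * od * bio_eps_pe
                    * _lognormal_factor(rng, spec.noise_cv)
                )
                pe_row_ratio = pe_counts / is_pe
                for sp in all_analytes:
                    noise = _lognormal_factor(rng, spec.noise_cv)
                    level = float(true_level[sp].loc[label])
                    if classes[sp] == "per_od":
                        counts = (
                            response_factors[sp] * level
                            * od * bio_eps[sp] * noise
                        )
                    else:
                        # membrane-bound analytes scale with the membrane
                        # amount sampled, i.e. with the total-PE signal
                        counts = (
                            response_factors[sp]
                            * (level / pe_per_od[i])
                            * pe_row_ratio * bio_eps[sp] * noise
                        )
                    rows.append(
                        {
                            "condition": label,
                            "bio_rep": b,
                            "tech_rep": t,
                            "mu": mu[i],
                            "od": od,
                            "analyte": sp,
                            "counts": counts,
                            "is_counts": is_counts[sp],
                            "analyte_class": classes[sp],
                        }
                    )
                rows.append(
                    {
                        "condition": label,
                        "bio_rep": b,
                        "tech_rep": t,
                        "mu": mu[i],
                        "od": od,
                        "analyte": "total_pe",
                        "counts": pe_counts,
                        "is_counts": is_pe,
                        "analyte_class": "total_pe",
                    }
                )
    table = pd.DataFrame(rows)
    truth = PlantedTruth(
        mu=mu,
        plsb_factors=factors,
        pe_flux=pe_flux,
        concentrations=conc,
        normalized_log2=planted,
        noiseless_r=noiseless_r,
        planted_r=planted_r,
        trend_sign=trend_sign,
        response_factors=response_factors,
    )
    return table, truth


def generate_fixture_table(seed: int = 0) -> pd.DataFrame:
    """Tiny deterministic table (3 conditions, 2 analytes + total PE).

    Intended for unit tests and documentation examples; passes the condition
    table invariants and supports a 2-row correlation report.
    """
    spec = SyntheticSpec(
        n_conditions=3,
        mu_range=(0.4, 1.2),
        n_bio=1,
        n_tech=2,
        noise_cv=0.05,
        bio_cv=0.0,
        seed=seed,
    )
    table, _ = generate_steady_state_dataset(spec)
    keep = table["analyte"].isin(["malonyl_acp", "c18_acp", "total_pe"])
    return table[keep].reset_index(drop=True)
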