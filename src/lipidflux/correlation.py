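"""Steady-state flux–concentration correlation analysis.

The analysis asks which pathway species track phospholipid synthesis flux
across steady-state growth conditions. PL flux is defined operationally as
the total-PE LC/MS signal multiplied by the growth rate µ (PE turnover is
slow relative to synthesis, so this approximates the PL synthesis rate).
Analyte signals are corrected by their isotopically labelled internal
standards, expressed per cell volume (OD) for soluble species and enzymes
or per membrane volume (total PE) for PL intermediates, averaged over
sampling replicates, normalised to the across-condition mean, and log2
transformed. Each analyte's centred series is then correlated against the
centred log2 PL-flux series; significance is the two-tailed p-value of the
t statistic t = r·sqrt(n−2)/sqrt(1−r²) with n−2 degrees of freedom.

Input is a tidy condition table with one row per
(condition, biological replicate, sampling replicate, analyte):

    condition  bio_rep  tech_rep  mu  od  analyte  counts  is_counts  analyte_class

``analyte_class`` is ``per_od``, ``per_total_pe`` or ``total_pe`` (the
special analyte carrying the total-PE signal used for both the flux and the
membrane-volume basis).

The model-object entry point is :class:`FluxCorrelation`:

>>> fit = FluxCorrelation.from_dataframe(table).fit()
>>> print(fit.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "TOTAL_PE_ANALYTE",
    "compute_pl_flux",
    "NormalizedSeries",
    "normalize_series",
    "pl_flux_series",
    "CorrelationResult",
    "pearson_with_significance",
    "p_from_r",
    "FluxCorrelation",
    "FluxCorrelationResults",
    "correlation_report",
]

REQUIRED_COLUMNS = (
    "condition",
    "bio_rep",
    "tech_rep",
    "mu",
    "od",
    "analyte",
    "counts",
    "is_counts",
    "analyte_class",
)

#: Name of the analyte row carrying the summed PE signal.
TOTAL_PE_ANALYTE = "total_pe"

_CLASSES = ("per_od", "per_total_pe", "total_pe")

#: Replicate pooling levels: average sampling replicates and keep biological
#: replicates as points ("bio", the default, n = conditions × bio reps),
#: average everything within a condition ("condition"), or keep every
#: sampling replicate ("none").
POOLING_LEVELS = ("bio", "condition", "none")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"condition table is missing columns {missing}")
    if (table["mu"] <= 0).any():
        raise ValueError("growth rate mu must be > 0")
    if (table["od"] <= 0).any():
        raise ValueError("OD must be > 0")
    if (table["counts"] < 0).any() or (table["is_counts"] < 0).any():
        raise ValueError("counts must be >= 0")
    bad = set(table["analyte_class"]) - set(_CLASSES)
    if bad:
        raise ValueError(f"unknown analyte_class values {sorted(bad)}")
    if table["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions")
    return table


def compute_pl_flux(total_pe_counts, mu):
    """Operational PL flux: total-PE LC/MS counts × µ (counts·h⁻¹)."""
    total_pe_counts = np.asarray(total_pe_counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(total_pe_counts < 0) or np.any(mu < 0):
        raise ValueError("counts and mu must be >= 0")
    out = total_pe_counts * mu
    return float(out) if out.ndim == 0 else out


def _group_cols(pooling: str) -> list[str]:
    if pooling == "bio":
        return ["condition", "bio_rep"]
    if pooling == "condition":
        return ["condition"]
    if pooling == "none":
        return ["condition", "bio_rep", "tech_rep"]
    raise ValueError(f"pooling must be one of {POOLING_LEVELS}")


@dataclass(frozen=True)
class NormalizedSeries:
    """Centred log2 series of one analyte across pooled measurement points."""

    analyte: str
    basis: str
    index: pd.MultiIndex | pd.Index
    values: np.ndarray  # centred log2
    excluded_conditions: tuple[str, ...] = ()

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name=self.analyte)


def _per_row_normalized(table: pd.DataFrame, analyte: str) -> pd.Series:
    """IS-corrected, volume-basis-corrected value per table row."""
    sub = table[table["analyte"] == analyte]
    if sub.empty:
        raise KeyError(f"analyte {analyte!r} not in table")
    basis = sub["analyte_class"].iloc[0]
    key = ["condition", "bio_rep", "tech_rep"]
    ratio = sub["counts"] / sub["is_counts"].replace(0, np.nan)
    if basis == "per_od":
        value = ratio / sub["od"].to_numpy()
    elif basis in ("per_total_pe", "total_pe"):
        pe = table[table["analyte"] == TOTAL_PE_ANALYTE]
        if pe.empty:
            raise KeyError("table has no total_pe rows for the membrane basis")
        pe_ratio = (pe["counts"] / pe["is_counts"].replace(0, np.nan)).to_frame("pe")
        pe_ratio[key] = pe[key]
        merged = sub[key].merge(pe_ratio, on=key, how="left")
        if basis == "total_pe":
            value = ratio / sub["od"].to_numpy()  # total PE itself is per cell volume
        else:
            value = ratio.to_numpy() / merged["pe"].to_numpy()
    else:
        raise ValueError(f"unknown basis {basis!r}")
    out = pd.Series(np.asarray(value, dtype=float), index=pd.MultiIndex.from_frame(sub[key]))
    return out


def normalize_series(
    table: pd.DataFrame,
    analyte: str,
    basis: str | None = None,
    exclusions=(),
    pooling: str = "bio",
) -> NormalizedSeries:
    """Normalise one analyte to a centred log2 series.

    Steps: divide counts by internal-standard counts; divide by OD
    (``per_od``) or the matching row's IS-corrected total-PE signal
    (``per_total_pe``); average within pooling groups; drop excluded
    conditions; take log2 and subtract the across-group mean of the log
    values (equivalently, divide by the geometric mean before log2), so the
    centred series has mean exactly 0. Zero denominators flag and drop the
    point with a warning.
    """
    table = _validate_table(table)
    sub = table[table["analyte"] == analyte]
    if sub.empty:
        raise KeyError(f"analyte {analyte!r} not in table")
    actual_basis = sub["analyte_class"].iloc[0]
    if basis is not None and basis != actual_basis:
        raise ValueError(
            f"requested basis {basis!r} but table declares {actual_basis!r} "
            f"for {analyte!r}"
        )
    per_row = _per_row_normalized(table, analyte)
    frame = per_row.rename("value").reset_index()
    frame = frame[~frame["condition"].isin(set(exclusions))]
    if frame["value"].isna().any() or (frame["value"] <= 0).any():
        n_bad = int((frame["value"].isna() | (frame["value"] <= 0)).sum())
        warnings.warn(
            f"{analyte}: dropped {n_bad} measurement(s) with zero/invalid "
            "denominator or signal",
            stacklevel=2,
        )
        frame = frame[frame["value"].notna() & (frame["value"] > 0)]
    grouped = frame.groupby(_group_cols(pooling), sort=True)["value"].mean()
    logged = np.log2(grouped)
    centred = logged - logged.mean()
    return NormalizedSeries(
        analyte=analyte,
        basis=actual_basis,
        index=centred.index,
        values=centred.to_numpy(),
        excluded_conditions=tuple(exclusions),
    )


def pl_flux_series(
    table: pd.DataFrame,
    exclusions=(),
    pooling: str = "bio",
) -> NormalizedSeries:
    """Centred log2 PL-flux series: per-biomass total-PE signal × µ.

    The total-PE counts are internal-standard corrected and expressed per
    OD (so the flux is per unit biomass) before multiplying by the growth
    rate.
    """
    table = _validate_table(table)
    pe = table[table["analyte"] == TOTAL_PE_ANALYTE]
    if pe.empty:
        raise KeyError("table has no total_pe rows; PL flux is not computable")
    ratio = (
        pe["counts"] / pe["is_counts"].replace(0, np.nan) / pe["od"]
    ).to_numpy()
    flux = compute_pl_flux(np.nan_to_num(ratio, nan=0.0), pe["mu"].to_numpy())
    frame = pd.DataFrame(
        {
            "condition": pe["condition"].to_numpy(),
            "bio_rep": pe["bio_rep"].to_numpy(),
            "tech_rep": pe["tech_rep"].to_numpy(),
            "value": flux,
        }
    )
    frame = frame[~frame["condition"].isin(set(exclusions))]
    frame = frame[frame["value"] > 0]
    grouped = frame.groupby(_group_cols(pooling), sort=True)["value"].mean()
    logged = np.log2(grouped)
    centred = logged - logged.mean()
    return NormalizedSeries(
        analyte="pl_flux",
        basis="flux",
        index=centred.index,
        values=centred.to_numpy(),
        excluded_conditions=tuple(exclusions),
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r, sample size and two-tailed p for one analyte vs PL flux."""

    analyte: str
    r: float
    n: int
    p: float
    excluded_conditions: tuple[str, ...] = ()


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson r with n paired measurements.

    Uses t = r·sqrt(n−2)/sqrt(1−r²) against Student's t with n−2 degrees of
    freedom; |r| = 1 returns 0.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3 for a p-value")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_with_significance(x, y, analyte: str = "") -> CorrelationResult:
    """Sample Pearson correlation with its two-tailed t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(analyte=analyte, r=r, n=n, p=p_from_r(r, n))


class FluxCorrelation:
    """Correlation of analyte series against PL flux across conditions.

    Parameters
    ----------
    table : tidy condition table (see module docstring).
    exclusions : mapping analyte → condition labels excluded before
        centring (e.g. G3P in glycerol medium, PGP-class analytes in
        glucose + cas-amino-acids).
    pooling : replicate pooling level (see :data:`POOLING_LEVELS`).
    analytes : analytes to report; defaults to every analyte in the table
        other than the total-PE signal itself.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        exclusions: dict[str, tuple[str, ...]] | None = None,
        pooling: str = "bio",
        analytes: tuple[str, ...] | None = None,
    ):
        self.table = _validate_table(table.copy())
        self.exclusions = {k: tuple(v) for k, v in (exclusions or {}).items()}
        if pooling not in POOLING_LEVELS:
            raise ValueError(f"pooling must be one of {POOLING_LEVELS}")
        self.pooling = pooling
        if analytes is None:
            analytes = tuple(
                a
                for a in self.table["analyte"].unique()
                if a != TOTAL_PE_ANALYTE
            )
        self.analytes = tuple(analytes)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "FluxCorrelation":
        return cls(table, **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "FluxCorrelation":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)

    def fit(self) -> "FluxCorrelationResults":
        results: list[CorrelationResult] = []
        skipped: list[str] = []
        for analyte in self.analytes:
            excl = self.exclusions.get(analyte, ())
            try:
                series = normalize_series(
                    self.table, analyte, exclusions=excl, pooling=self.pooling
                )
            except KeyError:
                warnings.warn(f"analyte {analyte!r} missing from table; skipped",
                              stacklevel=2)
                skipped.append(analyte)
                continue
            flux = pl_flux_series(self.table, exclusions=excl, pooling=self.pooling)
            joined = pd.concat(
                [series.as_series(), flux.as_series()], axis=1, join="inner"
            ).dropna()
            res = pearson_with_significance(
                joined.iloc[:, 0], joined.iloc[:, 1], analyte=analyte
            )
            results.append(
                CorrelationResult(
                    analyte=analyte,
                    r=res.r,
                    n=res.n,
                    p=res.p,
                    excluded_conditions=excl,
                )
            )
        return FluxCorrelationResults(
            model=self, results=tuple(results), skipped=tuple(skipped)
        )


@dataclass(frozen=True)
class FluxCorrelationResults:
    """Per-analyte Pearson correlations with PL flux (Table-1-style)."""

    model: FluxCorrelation
    results: tuple[CorrelationResult, ...]
    skipped: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def __getitem__(self, analyte: str) -> CorrelationResult:
        for res in self.results:
            if res.analyte == analyte:
                return res
        raise KeyError(analyte)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": [r.analyte for r in self.results],
                "n": [r.n for r in self.results],
                "r": [r.r for r in self.results],
                "p_two_tailed": [r.p for r in self.results],
                "excluded_conditions": [
                    ";".join(r.excluded_conditions) for r in self.results
                ],
            }
        )

    def summary(self) -> str:
        lines = ["Pearson correlation with PL flux (two-tailed significance)"]
        lines.append(f"{'analyte':<16s} {'n':>4s} {'r':>8s} {'P':>10s}  excluded")
        for r in self.results:
            excl = ",".join(r.excluded_conditions) or "-"
            lines.append(
                f"{r.analyte:<16s} {r.n:>4d} {r.r:>8.3f} {r.p:>10.3g}  {excl}"
            )
        if self.skipped:
            lines.append(f"skipped (missing): {', '.join(self.skipped)}")
        return "\n".join(lines)


def correlation_report(
    table: pd.DataFrame,
    exclusions: dict[str, tuple[str, ...]] | None = None,
    pooling: str = "bio",
    analytes: tuple[str, ...] | None = None,
) -> list[CorrelationResult]:
    """Functional front-end: one CorrelationResult per analyte in the table."""
    fit = FluxCorrelation(
        table, exclusions=exclusions, pooling=pooling, analytes=analytes
    ).fit()
    return list(fit.results)
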