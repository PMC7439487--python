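"""Normalisation, Pearson significance and the flux-correlation report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lipidflux.correlation import (
    FluxCorrelation,
    compute_pl_flux,
    normalize_series,
    p_from_r,
    pearson_with_significance,
    pl_flux_series,
)


def _tiny_table(counts_by_condition, od=1.0, is_counts=1.0):
    """Single-analyte per-OD table with one total-PE row per sample."""
    rows = []
    for i, c in enumerate(counts_by_condition):
        cond = f"c{i + 1}"
        mu = 0.4 + 0.2 * i
        rows.append(
            dict(condition=cond, bio_rep=1, tech_rep=1, mu=mu, od=od,
                 analyte="x", counts=c, is_counts=is_counts,
                 analyte_class="per_od")
        )
        rows.append(
            dict(condition=cond, bio_rep=1, tech_rep=1, mu=mu, od=od,
                 analyte="total_pe", counts=1000.0, is_counts=1.0,
                 analyte_class="total_pe")
        )
    return pd.DataFrame(rows)


def test_compute_pl_flux_is_the_product():
    assert compute_pl_flux(1e6, 0.5) == 5e5
    assert compute_pl_flux(123.0, 0.0) == 0.0
    assert compute_pl_flux(2e6, 0.5) == 2 * compute_pl_flux(1e6, 0.5)
    with pytest.raises(ValueError):
        compute_pl_flux(-1.0, 0.5)


def test_normalize_series_hand_example():
    """Counts {2,4,8}, OD and IS all 1: centred log2 = {-1, 0, +1}."""
    table = _tiny_table([2.0, 4.0, 8.0])
    series = normalize_series(table, "x")
    assert np.allclose(sorted(series.values), [-1.0, 0.0, 1.0])
    assert series.values.mean() == pytest.approx(0.0, abs=1e-12)


def test_constant_analyte_normalizes_to_zero():
    series = normalize_series(_tiny_table([5.0, 5.0, 5.0]), "x")
    assert np.allclose(series.values, 0.0)


def test_exclusion_recenters_remaining_conditions():
    table = _tiny_table([2.0, 4.0, 8.0, 16.0])
    series = normalize_series(table, "x", exclusions=("c4",))
    assert len(series.values) == 3
    assert series.values.mean() == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_normalization_scale_invariance(scale):
    base = _tiny_table([2.0, 3.0, 9.0])
    scaled = base.copy()
    mask = scaled["analyte"] == "x"
    scaled.loc[mask, "counts"] *= scale
    a = normalize_series(base, "x").values
    b = normalize_series(scaled, "x").values
    assert np.allclose(a, b)


def test_zero_denominator_flagged_and_dropped():
    table = _tiny_table([2.0, 4.0, 8.0])
    table.loc[(table["analyte"] == "x") & (table["condition"] == "c1"),
              "is_counts"] = 0.0
    with pytest.warns(UserWarning):
        series = normalize_series(table, "x")
    assert len(series.values) == 2


def test_pearson_known_values():
    res = pearson_with_significance([1, 2, 3], [2, 4, 6])
    assert res.r == pytest.approx(1.0)
    assert pearson_with_significance([1, 2, 3], [1, 3, 2]).r == pytest.approx(0.5)


def test_pearson_matches_scipy(rng):
    for n in (5, 12, 30):
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        ours = pearson_with_significance(x, y)
        ref_r, ref_p = stats.pearsonr(x, y)
        assert ours.r == pytest.approx(ref_r, rel=1e-12)
        assert ours.p == pytest.approx(ref_p, rel=1e-9)


def test_pearson_degenerate_inputs():
    with pytest.raises(ValueError):
        pearson_with_significance([1, 2], [3, 4])
    with pytest.raises(ValueError):
        pearson_with_significance([1, 1, 1], [1, 2, 3])


def test_p_value_agrees_with_permutation_null(rng):
    """t-formula p matches an empirical permutation p within 0.01 (n=12)."""
    n = 12
    x = rng.normal(size=n)
    y = 0.8 * x + 0.8 * rng.normal(size=n)
    res = pearson_with_significance(x, y)
    n_perm = 10_000
    count = 0
    for _ in range(n_perm):
        r_perm = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r_perm) >= abs(res.r):
            count += 1
    p_perm = count / n_perm
    assert abs(res.p - p_perm) <= 0.01


def test_report_invariant_to_row_order(synthetic_dataset):
    table, _ = synthetic_dataset
    shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = FluxCorrelation.from_dataframe(table).fit().to_frame()
    b = FluxCorrelation.from_dataframe(shuffled).fit().to_frame()
    a = a.sort_values("analyte").reset_index(drop=True)
    b = b.sort_values("analyte").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_report_row_accounting(synthetic_dataset):
    table, _ = synthetic_dataset
    analytes = sorted(set(table["analyte"]) - {"total_pe"})
    fit = FluxCorrelation.from_dataframe(table).fit()
    assert len(fit) == len(analytes)
    with pytest.warns(UserWarning):
        fit2 = FluxCorrelation.from_dataframe(
            table, analytes=tuple(analytes) + ("missing_analyte",)
        ).fit()
    assert len(fit2) == len(analytes)
    assert fit2.skipped == ("missing_analyte",)


def test_perfect_monotone_analyte_gives_r_one(synthetic_dataset):
    """An analyte that is an exact power of the flux correlates perfectly."""
    table, _ = synthetic_dataset
    pe = table[table["analyte"] == "total_pe"].copy()
    flux = pe["counts"] / pe["is_counts"] / pe["od"] * pe["mu"]
    clone = pe.copy()
    clone["analyte"] = "flux_tracker"
    clone["analyte_class"] = "per_od"
    clone["counts"] = (flux ** 1.3) * pe["od"]
    clone["is_counts"] = 1.0
    table2 = pd.concat([table, clone], ignore_index=True)
    fit = FluxCorrelation.from_dataframe(table2, analytes=("flux_tracker",)).fit()
    res = fit["flux_tracker"]
    # linear-space replicate averaging of a power transform leaves r a hair
    # below 1
    assert res.r == pytest.approx(1.0, abs=1e-3)
    assert res.p < 1e-10


def test_pooling_levels_control_n(synthetic_dataset):
    table, _ = synthetic_dataset
    for pooling, expected_n in (("bio", 12), ("condition", 6), ("none", 36)):
        fit = FluxCorrelation.from_dataframe(
            table, pooling=pooling, analytes=("malonyl_acp",)
        ).fit()
        assert fit["malonyl_acp"].n == expected_n


def test_flux_series_centred(synthetic_dataset):
    table, _ = synthetic_dataset
    flux = pl_flux_series(table)
    assert flux.values.mean() == pytest.approx(0.0, abs=1e-12)
    assert len(flux.values) == 12
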