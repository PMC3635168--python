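"""Hg-length regression, inverse prediction and threshold-grid rendering."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hgfish import (
    FishRecord,
    ScreeningConfig,
    Species,
    fit_length_regression,
    invert_to_threshold,
    threshold_table,
)
from hgfish.core import NotSignificantError, SingularDesignError
from hgfish.datasets import (
    SPECIES_LENGTH_RANGES,
    load_nc_regressions,
    published_fits,
    recomputed_threshold_grid,
)
from hgfish.hglength import LengthHgFit, LengthHgModel


def _records(lengths, hg, lake="L", species="largemouth_bass"):
    return [FishRecord(lake, species, L, hg_ww=h) for L, h in zip(lengths, hg)]


def _fit(a, b, species=Species.LARGEMOUTH_BASS, p=0.001, rng=(140.0, 560.0)):
    return LengthHgFit(lake_id="L", species=species, intercept_a=a, slope_b=b,
                       intercept_se=0.1, slope_se=1e-4, r2=0.8, p_value=p,
                       n=15, length_range=rng)


def test_exact_line_recovered():
    L = np.array([100.0, 200, 300, 400, 500])
    hg = 10 ** (-1.0 + 0.002 * L)
    fit = fit_length_regression(_records(L, hg))
    assert fit.intercept_a == pytest.approx(-1.0, abs=1e-12)
    assert fit.slope_b == pytest.approx(0.002, abs=1e-15)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.length_range == (100.0, 500.0)


def test_six_point_fixture_matches_normal_equations():
    L = np.array([120.0, 180, 260, 340, 410, 520])
    y = np.array([-1.42, -1.10, -0.95, -0.60, -0.52, -0.18])
    fit = LengthHgModel(L, 10 ** y, "fx", "largemouth_bass").fit()
    b = np.cov(L, y, ddof=1)[0, 1] / np.var(L, ddof=1)
    a = y.mean() - b * L.mean()
    assert fit.slope_b == pytest.approx(b, rel=1e-12)
    assert fit.intercept_a == pytest.approx(a, rel=1e-12)
    # model F-test p equals the slope t-test p in simple regression
    n = len(L)
    resid = y - (a + b * L)
    se_b = math.sqrt((resid @ resid / (n - 2)) / ((L - L.mean()) @ (L - L.mean())))
    import scipy.stats
    p_t = 2 * scipy.stats.t.sf(abs(b / se_b), n - 2)
    assert fit.p_value == pytest.approx(p_t, rel=1e-9)


def test_identical_lengths_singular():
    with pytest.raises(SingularDesignError):
        fit_length_regression(_records([300, 300, 300], [0.2, 0.3, 0.25]))


def test_mixed_cells_rejected():
    recs = _records([100, 200, 300], [0.1, 0.2, 0.3]) + \
        _records([100, 200, 300], [0.1, 0.2, 0.3], lake="M")
    with pytest.raises(ValueError, match="multiple"):
        fit_length_regression(recs)


@pytest.mark.parametrize("a, b, conc, expected", [
    (-0.659, 0.00121, 0.3, 112.1),   # most contaminated lake, bass
    (-2.481, 0.00651, 0.3, 300.9),   # least contaminated lake, crappie
    (-1.0, 0.002, 0.1, 0.0),         # log10(0.1) = -1: intercept case
])
def test_inverse_prediction_examples(a, b, conc, expected):
    fit = _fit(a, b)
    est = invert_to_threshold(fit, conc)
    assert est.length_at_level == pytest.approx(expected, abs=2.0)


def test_non_significant_fit_refused_unless_forced():
    fit = _fit(-1.262, 0.000975, species=Species.BLUEGILL, p=0.20)
    with pytest.raises(NotSignificantError):
        invert_to_threshold(fit, 0.3)
    est = invert_to_threshold(fit, 0.3, force=True)
    assert est.length_at_level is not None


def test_non_positive_slope_not_reached():
    est = invert_to_threshold(_fit(-1.0, 0.0), 0.3, force=True)
    assert est.length_at_level is None and not est.reached
    assert est.render() == "n.r."
    est = invert_to_threshold(_fit(-1.0, -0.001), 0.3, force=True)
    assert est.length_at_level is None


def test_negative_prediction_truncated_to_zero():
    # line already above the level at length 0
    est = invert_to_threshold(_fit(0.5, 0.002), 1.0)
    assert est.length_at_level == 0.0
    assert est.truncated_at_zero
    assert est.extrapolated_beyond_data


@given(a=st.floats(-4, 1), b=st.floats(1e-4, 0.01), conc=st.floats(0.05, 2.0))
def test_round_trip_invariant(a, b, conc):
    """a + b * L* == log10(C) to 1e-9, regardless of flags."""
    fit = _fit(a, b)
    est = invert_to_threshold(fit, conc)
    if not est.truncated_at_zero:
        assert a + b * est.length_at_level == pytest.approx(math.log10(conc), abs=1e-9)


@given(a=st.floats(-4, -0.5), b=st.floats(1e-4, 0.01),
       c1=st.floats(0.05, 2.0), c2=st.floats(0.05, 2.0))
def test_thresholds_monotone_in_concentration(a, b, c1, c2):
    lo, hi = sorted([c1, c2])
    if lo == hi:
        return
    fit = _fit(a, b)
    e_lo = invert_to_threshold(fit, lo)
    e_hi = invert_to_threshold(fit, hi)
    if not (e_lo.truncated_at_zero or e_hi.truncated_at_zero):
        assert e_lo.length_at_level < e_hi.length_at_level


def test_usepa_nc_usfda_ordering(config):
    fit = _fit(-1.4, 0.0025)
    lengths = [invert_to_threshold(fit, c, config).length_at_level
               for c in (0.3, 0.4, 1.0)]
    assert lengths == sorted(lengths)


def test_cap_rendering_precedence(config):
    """An estimate both beyond the data and beyond the species cap renders
    as > cap (cap suppresses the extrapolation mark)."""
    fit = _fit(-1.389, 0.00211, species=Species.BLUEGILL, rng=(79.0, 239.0))
    est = invert_to_threshold(fit, 0.3, config)
    assert est.exceeds_max_species_size and est.extrapolated_beyond_data
    assert est.render() == ">300"


def test_extrapolation_star_rendering(config):
    fit = _fit(-1.687, 0.00424, species=Species.BLUEGILL, rng=(79.0, 239.0))
    est = invert_to_threshold(fit, 0.3, config)
    assert est.extrapolated_beyond_data and not est.exceeds_max_species_size
    assert est.render().endswith("*")
    assert est.length_at_level == pytest.approx(274.9, abs=2.0)


def test_threshold_table_shapes_and_dashes(config):
    fits = [
        _fit(-1.389, 0.00211, species=Species.BLUEGILL, rng=(79.0, 239.0)),
        _fit(-1.262, 0.000975, species=Species.BLUEGILL, p=0.20, rng=(79.0, 239.0)),
    ]
    table = threshold_table(fits, config)
    assert list(table.columns[-3:]) == ["USEPA", "NC", "USFDA"]
    sig = table.iloc[0]
    assert (sig[["USEPA", "NC", "USFDA"]] == ">300").all()
    nonsig = table.iloc[1]
    assert (nonsig[["USEPA", "NC", "USFDA"]] == "---").all()


def test_null_slope_usually_non_significant():
    """Flat Hg-length truth with sd 0.2 at n = 15 rarely reaches p < 0.05."""
    rng = np.random.default_rng(3)
    nonsig = 0
    reps = 200
    for _ in range(reps):
        L = rng.uniform(80, 240, 15)
        y = -1.0 + rng.normal(0, 0.2, 15)
        fit = LengthHgModel(L, 10 ** y, "sim", "bluegill").fit()
        nonsig += fit.p_value > 0.05
    assert nonsig / reps > 0.85


def test_published_grid_reproduces_printed_cells(config):
    """Re-derived grid matches every printed cell: numeric lengths within
    ±2 mm (coefficient rounding), > cap cells reproduced exactly, dashes
    for the non-significant rows."""
    grid = recomputed_threshold_grid(config)
    table = load_nc_regressions()
    for (_, printed), (_, redone) in zip(table.iterrows(), grid.iterrows()):
        for col, label in (("usepa", "USEPA"), ("nc", "NC"), ("usfda", "USFDA")):
            cell = printed[col]
            if cell == "---":
                assert redone[label] == "---"
            elif cell.startswith(">"):
                assert redone[label] == cell
            else:
                printed_mm = float(cell.rstrip(" *"))
                assert redone[f"{label}_mm"] == pytest.approx(printed_mm, abs=2.0), (
                    printed["lake_id"], printed["species"], label)


def test_plot_smoke(tmp_path):
    fit = fit_length_regression(_records([100, 200, 300, 400], [0.1, 0.2, 0.35, 0.8]))
    ax = fit.plot()
    assert ax.get_xlabel() == "total length (mm)"
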