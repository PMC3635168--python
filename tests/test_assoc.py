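"""Correlation machinery and group comparisons."""

import math

import numpy as np
import pytest

from hgfish import (
    FishRecord,
    LakeContext,
    SurveyDataset,
    bonferroni_alpha,
    correlation_table,
    one_way_anova,
    partial_correlation,
    pearson,
    sex_comparison,
)
from hgfish.core import DegenerateDataError


def test_pearson_perfect_line():
    x = np.arange(10.0)
    r, p, n = pearson(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert n == 10


def test_pearson_five_pair_fixture():
    x = np.array([1.0, 2, 4, 5, 8])
    y = np.array([2.0, 3, 3, 6, 9])
    r, p, n = pearson(x, y)
    # direct covariance / sigma-sigma computation
    r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert r == pytest.approx(r_hand, rel=1e-12)
    t = r_hand * math.sqrt((n - 2) / (1 - r_hand ** 2))
    import scipy.stats
    assert p == pytest.approx(2 * scipy.stats.t.sf(abs(t), n - 2), rel=1e-6)


def test_pearson_zero_variance_rejected():
    with pytest.raises(DegenerateDataError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pearson_drops_incomplete_pairs():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [1.1, 1.9, 3.0, np.nan, 5.2]
    r, p, n = pearson(x, y)
    assert n == 3


def test_pearson_null_rejection_rate():
    """Independent vectors: rejection at alpha = 0.05 stays near nominal."""
    rng = np.random.default_rng(5)
    reps, rej = 1000, 0
    for _ in range(reps):
        x, y = rng.normal(size=(2, 30))
        rej += pearson(x, y)[1] < 0.05
    assert 0.03 <= rej / reps <= 0.07


def test_partial_empty_controls_equals_pearson():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=(2, 40))
    assert partial_correlation(y, x, [])[:2] == pytest.approx(pearson(y, x)[:2])


def test_partial_collinear_control_rejected():
    rng = np.random.default_rng(3)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    with pytest.raises(DegenerateDataError):
        partial_correlation(y, x, [x])


def _partial_by_matrix_inverse(target, x, controls):
    """Independent oracle: partial correlation from the inverse of the
    full correlation matrix, r_ij.rest = -P_ij / sqrt(P_ii P_jj)."""
    M = np.column_stack([target, x, *controls])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -P[0, 1] / math.sqrt(P[0, 0] * P[1, 1])


def test_partial_matches_matrix_identity():
    rng = np.random.default_rng(8)
    for _ in range(25):
        z1, z2 = rng.normal(size=(2, 50))
        x = z1 + 0.5 * z2 + rng.normal(size=50)
        y = 0.7 * x + z1 - z2 + rng.normal(size=50)
        r, _, _ = partial_correlation(y, x, [z1, z2])
        assert r == pytest.approx(_partial_by_matrix_inverse(y, x, [z1, z2]), abs=1e-10)


def test_partial_matches_pingouin():
    """Cross-check against an established implementation."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(9)
    z = rng.normal(size=60)
    x = z + rng.normal(size=60)
    y = 0.5 * x - z + rng.normal(size=60)
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    expected = pingouin.partial_corr(df, x="x", y="y", covar="z")
    r, p, n = partial_correlation(y, x, [z])
    assert r == pytest.approx(float(expected["r"].iloc[0]), abs=1e-9)
    assert p == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-9)


@pytest.mark.parametrize("alpha, m, expected", [
    (0.05, 6, 0.05 / 6),
    (0.05, 1, 0.05),
    (0.05, 3, 0.05 / 3),
])
def test_bonferroni(alpha, m, expected):
    got = bonferroni_alpha(alpha, m)
    assert got == pytest.approx(expected, rel=1e-12)


def test_bonferroni_six_comparisons_prints_as_008():
    assert round(bonferroni_alpha(0.05, 6), 3) == 0.008


def test_anova_no_between_variance_gives_zero_f():
    res = one_way_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 20)
    b = rng.normal(0.5, 1, 25)
    res = one_way_anova({"a": a, "b": b})
    import scipy.stats
    t, p_t = scipy.stats.ttest_ind(a, b, equal_var=True)
    assert res.statistic == pytest.approx(t ** 2, rel=1e-9)
    assert res.p_value == pytest.approx(p_t, rel=1e-9)


def test_anova_three_group_fixture_matches_sums_of_squares():
    groups = {"a": np.array([1.0, 2, 3]), "b": np.array([2.0, 4, 4]),
              "c": np.array([5.0, 6, 8])}
    res = one_way_anova(groups)
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    f_hand = (ss_between / 2) / (ss_within / (len(allv) - 3))
    assert res.statistic == pytest.approx(f_hand, rel=1e-12)


def _sexed_records(hg_f, hg_m, lake="L", species="largemouth_bass"):
    recs = [FishRecord(lake, species, 300, hg_ww=h, sex="female") for h in hg_f]
    recs += [FishRecord(lake, species, 300, hg_ww=h, sex="male") for h in hg_m]
    return recs


def test_sex_comparison_identical_groups():
    res = sex_comparison(_sexed_records([0.2, 0.3, 0.4], [0.2, 0.3, 0.4]))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_sex_comparison_requires_both_sexes():
    with pytest.raises(ValueError):
        sex_comparison(_sexed_records([0.2, 0.3], []))


def test_sex_comparison_type_i_and_power():
    rng = np.random.default_rng(6)
    reps = 400
    null_rej = shift_rej = 0
    for _ in range(reps):
        f = 10 ** rng.normal(-0.8, 0.3, 50)
        m = 10 ** rng.normal(-0.8, 0.3, 50)
        null_rej += sex_comparison(_sexed_records(f, m)).p_value < 0.05
        m_shift = 10 ** rng.normal(-0.5, 0.3, 50)  # one sd apart on log scale
        shift_rej += sex_comparison(_sexed_records(f, m_shift)).p_value < 0.05
    assert 0.02 <= null_rej / reps <= 0.08
    assert shift_rej / reps >= 0.90


def _cohort_dataset(effect="age", n=200, seed=0):
    """One lake x species cell where log10 Hg is driven by a single factor."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(1, 8, n)
    length = 60 * age + rng.normal(0, 40, n)  # length tracks age, noisily
    length = np.clip(length, 30, None)
    tp = 2.5 + 0.002 * length + rng.normal(0, 0.15, n)
    driver = {"age": 0.15 * age, "length": 0.004 * length}[effect]
    log_hg = -1.8 + driver + rng.normal(0, 0.08, n)
    baseline = 6.0
    recs = [FishRecord("L", "bluegill", L, hg_ww=10 ** h, age=a,
                       d15n=baseline + 3.4 * (t - 2))
            for L, h, a, t in zip(length, log_hg, age, tp)]
    return SurveyDataset(records=recs, lakes={"L": LakeContext("L", baseline)})


def test_correlation_table_recovers_age_driven_pattern():
    """Hg driven by age alone: pairwise r with length is large (length
    tracks age) but the partial r with length collapses."""
    table = correlation_table(_cohort_dataset("age", seed=1))
    by_factor = table.set_index("factor")
    assert by_factor.loc["total_length", "r_pairwise"] > 0.5
    assert abs(by_factor.loc["total_length", "r_partial"]) < 0.25
    assert by_factor.loc["age", "r_partial"] > 0.5
    assert by_factor.loc["age", "partial_significant"]


def test_correlation_table_recovers_direct_length_effect():
    """Hg driven directly by length: the partial r with length survives
    controlling age and trophic position."""
    table = correlation_table(_cohort_dataset("length", seed=2))
    by_factor = table.set_index("factor")
    assert by_factor.loc["total_length", "r_partial"] > 0.5
    assert by_factor.loc["total_length", "partial_significant"]


def test_correlation_table_r_and_p_ranges(study):
    table = correlation_table(study)
    assert len(table) > 0
    assert table["r_pairwise"].between(-1, 1).all()
    assert table["r_partial"].between(-1, 1).all()
    assert table["p_pairwise"].between(0, 1).all()
    assert table["p_partial"].between(0, 1).all()
    assert np.allclose(table["adjusted_alpha"], 0.05 / 6)
    # every cell contributes all three factor rows
    assert len(table) == 16 * 3


def test_correlation_table_omits_degenerate_cells():
    """A constant factor within a cell drops that row, not the whole table."""
    rng = np.random.default_rng(12)
    recs = [FishRecord("L", "bluegill", 100 + 10 * i + rng.uniform(0, 5),
                       hg_ww=0.1 + 0.01 * i + rng.uniform(0, 0.02),
                       age=3.0, d15n=8.0 + 0.1 * i + rng.normal(0, 0.3))
            for i in range(10)]
    ds = SurveyDataset(records=recs, lakes={"L": LakeContext("L", 6.0)})
    table = correlation_table(ds)
    factors = set(table["factor"])
    assert "age" not in factors  # constant age row omitted
    assert "total_length" in factors  # remaining factors survive
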