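"""Group comparisons and the pairwise/partial correlation analysis.

The question the correlation analysis answers: does tissue Hg track fish
length *per se*, or only through the covariates that grow with length —
age (slow Hg elimination means older fish have accumulated longer) and
trophic position (larger fish eat higher-trophic, more contaminated prey)?
For each lake × species cell, log10 Hg is correlated with total length,
age and trophic position pairwise, and partially (each factor with the
other two held constant via the residual method).  Significance within a
cell is Bonferroni-adjusted over the six correlations (family α 0.05 →
per-test 0.05/6 ≈ 0.008).

Hg is log10-transformed before every correlation and comparison to meet
normality/equal-variance assumptions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .core import DegenerateDataError, ScreeningConfig, Sex, Species, SurveyDataset
from .trophic import trophic_positions

logger = logging.getLogger(__name__)

__all__ = [
    "pearson",
    "partial_correlation",
    "bonferroni_alpha",
    "one_way_anova",
    "sex_comparison",
    "CorrelationRow",
    "ComparisonResult",
    "correlation_table",
]

FACTORS = ("total_length", "age", "trophic_position")


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # one_way_anova | two_sample_t | ancova
    statistic: float
    p_value: float
    group_labels: tuple
    adjusted_alpha: Optional[float] = None


@dataclass(frozen=True)
class CorrelationRow:
    lake_id: str
    species: Species
    factor: str
    r_pairwise: float
    p_pairwise: float
    r_partial: float
    p_partial: float
    n: int
    adjusted_alpha: float

    @property
    def pairwise_significant(self) -> bool:
        return self.p_pairwise < self.adjusted_alpha

    @property
    def partial_significant(self) -> bool:
        return self.p_partial < self.adjusted_alpha


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson(x, y) -> tuple:
    """Product-moment correlation over complete pairs.

    Returns ``(r, p, n)`` with a two-sided t-based p on n − 2 df.
    """
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined: a vector has zero variance")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p), n


def _residuals(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, controls]."""
    X = np.column_stack([np.ones(len(y)), controls])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(target, x, controls: Sequence) -> tuple:
    """Correlation of target and x with the controls' linear effects removed.

    Residual method: regress both ``target`` and ``x`` on the controls
    (with intercept) and correlate the residuals.  Returns ``(r, p, n)``
    with a two-sided t-based p on n − k − 2 df for k controls.  An empty
    control set reduces exactly to :func:`pearson`.
    """
    target = np.asarray(target, dtype=float)
    x = np.asarray(x, dtype=float)
    controls = [np.asarray(c, dtype=float) for c in controls]
    k = len(controls)
    if any(c.shape != target.shape for c in [x, *controls]):
        raise ValueError("all vectors must have equal length")
    ok = np.isfinite(target) & np.isfinite(x)
    for c in controls:
        ok &= np.isfinite(c)
    target, x = target[ok], x[ok]
    controls = [c[ok] for c in controls]
    n = len(target)
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 complete cases (k={k}), got {n}")
    if k == 0:
        return pearson(target, x)
    C = np.column_stack(controls)
    res_t = _residuals(target, C)
    res_x = _residuals(x, C)
    if np.allclose(res_x, 0, atol=1e-12 * max(1.0, float(np.abs(x).max()))):
        raise DegenerateDataError("x is collinear with the controls; residuals vanish")
    if np.allclose(res_t, 0, atol=1e-12 * max(1.0, float(np.abs(target).max()))):
        raise DegenerateDataError("target is collinear with the controls; residuals vanish")
    r = float(np.corrcoef(res_t, res_x)[0, 1])
    df = n - k - 2
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        p = 0.0
    else:
        t = r_clip * math.sqrt(df / (1.0 - r_clip ** 2))
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return r, p, n


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison significance threshold for a family of m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    return family_alpha / m


def one_way_anova(groups: dict) -> ComparisonResult:
    """One-way ANOVA over labelled numeric vectors (as supplied; transform first)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"group {label!r} needs >= 2 observations")
        arrays.append(v)
    f, p = scipy.stats.f_oneway(*arrays)
    return ComparisonResult(test="one_way_anova", statistic=float(f),
                            p_value=float(p), group_labels=tuple(groups))


def sex_comparison(records: Sequence) -> ComparisonResult:
    """Two-sided equal-variance t-test of log10 Hg, female vs male.

    Unknown-sex fish are excluded; both sexes need >= 2 fish with Hg.
    """
    by_sex = {Sex.FEMALE: [], Sex.MALE: []}
    for r in records:
        if r.sex in by_sex and r.hg_ww is not None:
            by_sex[r.sex].append(math.log10(r.hg_ww))
    for sex, vals in by_sex.items():
        if len(vals) < 2:
            raise ValueError(f"need >= 2 {sex.value} fish with Hg, got {len(vals)}")
    t, p = scipy.stats.ttest_ind(by_sex[Sex.FEMALE], by_sex[Sex.MALE], equal_var=True)
    return ComparisonResult(test="two_sample_t", statistic=float(t),
                            p_value=float(p), group_labels=("female", "male"))


def correlation_table(dataset: SurveyDataset, family_alpha: float = 0.05,
                      min_n: int = 5) -> pd.DataFrame:
    """Pairwise and partial correlations of log10 Hg with TL, age and TP.

    One row per lake × species × factor over complete cases (Hg, TL, age,
    δ15N all present).  The partial correlation for each factor controls
    the other two.  Cells with fewer than ``min_n`` complete cases, or a
    constant factor, are omitted with a log notice.
    """
    alpha_adj = bonferroni_alpha(family_alpha, 2 * len(FACTORS))
    rows = []
    groups = {}
    for r in dataset.records:
        groups.setdefault((r.lake_id, r.species), []).append(r)
    for (lake_id, species), recs in sorted(groups.items(),
                                           key=lambda kv: (kv[0][0], kv[0][1].value)):
        sel = [r for r in recs if r.hg_ww is not None and r.d15n is not None
               and r.age is not None]
        if len(sel) < min_n:
            logger.info("correlation_table: %s/%s omitted (%d complete cases < %d)",
                        lake_id, species.value, len(sel), min_n)
            continue
        log_hg = np.log10([r.hg_ww for r in sel])
        baseline = dataset.baseline_for(lake_id)
        vectors = {
            "total_length": np.array([r.total_length for r in sel]),
            "age": np.array([r.age for r in sel]),
            "trophic_position": trophic_positions([r.d15n for r in sel], baseline),
        }
        for factor in FACTORS:
            others = [vectors[f] for f in FACTORS if f != factor]
            try:
                r_pw, p_pw, n = pearson(log_hg, vectors[factor])
                r_pt, p_pt, _ = partial_correlation(log_hg, vectors[factor], others)
            except DegenerateDataError as exc:
                logger.info("correlation_table: %s/%s factor %s omitted (%s)",
                            lake_id, species.value, factor, exc)
                continue
            rows.append(CorrelationRow(
                lake_id=lake_id, species=species, factor=factor,
                r_pairwise=r_pw, p_pairwise=p_pw,
                r_partial=r_pt, p_partial=p_pt,
                n=n, adjusted_alpha=alpha_adj))
    columns = ["lake_id", "species", "factor", "n", "r_pairwise", "p_pairwise",
               "pairwise_significant", "r_partial", "p_partial",
               "partial_significant", "adjusted_alpha"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([{
        "lake_id": row.lake_id,
        "species": row.species.value,
        "factor": row.factor,
        "n": row.n,
        "r_pairwise": row.r_pairwise,
        "p_pairwise": row.p_pairwise,
        "pairwise_significant": row.pairwise_significant,
        "r_partial": row.r_partial,
        "p_partial": row.p_partial,
        "partial_significant": row.partial_significant,
        "adjusted_alpha": row.adjusted_alpha,
    } for row in rows])
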