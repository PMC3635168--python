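"""Trophic positioning from nitrogen isotopes and within-lake
biomagnification.

Trophic position of a fish is estimated from its δ15N relative to a
primary-consumer (benthic invertebrate composite) baseline::

    TP = (fish δ15N − baseline δ15N) / 3.4 + 2

where 3.4‰ is the per-trophic-transfer nitrogen fractionation and the +2
places the invertebrate baseline at trophic level two.

Within a lake, the regression of log10 tissue Hg on trophic position
summarises the food web: the slope measures biomagnification (10^slope is
the concentration multiplier per trophic level) and the back-transformed
intercept is a relative index of mercury at the base of the food web.  The
regression combines largemouth bass and bluegill, the two species present
in every lake; black crappie (partial collections) are excluded.  Slope
homogeneity across lakes is tested by ANCOVA (nested-model F test of the
lake × TP interaction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .core import (
    DegenerateDataError,
    LakeContext,
    SingularDesignError,
    Species,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FRACTIONATION_PERMIL",
    "BASELINE_TROPHIC_LEVEL",
    "TrophicPosition",
    "trophic_position",
    "trophic_positions",
    "BiomagnificationModel",
    "BiomagFit",
    "fit_biomagnification",
    "factor_per_trophic_level",
    "SlopeHomogeneityResult",
    "test_slope_homogeneity",
]

FRACTIONATION_PERMIL = 3.4
BASELINE_TROPHIC_LEVEL = 2.0

_BIOMAG_SPECIES = {Species.LARGEMOUTH_BASS, Species.BLUEGILL}


@dataclass(frozen=True)
class TrophicPosition:
    value: float
    fish_d15n: float
    baseline_d15n: float


def trophic_position(fish_d15n: float, baseline_d15n: float) -> TrophicPosition:
    """Trophic position of one fish from its δ15N and the lake baseline.

    Negative values are permitted (they indicate a baseline mismatch) but
    are logged.
    """
    if not (np.isfinite(fish_d15n) and np.isfinite(baseline_d15n)):
        raise ValueError("d15n values must be finite")
    value = (fish_d15n - baseline_d15n) / FRACTIONATION_PERMIL + BASELINE_TROPHIC_LEVEL
    if value < 0:
        logger.warning("negative trophic position %.3f (fish %.2f, baseline %.2f)",
                       value, fish_d15n, baseline_d15n)
    return TrophicPosition(value=value, fish_d15n=float(fish_d15n),
                           baseline_d15n=float(baseline_d15n))


def trophic_positions(fish_d15n, baseline_d15n) -> np.ndarray:
    """Vectorised trophic positions."""
    fish_d15n = np.asarray(fish_d15n, dtype=float)
    return (fish_d15n - baseline_d15n) / FRACTIONATION_PERMIL + BASELINE_TROPHIC_LEVEL


def factor_per_trophic_level(slope: float) -> float:
    """Concentration multiplier per trophic level implied by a log10 slope."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return float(10.0 ** slope)


@dataclass(frozen=True)
class BiomagFit:
    """Fitted within-lake Hg–trophic-position regression."""

    lake_id: str
    slope: float  # log10 ppm per trophic level
    intercept: float  # log10 ppm at TP 0
    slope_se: float
    intercept_se: float
    r2: float
    p_value: float  # model F-test (== slope t-test here)
    n: int

    @property
    def baseline_hg(self) -> float:
        """Relative food-web baseline Hg, ppm."""
        return 10.0 ** self.intercept

    @property
    def factor(self) -> float:
        """Per-trophic-level concentration multiplier, 10^slope."""
        return factor_per_trophic_level(self.slope)

    def slope_conf_int(self, alpha: float = 0.05) -> tuple:
        t = scipy.stats.t.ppf(1 - alpha / 2, self.n - 2)
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)

    def summary(self) -> str:
        lo, hi = self.slope_conf_int()
        return (f"Biomagnification fit: lake={self.lake_id} n={self.n}\n"
                f"  slope  = {self.slope:.3f} (SE {self.slope_se:.3f}, "
                f"95% CI {lo:.3f}..{hi:.3f}) -> x{self.factor:.1f} per trophic level\n"
                f"  intercept = {self.intercept:.3f} -> baseline Hg "
                f"{self.baseline_hg:.2e} ppm\n"
                f"  R^2 = {self.r2:.3f}, p = {self.p_value:.3g}")


def _ols_1d(x: np.ndarray, y: np.ndarray):
    if np.ptp(x) == 0:
        raise SingularDesignError("predictor has no variation")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return res


class BiomagnificationModel:
    """Model of log10 tissue Hg versus trophic position within one lake.

    Built from arrays or from fish records; ``fit()`` returns a
    :class:`BiomagFit` results object.
    """

    def __init__(self, trophic_position, log10_hg, lake_id: str = ""):
        tp = np.asarray(trophic_position, dtype=float)
        y = np.asarray(log10_hg, dtype=float)
        if tp.shape != y.shape:
            raise ValueError("trophic_position and log10_hg must match in length")
        ok = np.isfinite(tp) & np.isfinite(y)
        self.tp = tp[ok]
        self.log10_hg = y[ok]
        self.lake_id = lake_id
        if len(self.tp) < 3:
            raise ValueError(
                f"need >= 3 complete (Hg, d15n) records, got {len(self.tp)}")

    @classmethod
    def from_records(cls, records: Sequence, lake: LakeContext) -> "BiomagnificationModel":
        """Build from one lake's fish, restricted to bass and bluegill.

        Black crappie are excluded (partial collections preclude
        among-lake comparison); records missing Hg or δ15N are dropped.
        """
        sel = [r for r in records
               if r.species in _BIOMAG_SPECIES and r.lake_id == lake.lake_id
               and r.hg_ww is not None and r.d15n is not None]
        tp = trophic_positions([r.d15n for r in sel], lake.baseline_d15n)
        y = np.log10([r.hg_ww for r in sel]) if sel else np.array([])
        return cls(tp, y, lake_id=lake.lake_id)

    def fit(self) -> BiomagFit:
        res = _ols_1d(self.tp, self.log10_hg)
        return BiomagFit(
            lake_id=self.lake_id,
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            r2=float(res.rsquared),
            p_value=float(res.f_pvalue),
            n=int(res.nobs),
        )


def fit_biomagnification(records: Sequence, lake: LakeContext) -> BiomagFit:
    """OLS of log10(Hg) on trophic position for one lake (bass + bluegill)."""
    return BiomagnificationModel.from_records(records, lake).fit()


@dataclass(frozen=True)
class SlopeHomogeneityResult:
    """ANCOVA test of equal biomagnification slopes across lakes."""

    f_stat: float
    p_value: float
    df_num: float
    df_den: float
    n_lakes: int

    def summary(self) -> str:
        return (f"ANCOVA slope homogeneity over {self.n_lakes} lakes: "
                f"F({self.df_num:.0f}, {self.df_den:.0f}) = {self.f_stat:.3f}, "
                f"p = {self.p_value:.3g}")


def test_slope_homogeneity(groups: Mapping[str, tuple]) -> SlopeHomogeneityResult:
    """ANCOVA F-test of the lake × TP interaction.

    ``groups`` maps lake id to a ``(trophic_position, log10_hg)`` array
    pair.  The full model ``log10 Hg ~ TP + lake + TP:lake`` is compared
    with the no-interaction model by a nested F test; a small p indicates
    slopes differ among lakes.
    """
    if len(groups) < 2:
        raise ValueError("slope homogeneity test needs >= 2 lakes")
    tp_all, y_all, labels = [], [], []
    for lake_id, (tp, y) in groups.items():
        tp = np.asarray(tp, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(tp) < 3 or np.ptp(tp) == 0:
            raise SingularDesignError(f"lake {lake_id!r}: insufficient TP variation")
        tp_all.append(tp)
        y_all.append(y)
        labels.extend([lake_id] * len(tp))
    tp = np.concatenate(tp_all)
    y = np.concatenate(y_all)
    lake_ids = sorted(groups)
    # treatment-coded design: intercept, TP, lake dummies, TP x lake dummies
    n = len(y)
    dummies = np.column_stack([(np.array(labels) == lid).astype(float)
                               for lid in lake_ids[1:]])
    X_red = np.column_stack([np.ones(n), tp, dummies])
    X_full = np.column_stack([X_red, dummies * tp[:, None]])
    res_red = sm.OLS(y, X_red).fit()
    res_full = sm.OLS(y, X_full).fit()
    df_num = res_red.df_resid - res_full.df_resid
    df_den = res_full.df_resid
    ssr_red = res_red.ssr
    ssr_full = res_full.ssr
    f = ((ssr_red - ssr_full) / df_num) / (ssr_full / df_den)
    p = float(scipy.stats.f.sf(f, df_num, df_den))
    return SlopeHomogeneityResult(f_stat=float(f), p_value=p,
                                  df_num=float(df_num), df_den=float(df_den),
                                  n_lakes=len(groups))


def slope_homogeneity_from_dataset(dataset) -> SlopeHomogeneityResult:
    """ANCOVA over all lakes of a survey with enough bass + bluegill data."""
    groups = {}
    for lake_id, lake in dataset.lakes.items():
        sel = [r for r in dataset.records
               if r.lake_id == lake_id and r.species in _BIOMAG_SPECIES
               and r.hg_ww is not None and r.d15n is not None]
        if len(sel) < 3:
            continue
        tp = trophic_positions([r.d15n for r in sel], lake.baseline_d15n)
        if np.ptp(tp) == 0:
            continue
        groups[lake_id] = (tp, np.log10([r.hg_ww for r in sel]))
    return test_slope_homogeneity(groups)
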