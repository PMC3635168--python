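"""Harvest-regulation overlap statistics and the routine-monitoring
threshold predictor.

Two complementary risk views per lake × species:

* the fraction of *legally harvestable* fish (total length at or above the
  fishery length limit) whose tissue Hg exceeds a screening level — the
  probability that a single harvested meal is higher risk; and
* whether the inverse-predicted screening-level length falls below the
  length limit, in which case regulation restricts anglers to fish that
  have already crossed the screening level.

The monitoring predictor addresses a practical constraint: agencies
routinely analyse Hg only in a narrow length window of largemouth bass.
The mean tissue Hg inside that window, per lake, is regressed against the
lake's inverse-predicted screening-level length; more contaminated lakes
reach the level at smaller sizes, so the fitted slope is negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .core import ScreeningConfig, Species, SurveyDataset
from .hglength import (
    LengthHgFit,
    ThresholdEstimate,
    fit_length_regression,
    invert_to_threshold,
    threshold_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HarvestRiskSummary",
    "percent_harvestable_exceeding",
    "monitoring_window_mean",
    "MonitoringPredictor",
    "fit_threshold_predictor",
    "evaluate_predictor",
    "AdvisoryReport",
    "advisory_report",
]


@dataclass(frozen=True)
class HarvestRiskSummary:
    """Exceedance statistics among legally harvestable fish of one cell."""

    lake_id: str
    species: Species
    level_label: str
    level: float  # ppm
    length_limit: Optional[float]  # mm; None = no limit, all fish harvestable
    n_harvestable: int
    n_exceeding: int
    pct_exceeding: Optional[float]  # % of harvestable fish above the level
    threshold_vs_limit: Optional[str]  # threshold_below_limit | threshold_above_limit | not_reached


def _compare_threshold_to_limit(threshold: Optional[ThresholdEstimate],
                                limit: Optional[float]) -> Optional[str]:
    if threshold is None or limit is None:
        return None
    if threshold.length_at_level is None:
        return "not_reached"
    return ("threshold_below_limit" if threshold.length_at_level < limit
            else "threshold_above_limit")


def percent_harvestable_exceeding(records: Sequence, limit: Optional[float],
                                  level: float, level_label: str = "",
                                  threshold: Optional[ThresholdEstimate] = None,
                                  ) -> HarvestRiskSummary:
    """Percent of harvestable fish (TL >= limit) with Hg strictly above a level.

    Species without a length limit (``limit=None``) treat every fish as
    harvestable.  With no harvestable fish the percentage is undefined and
    reported as None with count 0.  Boundary fish at exactly the screening
    level are not counted as exceeding.
    """
    cells = {(r.lake_id, r.species) for r in records}
    if len(cells) > 1:
        raise ValueError("records span multiple lake/species cells")
    lake_id, species = next(iter(cells)) if cells else ("", None)
    sel = [r for r in records if r.hg_ww is not None]
    harvestable = [r for r in sel if limit is None or r.total_length >= limit]
    n_h = len(harvestable)
    n_x = sum(1 for r in harvestable if r.hg_ww > level)
    pct = 100.0 * n_x / n_h if n_h else None
    if n_h == 0:
        logger.info("no harvestable fish in %s/%s; exceedance undefined",
                    lake_id, species.value if species else "?")
    return HarvestRiskSummary(
        lake_id=lake_id, species=species, level_label=level_label, level=level,
        length_limit=limit, n_harvestable=n_h, n_exceeding=n_x,
        pct_exceeding=pct,
        threshold_vs_limit=_compare_threshold_to_limit(threshold, limit))


def monitoring_window_mean(records: Sequence, window: tuple) -> Optional[float]:
    """Arithmetic mean tissue Hg (ppm ww) over fish inside a closed length window."""
    lo, hi = window
    vals = [r.hg_ww for r in records
            if r.hg_ww is not None and lo <= r.total_length <= hi]
    if not vals:
        logger.info("no fish inside monitoring window [%g, %g] mm", lo, hi)
        return None
    return float(np.mean(vals))


@dataclass(frozen=True)
class MonitoringPredictor:
    """Fitted line predicting a screening-level length from window-mean Hg."""

    level_label: str
    intercept: float  # mm
    slope: float  # mm per ppm
    r: float  # signed correlation
    r2: float
    p_value: float
    n: int
    window: tuple = (320.0, 385.0)

    def summary(self) -> str:
        return (f"length at {self.level_label} level = {self.intercept:.2f} "
                f"{self.slope:+.2f} * (mean Hg in {self.window[0]:.0f}-"
                f"{self.window[1]:.0f} mm window)  "
                f"[r = {self.r:.2f}, p = {self.p_value:.3g}, n = {self.n}]")


def fit_threshold_predictor(means: Sequence[float], thresholds: Sequence[float],
                            level_label: str = "",
                            window: tuple = (320.0, 385.0)) -> MonitoringPredictor:
    """OLS of per-lake screening-level length (mm) on window-mean Hg (ppm)."""
    x = np.asarray(means, dtype=float)
    y = np.asarray(thresholds, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 lakes with both values, got {len(x)}")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r = float(np.corrcoef(x, y)[0, 1])
    return MonitoringPredictor(
        level_label=level_label,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r=r, r2=float(res.rsquared),
        p_value=float(res.f_pvalue),
        n=int(res.nobs),
        window=tuple(window))


def evaluate_predictor(predictor: MonitoringPredictor, mean_hg: float) -> float:
    """Predicted screening-level length (mm) at a window-mean Hg; floored at 0."""
    if mean_hg < 0:
        raise ValueError("mean_hg must be >= 0")
    return max(0.0, predictor.intercept + predictor.slope * mean_hg)


@dataclass
class AdvisoryReport:
    """Assembled analysis of one survey: fits, thresholds, food-web
    biomagnification, correlations, harvest risk and monitoring predictors."""

    fits: list
    thresholds: pd.DataFrame
    biomag: pd.DataFrame
    ancova: Optional[object]
    correlations: pd.DataFrame
    harvest_risk: pd.DataFrame
    predictors: list

    def render_text(self) -> str:
        lines = ["=== Hg-length regressions and screening-level lengths ===",
                 self.thresholds.to_string(index=False), ""]
        lines += ["=== Food-web biomagnification (bass + bluegill) ==="]
        if len(self.biomag):
            lines.append(self.biomag.to_string(index=False))
        if self.ancova is not None:
            lines.append(self.ancova.summary())
        lines += ["", "=== Harvest-regulation risk overlap ===",
                  self.harvest_risk.to_string(index=False), ""]
        if self.predictors:
            lines.append("=== Routine-monitoring predictors ===")
            lines += [p.summary() for p in self.predictors]
        return "\n".join(lines)


def advisory_report(dataset: SurveyDataset,
                    config: Optional[ScreeningConfig] = None,
                    level_label: str = "USEPA") -> AdvisoryReport:
    """Run the full pipeline on a survey and assemble the report.

    ``level_label`` selects which screening level drives the harvest-risk
    rows (the most conservative one by default).
    """
    from .assoc import correlation_table
    from .trophic import fit_biomagnification, slope_homogeneity_from_dataset

    config = config or ScreeningConfig()
    level = config.levels[level_label]

    groups = {}
    for r in dataset.records:
        groups.setdefault((r.lake_id, r.species), []).append(r)

    fits = []
    for (lake_id, species), recs in sorted(groups.items(),
                                           key=lambda kv: (kv[0][1].value, kv[0][0])):
        with_hg = [r for r in recs if r.hg_ww is not None]
        if len(with_hg) < 3:
            logger.info("skipping Hg-length fit for %s/%s (n=%d)",
                        lake_id, species.value, len(with_hg))
            continue
        fits.append(fit_length_regression(with_hg))
    thresholds = threshold_table(fits, config)

    biomag_rows = []
    for lake_id, lake in sorted(dataset.lakes.items()):
        try:
            bm = fit_biomagnification(dataset.records, lake)
        except ValueError as exc:
            logger.info("no biomagnification fit for %s (%s)", lake_id, exc)
            continue
        biomag_rows.append({
            "lake_id": bm.lake_id, "n": bm.n, "slope": bm.slope,
            "slope_se": bm.slope_se, "factor_per_level": bm.factor,
            "intercept": bm.intercept, "baseline_hg_ppm": bm.baseline_hg,
            "r2": bm.r2, "p_value": bm.p_value})
    biomag = pd.DataFrame(biomag_rows)
    try:
        ancova = slope_homogeneity_from_dataset(dataset)
    except ValueError:
        ancova = None

    correlations = correlation_table(dataset)

    fit_by_cell = {(f.lake_id, f.species): f for f in fits}
    risk_rows = []
    for (lake_id, species), recs in sorted(groups.items(),
                                           key=lambda kv: (kv[0][1].value, kv[0][0])):
        limit = config.length_limits.get(species)
        fit = fit_by_cell.get((lake_id, species))
        threshold = None
        if fit is not None and fit.p_value < config.significance_gate:
            threshold = invert_to_threshold(fit, level, config, label=level_label)
        summary = percent_harvestable_exceeding(
            recs, limit, level, level_label=level_label, threshold=threshold)
        risk_rows.append({
            "lake_id": lake_id, "species": species.value,
            "length_limit_mm": limit, "n_harvestable": summary.n_harvestable,
            "n_exceeding": summary.n_exceeding,
            "pct_exceeding": summary.pct_exceeding,
            "threshold_vs_limit": summary.threshold_vs_limit})
    harvest_risk = pd.DataFrame(risk_rows)

    # routine-monitoring predictors: bass window means vs threshold lengths
    predictors = []
    bass_means, bass_thresholds = {}, {}
    for lake_id in dataset.lakes:
        recs = dataset.subset(lake_id=lake_id, species=Species.LARGEMOUTH_BASS)
        mean_hg = monitoring_window_mean(recs, config.monitoring_window)
        if mean_hg is not None:
            bass_means[lake_id] = mean_hg
    for label, conc in config.levels.items():
        pairs = []
        for lake_id, mean_hg in bass_means.items():
            fit = fit_by_cell.get((lake_id, Species.LARGEMOUTH_BASS))
            if fit is None or not fit.p_value < config.significance_gate:
                continue
            est = invert_to_threshold(fit, conc, config, label=label)
            if est.length_at_level is not None:
                pairs.append((mean_hg, est.length_at_level))
        if len(pairs) >= 3:
            means, lengths = zip(*pairs)
            predictors.append(fit_threshold_predictor(
                means, lengths, level_label=label,
                window=config.monitoring_window))
        else:
            logger.info("monitoring predictor for %s skipped (%d lakes < 3)",
                        label, len(pairs))
    return AdvisoryReport(fits=fits, thresholds=thresholds, biomag=biomag,
                          ancova=ancova, correlations=correlations,
                          harvest_risk=harvest_risk, predictors=predictors)
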