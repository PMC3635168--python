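"""Per-lake, per-species log-linear Hg–length regression and inverse
prediction of screening-level lengths.

Within each lake × species cell, log10 tissue Hg is regressed on total
length (mm TL)::

    log10(Hg) = a + b * TL

Significant fits (model F-test p below the configured gate, default 0.05)
are inverted to the length at which the fitted line reaches a screening
concentration C::

    L* = (log10(C) − a) / b

Each inverted length carries two flags: whether it lies beyond the observed
length range of the fit (an extrapolation), and whether it exceeds the
maximum achievable size of the species (rendered as "> cap" — fish of that
species never reach the screening level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .core import (
    NotSignificantError,
    ScreeningConfig,
    SingularDesignError,
    Species,
)

__all__ = [
    "LengthHgModel",
    "LengthHgFit",
    "ThresholdEstimate",
    "fit_length_regression",
    "invert_to_threshold",
    "threshold_estimates",
    "threshold_table",
]


@dataclass(frozen=True)
class LengthHgFit:
    """Fitted log10(Hg)–length regression for one lake × species cell."""

    lake_id: str
    species: Species
    intercept_a: float  # log10 ppm
    slope_b: float  # log10 ppm per mm
    intercept_se: float
    slope_se: float
    r2: float
    p_value: float  # model F-test
    n: int
    length_range: tuple  # (min mm, max mm) observed
    _lengths: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _log10_hg: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def predict_log10(self, length) -> np.ndarray:
        length = np.asarray(length, dtype=float)
        out = self.intercept_a + self.slope_b * length
        return float(out) if out.ndim == 0 else out

    def predict(self, length):
        """Predicted tissue Hg (ppm wet weight) at a length."""
        out = 10.0 ** np.asarray(self.predict_log10(length))
        return float(out) if out.ndim == 0 else out

    def threshold(self, concentration: float, config: Optional[ScreeningConfig] = None,
                  label: str = "", force: bool = False) -> "ThresholdEstimate":
        return invert_to_threshold(self, concentration, config or ScreeningConfig(),
                                   label=label, force=force)

    def equation(self) -> str:
        return (f"log10(Hg) = {self.intercept_a:.4g} + {self.slope_b:.4g} * TL")

    def summary(self) -> str:
        return (f"Hg-length fit: lake={self.lake_id} species={self.species.value} "
                f"n={self.n}\n  {self.equation()}\n"
                f"  R^2 = {self.r2:.3f}, p = {self.p_value:.3g}, observed TL "
                f"{self.length_range[0]:.0f}-{self.length_range[1]:.0f} mm")

    def plot(self, ax=None, levels: Optional[dict] = None):
        """Scatter of the data with the fitted line and screening levels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self._lengths is not None:
            ax.scatter(self._lengths, self._log10_hg, s=18, alpha=0.7)
        grid = np.linspace(*self.length_range, 50)
        ax.plot(grid, self.predict_log10(grid), color="k")
        for label, conc in (levels or {"USEPA": 0.3}).items():
            ax.axhline(math.log10(conc), ls="--", lw=0.8, color="grey")
            ax.annotate(label, (self.length_range[0], math.log10(conc)),
                        fontsize=8, va="bottom")
        ax.set_xlabel("total length (mm)")
        ax.set_ylabel("log10 tissue Hg (ppm ww)")
        ax.set_title(f"{self.lake_id} / {self.species.value}")
        return ax


class LengthHgModel:
    """OLS model of log10 tissue Hg on total length for one cell."""

    def __init__(self, total_length, hg_ww, lake_id: str = "", species=Species.LARGEMOUTH_BASS):
        length = np.asarray(total_length, dtype=float)
        hg = np.asarray(hg_ww, dtype=float)
        if length.shape != hg.shape:
            raise ValueError("total_length and hg_ww must match in length")
        ok = np.isfinite(length) & np.isfinite(hg) & (hg > 0)
        self.length = length[ok]
        self.log10_hg = np.log10(hg[ok])
        self.lake_id = lake_id
        self.species = Species(species)
        if len(self.length) < 3:
            raise ValueError(f"need >= 3 complete (TL, Hg) records, got {len(self.length)}")

    @classmethod
    def from_records(cls, records: Sequence) -> "LengthHgModel":
        """Build from fish records of a single lake × species cell."""
        cells = {(r.lake_id, r.species) for r in records}
        if len(cells) != 1:
            raise ValueError(f"records span multiple lake/species cells: {sorted(str(c) for c in cells)}")
        (lake_id, species), = cells
        sel = [r for r in records if r.hg_ww is not None]
        return cls([r.total_length for r in sel], [r.hg_ww for r in sel],
                   lake_id=lake_id, species=species)

    def fit(self) -> LengthHgFit:
        if np.ptp(self.length) == 0:
            raise SingularDesignError("all lengths identical; Hg-length fit undefined")
        res = sm.OLS(self.log10_hg, sm.add_constant(self.length)).fit()
        return LengthHgFit(
            lake_id=self.lake_id,
            species=self.species,
            intercept_a=float(res.params[0]),
            slope_b=float(res.params[1]),
            intercept_se=float(res.bse[0]),
            slope_se=float(res.bse[1]),
            r2=float(res.rsquared),
            p_value=float(res.f_pvalue),
            n=int(res.nobs),
            length_range=(float(self.length.min()), float(self.length.max())),
            _lengths=self.length,
            _log10_hg=self.log10_hg,
        )


def fit_length_regression(records: Sequence) -> LengthHgFit:
    """OLS of log10(Hg) on TL for one lake × species cell of records."""
    return LengthHgModel.from_records(records).fit()


@dataclass(frozen=True)
class ThresholdEstimate:
    """Inverse-predicted length at a screening concentration.

    ``length_at_level`` is None when the fitted line never reaches the
    level (non-positive slope).  ``render()`` reproduces the reporting
    conventions: "> cap" when the estimate exceeds the species maximum
    size (which takes precedence), a trailing "*" when it is an
    extrapolation beyond the observed length range.
    """

    level_label: str
    concentration: float  # ppm
    length_at_level: Optional[float]  # mm
    extrapolated_beyond_data: bool = False
    exceeds_max_species_size: bool = False
    truncated_at_zero: bool = False
    species: Optional[Species] = None
    species_cap: Optional[float] = None
    lake_id: str = ""

    @property
    def reached(self) -> bool:
        return self.length_at_level is not None

    def render(self) -> str:
        if self.length_at_level is None:
            return "n.r."
        if self.exceeds_max_species_size and self.species_cap is not None:
            return f">{self.species_cap:g}"
        if self.extrapolated_beyond_data:
            return f"{self.length_at_level:.1f} *"
        return f"{self.length_at_level:.1f}"


def invert_to_threshold(fit: LengthHgFit, concentration: float,
                        config: Optional[ScreeningConfig] = None,
                        label: str = "", force: bool = False) -> ThresholdEstimate:
    """Length at which the fitted line reaches a screening concentration.

    Refuses non-significant fits (p >= the configured gate) unless
    ``force=True``; a non-positive slope yields a not-reached estimate.
    Negative inverse predictions are truncated to 0 and flagged.
    """
    config = config or ScreeningConfig()
    if not concentration > 0:
        raise ValueError("concentration must be > 0")
    if not force and not (fit.p_value < config.significance_gate):
        raise NotSignificantError(
            f"fit {fit.lake_id}/{fit.species.value} has p = {fit.p_value:.3g} >= "
            f"{config.significance_gate}; pass force=True to invert anyway")
    cap = config.max_species_length.get(fit.species)
    if fit.slope_b <= 0:
        return ThresholdEstimate(
            level_label=label, concentration=concentration, length_at_level=None,
            species=fit.species, species_cap=cap, lake_id=fit.lake_id)
    length = (math.log10(concentration) - fit.intercept_a) / fit.slope_b
    truncated = length < 0
    if truncated:
        length = 0.0
    lo, hi = fit.length_range
    return ThresholdEstimate(
        level_label=label,
        concentration=concentration,
        length_at_level=float(length),
        extrapolated_beyond_data=not (lo <= length <= hi),
        exceeds_max_species_size=(cap is not None and length > cap),
        truncated_at_zero=truncated,
        species=fit.species,
        species_cap=cap,
        lake_id=fit.lake_id,
    )


def threshold_estimates(fits: Sequence[LengthHgFit],
                        config: Optional[ScreeningConfig] = None) -> list:
    """All (significant fit) × (screening level) threshold estimates."""
    config = config or ScreeningConfig()
    out = []
    for fit in fits:
        if not (fit.p_value < config.significance_gate):
            continue
        for label, conc in config.levels.items():
            out.append(invert_to_threshold(fit, conc, config, label=label))
    return out


def threshold_table(fits: Sequence[LengthHgFit],
                    config: Optional[ScreeningConfig] = None):
    """Reporting grid: one row per fit, one rendered column per level.

    Non-significant fits keep their row but carry dashed threshold cells.
    """
    import pandas as pd

    config = config or ScreeningConfig()
    rows = []
    for fit in fits:
        row = {
            "lake_id": fit.lake_id,
            "species": fit.species.value,
            "n": fit.n,
            "p_value": fit.p_value,
            "r2": fit.r2,
            "equation": fit.equation(),
        }
        for label, conc in config.levels.items():
            if fit.p_value < config.significance_gate:
                row[label] = invert_to_threshold(fit, conc, config, label=label).render()
            else:
                row[label] = "---"
        rows.append(row)
    cols = ["lake_id", "species", "n", "p_value", "r2", "equation", *config.levels]
    return pd.DataFrame(rows, columns=cols)
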