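"""Domain types and unit conventions for fish-tissue mercury surveys.

One row of a survey is a :class:`FishRecord`: a single fish with its lake,
species, total length (mm TL), wet mass (g), wet-weight tissue mercury
(ppm = mg/kg fresh tissue), nitrogen stable-isotope ratio (δ15N, ‰), otolith
age (years) and sex.  Mercury is stored and analysed in ppm wet weight
throughout; laboratory dry-weight measurements are converted at ingest with
:func:`dry_to_wet`.  Each lake carries an invertebrate δ15N baseline
(:class:`LakeContext`) used for trophic positioning, and the regulatory
context (screening levels, fishery length limits, species size caps, size
class bounds) lives in :class:`ScreeningConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "Species",
    "Sex",
    "FishRecord",
    "LakeContext",
    "ScreeningConfig",
    "SurveyDataset",
    "dry_to_wet",
    "ValidationError",
    "SingularDesignError",
    "NotSignificantError",
    "DegenerateDataError",
]


class ValidationError(ValueError):
    """Raised when input data violate the survey schema."""


class SingularDesignError(ValueError):
    """Raised when a regression design matrix has no variation."""


class NotSignificantError(ValueError):
    """Raised when a non-significant fit is used where the analysis forbids it."""


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined on the supplied data (e.g. zero variance)."""


class Species(str, Enum):
    BLUEGILL = "bluegill"
    BLACK_CRAPPIE = "black_crappie"
    LARGEMOUTH_BASS = "largemouth_bass"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _coerce_species(value) -> Species:
    if isinstance(value, Species):
        return value
    try:
        return Species(str(value))
    except ValueError:
        raise ValidationError(
            f"unknown species {value!r}; expected one of "
            f"{[s.value for s in Species]}"
        ) from None


def _coerce_sex(value) -> Sex:
    if value is None:
        return Sex.UNKNOWN
    if isinstance(value, Sex):
        return value
    try:
        return Sex(str(value))
    except ValueError:
        raise ValidationError(f"unknown sex {value!r}") from None


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    f = float(value)
    if math.isnan(f):
        return None
    return f


@dataclass(frozen=True)
class FishRecord:
    """A single sampled fish.

    Lengths are measured to the nearest mm in the field but carried as
    floats; ``hg_ww`` is tissue total mercury in ppm wet weight (>95% of
    which is methylmercury in fish muscle).
    """

    lake_id: str
    species: Species
    total_length: float  # mm TL
    hg_ww: Optional[float] = None  # ppm wet weight
    wet_mass: Optional[float] = None  # g
    d15n: Optional[float] = None  # permil
    age: Optional[float] = None  # years
    sex: Sex = Sex.UNKNOWN

    def __post_init__(self):
        object.__setattr__(self, "species", _coerce_species(self.species))
        object.__setattr__(self, "sex", _coerce_sex(self.sex))
        object.__setattr__(self, "total_length", float(self.total_length))
        for name in ("hg_ww", "wet_mass", "d15n", "age"):
            object.__setattr__(self, name, _opt_float(getattr(self, name)))
        if not (self.total_length > 0):
            raise ValidationError(f"total_length must be > 0, got {self.total_length}")
        if self.hg_ww is not None and not (self.hg_ww > 0):
            raise ValidationError(f"hg_ww must be > 0 when present, got {self.hg_ww}")
        if self.age is not None and self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")


@dataclass(frozen=True)
class LakeContext:
    """Per-lake metadata: the invertebrate composite δ15N baseline."""

    lake_id: str
    baseline_d15n: float  # permil, mean of the invertebrate composite
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "baseline_d15n", float(self.baseline_d15n))
        if not math.isfinite(self.baseline_d15n):
            raise ValidationError("baseline_d15n must be finite")


def _default_levels() -> dict:
    # ppm wet weight: USEPA screening 0.3, North Carolina screening 0.4,
    # USFDA action level 1.0
    return {"USEPA": 0.3, "NC": 0.4, "USFDA": 1.0}


def _default_limits() -> dict:
    # minimum legal harvest length, mm TL; bluegill typically unregulated
    return {
        Species.LARGEMOUTH_BASS: 355.0,
        Species.BLACK_CRAPPIE: 203.0,
        Species.BLUEGILL: None,
    }


def _default_caps() -> dict:
    # maximum achievable size of the species, mm TL; the bass cap is a
    # configurable convention (no published value)
    return {
        Species.BLUEGILL: 300.0,
        Species.BLACK_CRAPPIE: 500.0,
        Species.LARGEMOUTH_BASS: 700.0,
    }


def _default_class_bounds() -> dict:
    # (small/medium, medium/large) cut points, mm TL
    return {
        Species.BLUEGILL: (115.0, 150.0),
        Species.LARGEMOUTH_BASS: (355.0, 432.0),
        Species.BLACK_CRAPPIE: (203.0, 279.0),
    }


@dataclass
class ScreeningConfig:
    """Screening levels, harvest length limits and size conventions.

    Parameters
    ----------
    levels : mapping of label -> concentration (ppm wet weight)
    length_limits : mapping of species -> minimum harvest length (mm) or None
    max_species_length : mapping of species -> maximum achievable length (mm)
    size_class_bounds : mapping of species -> (small/medium, medium/large)
        length cut points (mm) for the stratified sampling design
    significance_gate : regressions with p >= gate are not inverted to
        threshold lengths (default 0.05)
    monitoring_window : closed length interval (mm) used for the routine
        monitoring mean-Hg predictor (default 320-385 mm)
    """

    levels: dict = field(default_factory=_default_levels)
    length_limits: dict = field(default_factory=_default_limits)
    max_species_length: dict = field(default_factory=_default_caps)
    size_class_bounds: dict = field(default_factory=_default_class_bounds)
    significance_gate: float = 0.05
    monitoring_window: tuple = (320.0, 385.0)

    def __post_init__(self):
        self.length_limits = {_coerce_species(k): (None if v is None else float(v))
                              for k, v in self.length_limits.items()}
        self.max_species_length = {_coerce_species(k): float(v)
                                   for k, v in self.max_species_length.items()}
        self.size_class_bounds = {_coerce_species(k): (float(v[0]), float(v[1]))
                                  for k, v in self.size_class_bounds.items()}
        for label, conc in self.levels.items():
            if not conc > 0:
                raise ValidationError(f"screening level {label!r} must be > 0")
        for sp, (lo, hi) in self.size_class_bounds.items():
            if not lo < hi:
                raise ValidationError(
                    f"size class cut points for {sp.value} must be strictly "
                    f"increasing, got {(lo, hi)}"
                )
        if not self.monitoring_window[0] < self.monitoring_window[1]:
            raise ValidationError("monitoring window must have min < max")

    @classmethod
    def from_dict(cls, overrides: Mapping) -> "ScreeningConfig":
        """Build a config from a (possibly partial) key-value mapping."""
        cfg = cls()
        if not overrides:
            return cfg
        known = {"levels", "length_limits", "max_species_length",
                 "size_class_bounds", "significance_gate", "monitoring_window"}
        unknown = set(overrides) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "levels" in overrides:
            cfg.levels = {str(k): float(v) for k, v in overrides["levels"].items()}
        if "length_limits" in overrides:
            cfg.length_limits.update(
                {_coerce_species(k): (None if v is None else float(v))
                 for k, v in overrides["length_limits"].items()})
        if "max_species_length" in overrides:
            cfg.max_species_length.update(
                {_coerce_species(k): float(v)
                 for k, v in overrides["max_species_length"].items()})
        if "size_class_bounds" in overrides:
            cfg.size_class_bounds.update(
                {_coerce_species(k): (float(v[0]), float(v[1]))
                 for k, v in overrides["size_class_bounds"].items()})
        if "significance_gate" in overrides:
            cfg.significance_gate = float(overrides["significance_gate"])
        if "monitoring_window" in overrides:
            lo, hi = overrides["monitoring_window"]
            cfg.monitoring_window = (float(lo), float(hi))
        cfg.__post_init__()
        return cfg

    @classmethod
    def from_file(cls, path) -> "ScreeningConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


FISH_COLUMNS = ["lake_id", "species", "total_length_mm", "wet_mass_g",
                "hg_ppm_ww", "d15n_permil", "age_yr", "sex"]
LAKE_COLUMNS = ["lake_id", "name", "baseline_d15n_permil"]


@dataclass
class SurveyDataset:
    """A fish survey: records plus the per-lake baseline table."""

    records: list
    lakes: dict  # lake_id -> LakeContext

    def __post_init__(self):
        if not isinstance(self.lakes, dict):
            self.lakes = {lk.lake_id: lk for lk in self.lakes}
        missing = {r.lake_id for r in self.records} - set(self.lakes)
        if missing:
            raise ValidationError(
                f"fish records reference unknown lakes: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def baseline_for(self, lake_id: str) -> float:
        return self.lakes[lake_id].baseline_d15n

    def to_frame(self) -> pd.DataFrame:
        """Canonical tidy table, one row per fish."""
        rows = [{
            "lake_id": r.lake_id,
            "species": r.species.value,
            "total_length_mm": r.total_length,
            "wet_mass_g": np.nan if r.wet_mass is None else r.wet_mass,
            "hg_ppm_ww": np.nan if r.hg_ww is None else r.hg_ww,
            "d15n_permil": np.nan if r.d15n is None else r.d15n,
            "age_yr": np.nan if r.age is None else r.age,
            "sex": r.sex.value,
        } for r in self.records]
        return pd.DataFrame(rows, columns=FISH_COLUMNS)

    def lake_frame(self) -> pd.DataFrame:
        rows = [{"lake_id": lk.lake_id, "name": lk.name,
                 "baseline_d15n_permil": lk.baseline_d15n}
                for lk in self.lakes.values()]
        return pd.DataFrame(rows, columns=LAKE_COLUMNS)

    @classmethod
    def from_frames(cls, fish: pd.DataFrame, lakes: pd.DataFrame) -> "SurveyDataset":
        lake_objs = {}
        for _, row in lakes.iterrows():
            lid = str(row["lake_id"])
            if lid in lake_objs:
                raise ValidationError(f"duplicate lake_id {lid!r} in lake table")
            lake_objs[lid] = LakeContext(
                lake_id=lid,
                baseline_d15n=float(row["baseline_d15n_permil"]),
                name=str(row.get("name", "") or ""),
            )
        records = []
        for _, row in fish.iterrows():
            records.append(FishRecord(
                lake_id=str(row["lake_id"]),
                species=row["species"],
                total_length=row["total_length_mm"],
                wet_mass=row.get("wet_mass_g"),
                hg_ww=row.get("hg_ppm_ww"),
                d15n=row.get("d15n_permil"),
                age=row.get("age_yr"),
                sex=row.get("sex") if pd.notna(row.get("sex")) else None,
            ))
        return cls(records=records, lakes=lake_objs)

    def subset(self, lake_id=None, species=None) -> list:
        """Records filtered by lake and/or species."""
        out = self.records
        if lake_id is not None:
            out = [r for r in out if r.lake_id == lake_id]
        if species is not None:
            sp = _coerce_species(species)
            out = [r for r in out if r.species == sp]
        return out


def dry_to_wet(hg_dry, percent_moisture):
    """Convert dry-weight tissue Hg (ppm) back to wet weight.

    The homogenised filet is freeze-dried before analysis; the wet-weight
    concentration is the dry-weight value scaled by the solids fraction::

        hg_ww = hg_dry * (1 - percent_moisture / 100)

    Accepts scalars or arrays.  ``percent_moisture`` must lie in [0, 100).
    """
    hg_dry = np.asarray(hg_dry, dtype=float)
    pm = np.asarray(percent_moisture, dtype=float)
    if np.any(pm < 0) or np.any(pm >= 100):
        raise ValueError("percent_moisture must be in [0, 100)")
    if np.any(hg_dry < 0):
        raise ValueError("hg_dry must be >= 0")
    out = hg_dry * (1.0 - pm / 100.0)
    if out.ndim == 0:
        return float(out)
    return out
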