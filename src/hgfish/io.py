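"""Readers and writers for the delimited survey tables.

Two plain-text tables describe a survey: a fish table (one row per fish)
and a lake table (one row per lake with its invertebrate δ15N baseline).
The delimiter is auto-detected among comma and tab, since agency exports
vary.  A dry-weight mercury column plus percent moisture may be supplied in
place of wet-weight mercury; the dry→wet conversion is applied at ingest.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    FISH_COLUMNS,
    LAKE_COLUMNS,
    ScreeningConfig,
    Species,
    SurveyDataset,
    ValidationError,
    dry_to_wet,
)

logger = logging.getLogger(__name__)

_FISH_NUMERIC = ["total_length_mm", "wet_mass_g", "hg_ppm_ww",
                 "d15n_permil", "age_yr", "hg_ppm_dry", "percent_moisture"]


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _read_table(path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def _coerce_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        if col not in df.columns:
            continue
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & (raw.str.strip() != "") & coerced.isna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: malformed numeric cell in column {col!r} at data "
                f"row {idx} (value {raw.iloc[idx]!r})")
        # re-parse with Python float(): exact round trip of written values
        # (pandas' fast string parser can be off in the last ulp)
        df[col] = raw.map(lambda s: float(s)
                          if isinstance(s, str) and s.strip() != "" else np.nan)
    return df


def read_lake_table(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = {"lake_id", "baseline_d15n_permil"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: lake table missing columns {sorted(missing)}")
    df = _coerce_numeric(df, ["baseline_d15n_permil"], path)
    if df["lake_id"].duplicated().any():
        dup = df["lake_id"][df["lake_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate lake_id {dup!r} in lake table")
    if "name" not in df.columns:
        df["name"] = ""
    return df[LAKE_COLUMNS]


def read_survey(fish_path, lakes_path, config: Optional[ScreeningConfig] = None) -> SurveyDataset:
    """Read the fish and lake tables into a validated :class:`SurveyDataset`.

    Rows with missing optional fields (wet mass, δ15N, age, sex) are
    retained; malformed numeric cells and unknown species labels are
    rejected with the offending row named.
    """
    lakes = read_lake_table(lakes_path)
    fish = _read_table(fish_path)
    required = {"lake_id", "species", "total_length_mm"}
    missing = required - set(fish.columns)
    if missing:
        raise ValidationError(f"{fish_path}: fish table missing columns {sorted(missing)}")
    fish = _coerce_numeric(fish, _FISH_NUMERIC, fish_path)

    valid_species = {s.value for s in Species}
    bad = ~fish["species"].isin(valid_species)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{fish_path}: unknown species {fish['species'].iloc[idx]!r} at "
            f"data row {idx}")

    # dry-weight ingest path
    if "hg_ppm_ww" not in fish.columns:
        if {"hg_ppm_dry", "percent_moisture"} <= set(fish.columns):
            fish["hg_ppm_ww"] = dry_to_wet(
                fish["hg_ppm_dry"].to_numpy(float),
                fish["percent_moisture"].to_numpy(float))
            logger.info("converted dry-weight Hg to wet weight at ingest")
        else:
            raise ValidationError(
                f"{fish_path}: need hg_ppm_ww or (hg_ppm_dry + percent_moisture)")
    for col in FISH_COLUMNS:
        if col not in fish.columns:
            fish[col] = np.nan
    return SurveyDataset.from_frames(fish[FISH_COLUMNS], lakes)


def write_survey(dataset: SurveyDataset, fish_path, lakes_path, sep: str = ",") -> None:
    """Write a dataset back to the two canonical delimited tables."""
    # %.17g guarantees float64 values survive the text round trip exactly
    dataset.to_frame().to_csv(fish_path, sep=sep, index=False, float_format="%.17g")
    dataset.lake_frame().to_csv(lakes_path, sep=sep, index=False, float_format="%.17g")
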