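"""Packaged fixture data: published regional estimates for Namibia.

The bundled CSVs transcribe the published direct size estimates for female
sex workers (FSW) and men who have sex with men (MSM) from Namibia's
Integrated Bio-Behavioral Surveillance Studies (four surveyed regions per
population, seven estimation methods, with SS-PSE unavailable for MSM in
Karas and Oshana), the published Bayesian-consensus estimates per surveyed
region, and the published 2021 extrapolated regional estimates for all 13
regions under three imputation variants (simple, stratified by HIV
prevalence, stratified by population density), each before and after
program data informed the consensus priors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core_data import Dataset, conform_table

__all__ = [
    "load_namibia_regions",
    "load_namibia_direct_estimates",
    "load_namibia_consensus_estimates",
    "load_namibia_extrapolated_estimates",
    "load_namibia_dataset",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("kpsae.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype=str)


def load_namibia_regions() -> pd.DataFrame:
    """The 13 Namibian regions (region_id, name)."""
    return conform_table(_read("namibia_regions.csv"), "regions")


def load_namibia_direct_estimates() -> pd.DataFrame:
    """Method-level direct size estimates for the surveyed regions (54 rows)."""
    return conform_table(_read("namibia_direct_estimates.csv"), "direct_estimates")


def load_namibia_consensus_estimates() -> pd.DataFrame:
    """Published consensus estimates per surveyed region and population."""
    df = _read("namibia_consensus_estimates.csv")
    for c in ("point", "ci_lower", "ci_upper"):
        df[c] = pd.to_numeric(df[c])
    return df


def load_namibia_extrapolated_estimates() -> pd.DataFrame:
    """Published 2021 extrapolated regional estimates, long format.

    Columns: population, region_id, variant
    ({simple, stratified_hiv, stratified_density}), data_mode
    ({pre_program, post_program}), estimate (persons).
    """
    df = _read("namibia_extrapolated_estimates.csv")
    df["estimate"] = pd.to_numeric(df["estimate"]).astype(int)
    return df


def load_namibia_dataset() -> Dataset:
    """Regions plus direct estimates as a :class:`~kpsae.core_data.Dataset`."""
    return Dataset(
        regions=load_namibia_regions(),
        direct_estimates=load_namibia_direct_estimates(),
    )
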