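"""Packaged table of observed per-treatment mean growth increments.

The package ships the published field study's treatment-cell means (mean
growth increment per year x browsing x insect cell for each of the three
traits, with per-cell sample sizes) as a small CSV.  These means anchor the
desk-checkable worked examples: percentage growth reductions and the
multiplicative-risk interaction arithmetic can be reproduced from them
without any raw data.

Cells are labelled with the same level names used throughout the package:
2016 browsing in {control, clipped} x insects in {no, yes}; 2017 browsing in
{none, b2016, b2017, b2016_2017} x insects in {once, twice}.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["observed_cell_means", "fixture_mean"]


@lru_cache(maxsize=1)
def _load() -> pd.DataFrame:
    with resources.files("pinegrowth").joinpath("resources/observed_cell_means.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    df["year"] = df["year"].astype(int)
    df["n"] = df["n"].astype(int)
    return df


def observed_cell_means() -> pd.DataFrame:
    """The 36-row table of observed cell means (12 cells for 2016, 24 for 2017).

    Columns: year, browsing, insects, trait, mean, n, unit.  Radial means in
    mm, height means in cm.
    """
    return _load().copy()


def fixture_mean(year: int, browsing: str, insects: str, trait: str) -> float:
    """Look up one observed cell mean."""
    df = _load()
    hit = df[
        (df["year"] == int(year))
        & (df["browsing"] == browsing)
        & (df["insects"] == insects)
        & (df["trait"] == trait)
    ]
    if len(hit) != 1:
        raise KeyError(f"no unique fixture cell ({year}, {browsing}, {insects}, {trait})")
    return float(hit["mean"].iloc[0])
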