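"""Growth simulation with known ground truth for the factorial experiment.

The generator produces wide measurement tables (the same CSV schema a field
campaign would yield) from a treatment design plus an effect configuration.
Per tree, trait and year the growth increment is

    increment = baseline + slope * start_size
                + browsing_shift + insect_shift + interaction_shift
                + stand_intercept + block_intercept + residual

with the residual standard deviation chosen by the tree's browsing level —
the same group-wise variance structure the inference model estimates.  All
draws come from one seeded generator, so a (design, effects, seed) triple is
bit-reproducible.

``EffectConfig.field_calibrated()`` parameterises the generator so that expected
treatment-cell means at the mean starting size equal the observed field cell
means, with noise levels chosen to give standard errors of the mean of
roughly 1 mm (radial) and 3-4 cm (height) at the field cell sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fixture as fixture_mod
from .data import (
    BROWSING_Y1_LEVELS,
    BROWSING_Y2_LEVELS,
    INSECTS_Y1_LEVELS,
    INSECTS_Y2_LEVELS,
    TRAITS,
    compute_increments,
)
from .design import DesignConfig, ExperimentDesign, design_experiment
from .errors import ConfigurationError

__all__ = [
    "TraitYearEffects",
    "EffectConfig",
    "simulate_measurements",
    "simulate_growth",
]

_BROWSING_LEVELS = {2016: BROWSING_Y1_LEVELS, 2017: BROWSING_Y2_LEVELS}
_INSECT_LEVELS = {2016: INSECTS_Y1_LEVELS, 2017: INSECTS_Y2_LEVELS}

# trait -> (wide start column, mean attr of DesignConfig)
_START_COLS = {
    "R02": ("start_diam02_mm", "start_diam02_mean", "start_diam02_sd"),
    "R075": ("start_diam075_mm", "start_diam075_mean", "start_diam075_sd"),
    "H": ("start_height_cm", "start_height_mean", "start_height_sd"),
}
_END_COLS = {
    "R02": ("d02_2016_mm", "d02_2017_mm"),
    "R075": ("d075_2016_mm", "d075_2017_mm"),
    "H": ("h2016_cm", "h2017_cm"),
}


@dataclass
class TraitYearEffects:
    """Ground-truth linear predictor for one trait in one year.

    ``browsing`` and ``insects`` map every factor level (reference included,
    usually 0.0) to an additive shift on the increment scale;
    ``interaction`` maps (browsing, insects) cells to an extra shift (empty
    dict = purely additive truth).  ``resid_sd_by_browsing`` holds one
    residual SD per browsing level of the year.
    """

    baseline: float
    browsing: dict = field(default_factory=dict)
    insects: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    start_size_slope: float = 0.0
    stand_sd: float = 0.0
    block_sd: float = 0.0
    resid_sd_by_browsing: dict = field(default_factory=dict)

    def validate(self, year: int) -> None:
        for name, sd in (("stand_sd", self.stand_sd), ("block_sd", self.block_sd)):
            if sd < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {sd}")
        for lvl, sd in self.resid_sd_by_browsing.items():
            if sd < 0:
                raise ConfigurationError(f"resid_sd_by_browsing[{lvl!r}] must be >= 0")
        missing = [l for l in _BROWSING_LEVELS[year] if l not in self.resid_sd_by_browsing]
        if missing:
            raise ConfigurationError(
                f"resid_sd_by_browsing missing browsing level(s) {missing} for year {year}"
            )

    def shift(self, browsing: str, insects: str, year: int) -> float:
        """Total treatment shift for one cell (full controls shift by 0)."""
        try:
            b = self.browsing[browsing]
        except KeyError:
            raise ConfigurationError(
                f"no browsing effect configured for level {browsing!r} (year {year})"
            ) from None
        if insects == "none":  # never-treated full-control tree
            return b
        try:
            i = self.insects[insects]
        except KeyError:
            raise ConfigurationError(
                f"no insect effect configured for level {insects!r} (year {year})"
            ) from None
        return b + i + self.interaction.get((browsing, insects), 0.0)


def _zero_levels(levels) -> dict:
    return {l: 0.0 for l in levels}


class EffectConfig:
    """Ground-truth effects for every (trait, year) combination."""

    def __init__(self, effects: dict):
        missing = [(t, y) for t in TRAITS for y in (2016, 2017) if (t, y) not in effects]
        if missing:
            raise ConfigurationError(f"EffectConfig missing trait-year entries: {missing}")
        self.effects = dict(effects)
        for (trait, year), eff in self.effects.items():
            eff.validate(year)

    def __getitem__(self, key) -> TraitYearEffects:
        return self.effects[key]

    def to_dict(self) -> dict:
        """Plain nested dict (YAML/JSON-safe) representation."""
        out: dict = {}
        for (trait, year), e in self.effects.items():
            out.setdefault(trait, {})[int(year)] = {
                "baseline": e.baseline,
                "browsing": dict(e.browsing),
                "insects": dict(e.insects),
                "interaction": {f"{b}|{i}": v for (b, i), v in e.interaction.items()},
                "start_size_slope": e.start_size_slope,
                "stand_sd": e.stand_sd,
                "block_sd": e.block_sd,
                "resid_sd_by_browsing": dict(e.resid_sd_by_browsing),
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "EffectConfig":
        effects = {}
        for trait, by_year in d.items():
            for year, e in by_year.items():
                effects[(trait, int(year))] = TraitYearEffects(
                    baseline=float(e["baseline"]),
                    browsing={k: float(v) for k, v in e.get("browsing", {}).items()},
                    insects={k: float(v) for k, v in e.get("insects", {}).items()},
                    interaction={
                        tuple(k.split("|")): float(v)
                        for k, v in e.get("interaction", {}).items()
                    },
                    start_size_slope=float(e.get("start_size_slope", 0.0)),
                    stand_sd=float(e.get("stand_sd", 0.0)),
                    block_sd=float(e.get("block_sd", 0.0)),
                    resid_sd_by_browsing={
                        k: float(v) for k, v in e["resid_sd_by_browsing"].items()
                    },
                )
        return cls(effects)

    @classmethod
    def null(cls, baseline: float = 10.0, resid_sd: float = 1.0,
             stand_sd: float = 0.0, block_sd: float = 0.0) -> "EffectConfig":
        """All treatment effects zero — the no-effect reference configuration."""
        effects = {}
        for trait in TRAITS:
            for year in (2016, 2017):
                effects[(trait, year)] = TraitYearEffects(
                    baseline=baseline,
                    browsing=_zero_levels(_BROWSING_LEVELS[year]),
                    insects=_zero_levels(_INSECT_LEVELS[year]),
                    start_size_slope=0.0,
                    stand_sd=stand_sd,
                    block_sd=block_sd,
                    resid_sd_by_browsing={l: resid_sd for l in _BROWSING_LEVELS[year]},
                )
        return cls(effects)

    @classmethod
    def field_calibrated(cls) -> "EffectConfig":
        """Truth calibrated to the observed field cell means.

        Expected cell means at the mean starting size reproduce the observed
        per-cell growth means; shifts are coded against the un-clipped /
        least-defoliated reference cell.  Noise: residual SD 2.5 mm radial
        (10% higher per clipping event) and 9 cm height, block SD about 40%
        and stand SD about 20% of the residual SD.
        """
        fx = fixture_mod.observed_cell_means()
        slopes = {"R02": 0.05, "R075": 0.05, "H": 0.10}
        start_means = {"R02": 42.0, "R075": 29.5, "H": 172.0}
        resid0 = {"R02": 2.5, "R075": 2.5, "H": 9.0}
        clip_events = {
            "control": 0, "clipped": 1,
            "none": 0, "b2016": 1, "b2017": 1, "b2016_2017": 2,
        }
        ref_ins = {2016: "no", 2017: "once"}
        ref_b = {2016: "control", 2017: "none"}
        effects = {}
        for trait in TRAITS:
            for year in (2016, 2017):
                sub = fx[(fx["trait"] == trait) & (fx["year"] == year)]
                mean = {
                    (b, i): m
                    for b, i, m in zip(sub["browsing"], sub["insects"], sub["mean"])
                }
                rb, ri = ref_b[year], ref_ins[year]
                ref = mean[(rb, ri)]
                browsing = {b: mean[(b, ri)] - ref for b in _BROWSING_LEVELS[year]}
                insects = {i: mean[(rb, i)] - ref for i in _INSECT_LEVELS[year]}
                interaction = {}
                for b in _BROWSING_LEVELS[year]:
                    for i in _INSECT_LEVELS[year]:
                        extra = mean[(b, i)] - (ref + browsing[b] + insects[i])
                        if abs(extra) > 1e-12:
                            interaction[(b, i)] = extra
                effects[(trait, year)] = TraitYearEffects(
                    baseline=ref - slopes[trait] * start_means[trait],
                    browsing=browsing,
                    insects=insects,
                    interaction=interaction,
                    start_size_slope=slopes[trait],
                    stand_sd=0.2 * resid0[trait],
                    block_sd=0.4 * resid0[trait],
                    resid_sd_by_browsing={
                        l: resid0[trait] * (1 + 0.1 * clip_events[l])
                        for l in _BROWSING_LEVELS[year]
                    },
                )
        return cls(effects)


def simulate_measurements(
    design: ExperimentDesign, eff: EffectConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate a wide measurement table for a designed experiment.

    Starting sizes are drawn once per tree from the configured normals and
    truncated at 1% of their mean (a deterministic positivity guard); random
    intercepts are drawn per stand and per block independently for each
    trait-year; residuals use the browsing-level-specific SD.
    """
    rng = np.random.default_rng(seed)
    cfg = design.config
    trees = design.trees.reset_index(drop=True)
    n = len(trees)
    wide = trees.copy()

    stands = pd.unique(trees["stand"])
    blocks = pd.unique(trees["block"])
    stand_ix = trees["stand"].map({s: k for k, s in enumerate(stands)}).to_numpy()
    block_ix = trees["block"].map({b: k for k, b in enumerate(blocks)}).to_numpy()

    start = {}
    for trait, (col, mean_attr, sd_attr) in _START_COLS.items():
        mu, sd = getattr(cfg, mean_attr), getattr(cfg, sd_attr)
        draws = rng.normal(mu, sd, size=n)
        start[trait] = np.maximum(draws, 0.01 * mu)
        wide[col] = start[trait]

    for trait in TRAITS:
        floor = 0.01 * getattr(cfg, _START_COLS[trait][1])
        prev = start[trait]
        for year, end_col in zip((2016, 2017), _END_COLS[trait]):
            e = eff[(trait, year)]
            stand_u = rng.normal(0.0, e.stand_sd, size=len(stands)) if e.stand_sd else np.zeros(len(stands))
            block_u = rng.normal(0.0, e.block_sd, size=len(blocks)) if e.block_sd else np.zeros(len(blocks))
            browsing = trees["browsing_y1"] if year == 2016 else trees["browsing_y2"]
            insects = trees["insects_y1"] if year == 2016 else trees["insects"]
            mu = np.empty(n)
            sd = np.empty(n)
            for k in range(n):
                b, i = browsing.iat[k], insects.iat[k]
                mu[k] = e.baseline + e.start_size_slope * start[trait][k] + e.shift(b, i, year)
                sd[k] = e.resid_sd_by_browsing[b]
            mu += stand_u[stand_ix] + block_u[block_ix]
            inc = mu + rng.normal(0.0, 1.0, size=n) * sd
            end = np.maximum(prev + inc, floor)
            wide[end_col] = end
            prev = end
    return wide


def simulate_growth(
    design: ExperimentDesign, eff: EffectConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate and return the long growth table (one row per tree-trait-year)."""
    return compute_increments(simulate_measurements(design, eff, seed))


def simulate_default_experiment(seed: int | None = None, **design_kwargs) -> pd.DataFrame:
    """Convenience: default field design + field-calibrated effects -> wide table."""
    cfg = DesignConfig(seed=seed, **design_kwargs)
    design = design_experiment(cfg)
    sim_seed = None if seed is None else seed + 1
    return simulate_measurements(design, EffectConfig.field_calibrated(), sim_seed)
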