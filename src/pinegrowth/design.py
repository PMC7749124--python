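"""Factorial block-design generator for the two-year herbivory experiment.

The default configuration reproduces the field layout: 2 stands x 8 blocks
x 4 trees = 64 trees.  In year 1 each block receives the full 2 x 2
factorial (clipped/control crossed with sawflies yes/no, one tree per cell).
Between seasons half the previously clipped and half the previously
un-clipped trees are (re-)clipped, and all trees receive larvae, producing
the 4-level browsing history crossed with sawflies once/twice — 8 cells.

Re-randomisation is stratified so that, within each stand, the year-1 insect
exposure is split evenly across the four browsing histories: for each prior
treatment pair inside a block the member that escalates is chosen per block,
with exactly half of a stand's blocks escalating the previously-defoliated
member.  With the default configuration every year-2 cell therefore holds
8 trees.

Additional never-treated reference trees ("full controls") can be appended;
by default 7 such trees are placed in distinct blocks of stand 2, mirroring
the field protocol.  Their block placement within the stand is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError

__all__ = ["DesignConfig", "ExperimentDesign", "design_experiment"]


@dataclass(frozen=True)
class DesignConfig:
    """Size and starting-size parameters of a synthetic experiment.

    Starting sizes are drawn per tree from independent normals; defaults are
    the field cohort's summary statistics (height 172.0 +/- 23.6 cm, diameter
    42.0 +/- 8.2 mm at 0.2 m and 29.5 +/- 7.8 mm at 0.75 m).
    """

    n_stands: int = 2
    blocks_per_stand: int = 8
    trees_per_block: int = 4
    start_height_mean: float = 172.0
    start_height_sd: float = 23.6
    start_diam02_mean: float = 42.0
    start_diam02_sd: float = 8.2
    start_diam075_mean: float = 29.5
    start_diam075_sd: float = 7.8
    n_full_controls: int = 7
    seed: int | None = None

    def __post_init__(self):
        for name in ("n_stands", "blocks_per_stand", "trees_per_block"):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("start_height_sd", "start_diam02_sd", "start_diam075_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.trees_per_block % 2:
            raise DesignError(
                "trees_per_block must be even: year-1 clipping is applied to "
                f"exactly half of each block (got {self.trees_per_block})"
            )
        if self.n_full_controls < 0:
            raise DesignError("n_full_controls must be >= 0")

    @property
    def n_trees(self) -> int:
        return self.n_stands * self.blocks_per_stand * self.trees_per_block

    @property
    def n_blocks(self) -> int:
        return self.n_stands * self.blocks_per_stand

    def with_seed(self, seed: int) -> "DesignConfig":
        return replace(self, seed=seed)


@dataclass
class ExperimentDesign:
    """Treatment assignment skeleton: one row per tree, no measurements yet."""

    config: DesignConfig
    trees: pd.DataFrame  # tree_id, stand, block, browsing_y1, insects_y1, browsing_y2, insects, is_full_control

    @property
    def n_trees(self) -> int:
        return int((~self.trees["is_full_control"]).sum())

    def cell_counts(self, year: int = 2017) -> pd.Series:
        """Tree counts per treatment cell of the requested year."""
        t = self.trees[~self.trees["is_full_control"]]
        if year == 2016:
            return t.groupby(["browsing_y1", "insects_y1"], observed=True).size()
        return t.groupby(["browsing_y2", "insects"], observed=True).size()


def _split_half(items: list, rng: np.random.Generator) -> tuple[list, list]:
    """Random half/half partition (first list gets the ceil on odd sizes)."""
    items = list(items)
    rng.shuffle(items)
    k = (len(items) + 1) // 2
    return items[:k], items[k:]


def design_experiment(cfg: DesignConfig) -> ExperimentDesign:
    """Generate the block-stratified two-year treatment assignment.

    Deterministic for a fixed ``cfg.seed``.  Year-1 randomisation assigns
    clipping to half of each block and sawflies to half of each clipping
    group; year-2 escalation is stratified within (block x prior treatment)
    so year-2 cells are as balanced as the tree count allows.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for s in range(1, cfg.n_stands + 1):
        stand = f"S{s}"
        # which blocks escalate their previously-defoliated member, per
        # prior browsing stratum — exactly half of the stand's blocks each
        nb = cfg.blocks_per_stand
        esc_clipped = set(_split_half(range(nb), rng)[0])
        esc_control = set(_split_half(range(nb), rng)[0])
        for b in range(nb):
            block = f"B{b + 1:02d}"
            n = cfg.trees_per_block
            idx = list(range(n))
            clipped, control = _split_half(idx, rng)
            for group, browsing_y1 in ((clipped, "clipped"), (control, "control")):
                with_insects, without = _split_half(group, rng)
                escalate = esc_clipped if browsing_y1 == "clipped" else esc_control
                # year-2: half of each prior-treatment group is (re-)clipped;
                # which insect-history members escalate alternates across the
                # stand's blocks so insect exposure splits evenly
                if b in escalate:
                    ordered = with_insects + without
                else:
                    ordered = without + with_insects
                k = (len(group) + 1) // 2
                reclipped = set(ordered[:k])
                for t in group:
                    insects_y1 = "yes" if t in with_insects else "no"
                    if browsing_y1 == "clipped":
                        browsing_y2 = "b2016_2017" if t in reclipped else "b2016"
                    else:
                        browsing_y2 = "b2017" if t in reclipped else "none"
                    rows.append(
                        {
                            "tree_id": f"{stand}{block}T{t + 1}",
                            "stand": stand,
                            "block": f"{stand}{block}",
                            "browsing_y1": browsing_y1,
                            "insects_y1": insects_y1,
                            "browsing_y2": browsing_y2,
                            "insects": "twice" if insects_y1 == "yes" else "once",
                            "is_full_control": False,
                        }
                    )
    # never-treated reference trees, one per block of the last stand
    fc_stand = f"S{cfg.n_stands}"
    for j in range(cfg.n_full_controls):
        b = j % cfg.blocks_per_stand
        rows.append(
            {
                "tree_id": f"{fc_stand}B{b + 1:02d}FC{j + 1}",
                "stand": fc_stand,
                "block": f"{fc_stand}B{b + 1:02d}",
                "browsing_y1": "control",
                "insects_y1": "no",
                "browsing_y2": "none",
                "insects": "none",
                "is_full_control": True,
            }
        )
    trees = pd.DataFrame(rows)
    trees = trees.sort_values("tree_id", kind="stable").reset_index(drop=True)
    return ExperimentDesign(config=cfg, trees=trees)
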