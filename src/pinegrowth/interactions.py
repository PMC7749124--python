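"""Observed-vs-expected classification of combined herbivory effects.

For each treatment that combines clipping with repeated defoliation the
observed per-tree growth reduction is compared with the reduction expected
if the two stressors acted independently:

* per-tree observed relative reduction  Obs_t = (x̄_control − y_t) / x̄_control,
* single-stressor effect sizes          Ind = |x̄_treatment − x̄_control| / x̄_control,
* multiplicative-risk expectation       Exp = Ind_i + Ind_j − Ind_i · Ind_j,

and the per-tree differences D_t = Obs_t − Exp are summarised by their mean
and a 95% confidence interval.  If the whole interval lies above zero the
combined effect is *synergistic* (more reduction than expected), below zero
*antagonistic* (less than expected), otherwise *additive*.  The
multiplicative-risk combination keeps expected reductions below 100%, which
a plain sum of proportional effects would not.

Sign convention: reductions are coded positive.  Written literally as
"(observed − control)/control" the observed effect of a damaged tree would
be negative while Exp is a positive magnitude, making every damaged
treatment spuriously antagonistic; the reduction-positive orientation keeps
Obs and Exp on the same scale so that Obs − Exp > 0 means a
greater-than-expected reduction.  The literal orientation remains available
via ``sign="literal"`` for sensitivity checks.

In the year-2 design every tree carries larvae, so the control cell is the
un-clipped, defoliated-once cell, the browsing-only references are the
clipped, defoliated-once cells, and the insect-only reference is the
un-clipped, defoliated-twice cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import experimental_rows
from .errors import ValidationError

__all__ = [
    "COMBINED_TREATMENTS",
    "InteractionClassification",
    "observed_effects",
    "individual_effect",
    "expected_combined",
    "classify_interaction",
    "interaction_analysis",
]

#: the three clipping x repeated-defoliation cells that are classified
COMBINED_TREATMENTS = ("b2016", "b2017", "b2016_2017")
_CONTROL_CELL = ("none", "once")
_INSECT_ONLY_CELL = ("none", "twice")


def _cell(table: pd.DataFrame, browsing: str, insects: str, trait: str) -> np.ndarray:
    sub = table[
        (table["trait"] == trait)
        & (table["year"] == 2017)
        & (table["browsing_y2"] == browsing)
        & (table["insects"] == insects)
    ]
    return sub["increment"].to_numpy(float)


def observed_effects(table: pd.DataFrame, combined_treatment: str,
                     trait: str, sign: str = "reduction") -> np.ndarray:
    """Per-tree observed relative effects for one combined-herbivory cell.

    With the default reduction-positive convention each tree contributes
    (x̄_control − increment) / x̄_control; trees that outgrew the control
    mean yield negative values.
    """
    table = experimental_rows(table)
    control = _cell(table, *_CONTROL_CELL, trait)
    if control.size == 0:
        raise ValidationError(f"control cell {_CONTROL_CELL} empty for trait {trait}")
    xbar = float(control.mean())
    if xbar <= 0:
        raise ValidationError(f"control mean {xbar} <= 0: relative effects undefined")
    obs = _cell(table, combined_treatment, "twice", trait)
    rel = (xbar - obs) / xbar
    if sign == "literal":
        rel = -rel
    elif sign != "reduction":
        raise ValueError(f"sign must be 'reduction' or 'literal', got {sign!r}")
    return rel


def individual_effect(mean_treatment: float, mean_control: float) -> float:
    """Single-stressor effect size |x̄_treatment − x̄_control| / x̄_control."""
    if mean_control <= 0:
        raise ValidationError(
            f"control mean {mean_control} <= 0: effect size undefined"
        )
    return abs(mean_treatment - mean_control) / mean_control


def expected_combined(ind_i: float, ind_j: float) -> float:
    """Multiplicative-risk expectation Ind_i + Ind_j − Ind_i·Ind_j."""
    if ind_i < 0 or ind_j < 0:
        raise ValidationError("individual effect sizes must be >= 0")
    return ind_i + ind_j - ind_i * ind_j


@dataclass(frozen=True)
class InteractionClassification:
    """Mean observed-minus-expected effect with its CI and ternary label."""

    trait: str
    combined_treatment: str
    n_trees: int
    mean_diff: float
    ci_low: float
    ci_high: float
    label: str
    confidence: float = 0.95


def classify_interaction(obs, exp: float, confidence: float = 0.95,
                         ci: str = "t", n_boot: int = 10_000,
                         seed: int | None = None,
                         trait: str = "", combined_treatment: str = "",
                         ) -> InteractionClassification:
    """Classify one combined treatment from per-tree observed effects.

    The per-tree differences D = Obs − Exp are summarised by their mean and
    a two-sided confidence interval: Student-t with n−1 degrees of freedom
    by default, or a seeded percentile bootstrap (``ci="bootstrap"``).
    Labels: synergistic if the interval lies strictly above zero,
    antagonistic if strictly below, additive otherwise — an interval
    touching zero counts as additive (conservative closed-interval rule).
    """
    obs = np.asarray(obs, float)
    if obs.size < 2:
        raise ValidationError(
            f"need >= 2 trees to form a confidence interval, got {obs.size}"
        )
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    d = obs - exp
    mean = float(d.mean())
    if ci == "t":
        se = float(d.std(ddof=1) / np.sqrt(d.size))
        tcrit = stats.t.ppf(0.5 + confidence / 2, d.size - 1)
        lo, hi = mean - tcrit * se, mean + tcrit * se
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = rng.choice(d, size=(n_boot, d.size), replace=True).mean(axis=1)
        alpha = 1 - confidence
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        lo, hi = float(lo), float(hi)
    else:
        raise ValueError(f"ci must be 't' or 'bootstrap', got {ci!r}")
    if lo > 0:
        label = "synergistic"
    elif hi < 0:
        label = "antagonistic"
    else:
        label = "additive"
    return InteractionClassification(
        trait=trait, combined_treatment=combined_treatment, n_trees=int(d.size),
        mean_diff=mean, ci_low=lo, ci_high=hi, label=label, confidence=confidence,
    )


def interaction_analysis(table: pd.DataFrame, confidence: float = 0.95,
                         ci: str = "t", n_boot: int = 10_000,
                         seed: int | None = None,
                         sign: str = "reduction") -> pd.DataFrame:
    """Classify every combined treatment x trait of a year-2 growth table.

    Returns the 9-row classification table (3 combined treatments x 3
    traits) with columns trait, treatment, n, mean_diff, ci_low, ci_high,
    label.  Raises if any required cell (control, browsing-only reference,
    insect-only reference, or combined cell) is empty.
    """
    table = experimental_rows(table)
    traits = [t for t in ("R02", "R075", "H") if (table["trait"] == t).any()]
    rows = []
    for trait in traits:
        control = _cell(table, *_CONTROL_CELL, trait)
        insect_only = _cell(table, *_INSECT_ONLY_CELL, trait)
        for name, arr in (("control (none, once)", control),
                          ("insect-only (none, twice)", insect_only)):
            if arr.size == 0:
                raise ValidationError(f"required cell {name} empty for trait {trait}")
        xbar = float(control.mean())
        ind_insects = individual_effect(float(insect_only.mean()), xbar)
        for combo in COMBINED_TREATMENTS:
            browsing_only = _cell(table, combo, "once", trait)
            combined = _cell(table, combo, "twice", trait)
            if browsing_only.size == 0:
                raise ValidationError(
                    f"required cell ({combo}, once) empty for trait {trait}"
                )
            if combined.size == 0:
                raise ValidationError(
                    f"combined cell ({combo}, twice) empty for trait {trait}"
                )
            ind_browsing = individual_effect(float(browsing_only.mean()), xbar)
            # Exp is a positive reduction magnitude in both conventions;
            # under sign="literal" the Obs values flip, reproducing the
            # everything-antagonistic artefact discussed in the module docs
            exp = expected_combined(ind_browsing, ind_insects)
            obs = observed_effects(table, combo, trait, sign=sign)
            cls = classify_interaction(
                obs, exp, confidence=confidence, ci=ci, n_boot=n_boot, seed=seed,
                trait=trait, combined_treatment=combo,
            )
            rows.append(
                {"trait": trait, "treatment": f"{combo}+twice", "n": cls.n_trees,
                 "mean_diff": cls.mean_diff, "ci_low": cls.ci_low,
                 "ci_high": cls.ci_high, "label": cls.label}
            )
    return pd.DataFrame(rows)
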