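"""Data model, I/O and derived quantities for two-year pine herbivory experiments.

The experimental vocabulary
---------------------------
Each tree sits in a *block* (four neighbouring trees sharing microclimate)
nested in a *stand*.  Treatments are simulated ungulate browsing (clipping of
lateral shoots during dormancy) and sawfly defoliation (larvae feeding during
the growing season):

* year 1 — ``browsing_y1`` in {control, clipped} crossed with ``insects_y1``
  in {no, yes} (2 x 2 factorial);
* year 2 — every tree receives larvae, so the factors become the four-level
  browsing history ``browsing_y2`` in {none, b2016, b2017, b2016_2017}
  crossed with ``insects`` in {once, twice} (4 x 2 factorial, 8 cells).

Growth is tracked on three traits: radial increment at 0.2 m and 0.75 m stem
height (``R02``, ``R075``, mm) and height increment (``H``, cm).

Measurement tables are *wide* (one row per tree, one column per measurement
occasion); all inference runs on the *long* growth table produced by
:func:`compute_increments` (one row per tree x trait x year).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

TRAITS = ("R02", "R075", "H")
TRAIT_UNITS = {"R02": "mm", "R075": "mm", "H": "cm"}
YEARS = (2016, 2017)

BROWSING_Y1_LEVELS = ("control", "clipped")
INSECTS_Y1_LEVELS = ("no", "yes")
BROWSING_Y2_LEVELS = ("none", "b2016", "b2017", "b2016_2017")
INSECTS_Y2_LEVELS = ("once", "twice")

#: mandatory columns of the wide per-tree measurement CSV
MEASUREMENT_COLUMNS = (
    "tree_id",
    "stand",
    "block",
    "browsing_y1",
    "browsing_y2",
    "insects_y1",
    "insects",
    "start_height_cm",
    "start_diam02_mm",
    "start_diam075_mm",
    "h2016_cm",
    "d02_2016_mm",
    "d075_2016_mm",
    "h2017_cm",
    "d02_2017_mm",
    "d075_2017_mm",
)

_NUMERIC_COLUMNS = MEASUREMENT_COLUMNS[7:]

#: wide-table column holding each (trait, occasion) measurement
TRAIT_MEASUREMENTS = {
    "R02": ("start_diam02_mm", "d02_2016_mm", "d02_2017_mm"),
    "R075": ("start_diam075_mm", "d075_2016_mm", "d075_2017_mm"),
    "H": ("start_height_cm", "h2016_cm", "h2017_cm"),
}

# Sequence of herbivory events per year-2 cell.  Events are ordered in time:
# clipping happens while the tree is dormant (early spring), larvae feed in
# May-June, so within one calendar year clipping precedes defoliation.
_EVENT_SEP = "–"  # en dash, as conventionally printed
_SEQUENCES = {
    ("none", "once"): "Insect",
    ("none", "twice"): "Insect–Insect",
    ("b2016", "once"): "Clipping–Insect",
    ("b2016", "twice"): "Clipping–Insect–Insect",
    ("b2017", "once"): "Clipping–Insect",
    ("b2017", "twice"): "Insect–Clipping–Insect",
    ("b2016_2017", "once"): "Clipping–Clipping–Insect",
    ("b2016_2017", "twice"): "Clipping–Insect–Clipping–Insect",
}


@dataclass(frozen=True)
class TreatmentCode:
    """A year-2 treatment cell with its herbivory-event history."""

    browsing: str
    insects: str
    sequence: str
    n_events: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.browsing}+{self.insects} [{self.sequence}]"


def encode_treatment(browsing_y2: str, insects: str) -> TreatmentCode:
    """Return the herbivory-event sequence for a year-2 treatment cell.

    The sequence lists clipping and defoliation events in chronological
    order, e.g. a tree clipped in 2017 only and defoliated both years
    experienced Insect (2016) – Clipping (winter) – Insect (2017).

    Note that two distinct cells, (b2016, once) and (b2017, once), share the
    sequence string "Clipping–Insect": the event *history* alone does not
    identify the cell, only the full code does.
    """
    key = (browsing_y2, insects)
    if key not in _SEQUENCES:
        raise ValidationError(
            f"unknown treatment cell browsing_y2={browsing_y2!r}, insects={insects!r}"
        )
    seq = _SEQUENCES[key]
    return TreatmentCode(browsing_y2, insects, seq, seq.count(_EVENT_SEP) + 1)


def all_treatment_codes() -> list[TreatmentCode]:
    """The 8 year-2 treatment cells in factorial order."""
    return [
        encode_treatment(b, i)
        for b in BROWSING_Y2_LEVELS
        for i in INSECTS_Y2_LEVELS
    ]


@dataclass
class ValidationReport:
    """Outcome of structural validation of a measurement table.

    ``violations`` are inconsistencies that make a record unusable for
    inference (wrong factor levels, non-positive sizes, duplicated ids);
    ``warnings`` flag suspicious but plausible data such as negative growth
    increments (caliper measurement error can shrink a diameter).
    No row is ever dropped silently.
    """

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_on_violations(self) -> None:
        if self.violations:
            raise ValidationError(
                "measurement table failed validation:\n  "
                + "\n  ".join(self.violations)
            )


def validate_measurements(df: pd.DataFrame) -> ValidationReport:
    """Check structural invariants of a wide measurement table.

    An optional boolean ``is_full_control`` column marks trees that were
    never treated (extra reference trees outside the factorial design); for
    those rows the only accepted factor values are control/none/no.
    """
    report = ValidationReport()
    dup = df["tree_id"][df["tree_id"].duplicated()]
    for tid in dup:
        report.violations.append(f"duplicated tree_id {tid!r}")
    full_control = _full_control_mask(df)
    for row, is_fc in zip(df.itertuples(index=False), full_control):
        tid = row.tree_id
        if is_fc:
            if (row.browsing_y1, row.browsing_y2, row.insects_y1) != ("control", "none", "no"):
                report.violations.append(f"{tid}: full-control tree carries treatment levels")
            _check_sizes(row, report)
            continue
        if row.browsing_y1 not in BROWSING_Y1_LEVELS:
            report.violations.append(f"{tid}: unknown browsing_y1 {row.browsing_y1!r}")
            continue
        if row.browsing_y2 not in BROWSING_Y2_LEVELS:
            report.violations.append(f"{tid}: unknown browsing_y2 {row.browsing_y2!r}")
            continue
        clipped_y1 = row.browsing_y2 in ("b2016", "b2016_2017")
        if clipped_y1 != (row.browsing_y1 == "clipped"):
            report.violations.append(
                f"{tid}: browsing_y2={row.browsing_y2} inconsistent with "
                f"browsing_y1={row.browsing_y1}"
            )
        if row.insects not in INSECTS_Y2_LEVELS or row.insects_y1 not in INSECTS_Y1_LEVELS:
            report.violations.append(
                f"{tid}: unknown insect levels ({row.insects_y1!r}, {row.insects!r})"
            )
        elif (row.insects == "twice") != (row.insects_y1 == "yes"):
            report.violations.append(
                f"{tid}: insects={row.insects} inconsistent with insects_y1={row.insects_y1}"
            )
        _check_sizes(row, report)
    return report


def _full_control_mask(df: pd.DataFrame) -> np.ndarray:
    if "is_full_control" not in df.columns:
        return np.zeros(len(df), dtype=bool)
    col = df["is_full_control"]
    if col.dtype == bool:
        return col.to_numpy()
    return col.astype(str).str.strip().str.lower().isin(("true", "1", "yes")).to_numpy()


def _check_sizes(row, report: ValidationReport) -> None:
    tid = row.tree_id
    for col in _NUMERIC_COLUMNS:
        val = getattr(row, col)
        if pd.notna(val) and val <= 0:
            report.violations.append(f"{tid}: non-positive size {col}={val}")
    # negative increments are flagged, not rejected: caliper/pole error can
    # plausibly shrink a measurement between occasions
    for trait, (c0, c1, c2) in TRAIT_MEASUREMENTS.items():
        v0, v1, v2 = getattr(row, c0), getattr(row, c1), getattr(row, c2)
        if pd.notna(v0) and pd.notna(v1) and v1 < v0:
            report.warnings.append(f"{tid}: negative 2016 {trait} increment ({v1} < {v0})")
        if pd.notna(v1) and pd.notna(v2) and v2 < v1:
            report.warnings.append(f"{tid}: negative 2017 {trait} increment ({v2} < {v1})")


def read_measurements(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a wide measurement CSV.

    Unknown columns are preserved but ignored.  Missing mandatory columns
    raise :class:`SchemaError`; unparseable numeric entries raise
    :class:`ValidationError` naming the offending line.  Structural
    inconsistencies (factor mismatches, non-positive sizes) do not raise:
    they are listed in the returned :class:`ValidationReport` so the caller
    decides.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    bad_lines = []
    for col in _NUMERIC_COLUMNS:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        newly_bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        for idx in df.index[newly_bad]:
            # +2: header line plus 1-based counting
            bad_lines.append(f"line {idx + 2}: column {col} value {raw[idx]!r}")
        df[col] = parsed
    if bad_lines:
        raise ValidationError("unparseable numeric value(s):\n  " + "\n  ".join(bad_lines))
    for col in ("tree_id", "stand", "block"):
        df[col] = df[col].astype(str)
    report = validate_measurements(df)
    return df, report


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a wide measurement table as UTF-8 CSV with a header row."""
    cols = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    # round-trippable float formatting
    with io.StringIO() as buf:
        df.to_csv(buf, index=False, columns=cols)
        text = buf.getvalue()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(text)


def compute_increments(df: pd.DataFrame, years=YEARS) -> pd.DataFrame:
    """Derive the long growth table from a wide measurement table.

    Increment definitions: 2016 growth = end-of-2016 size minus starting
    size; 2017 growth = end-of-2017 size minus end-of-2016 size.  The
    ``start_size`` column carries the tree's pre-experiment starting size for
    the trait (the covariate used by the growth models in both years).

    Returns one row per tree x trait x requested year with columns
    tree_id, stand, block, browsing_y1, browsing_y2, insects_y1, insects,
    trait, year, start_size, increment, unit.
    """
    years = tuple(int(y) for y in years)
    if 2017 in years:
        for trait, (_, c1, _) in TRAIT_MEASUREMENTS.items():
            missing = df.loc[df[c1].isna(), "tree_id"].tolist()
            if missing:
                raise ValidationError(
                    f"2017 increments need end-of-2016 {trait} measurements; "
                    f"missing for tree(s): {', '.join(map(str, missing))}"
                )
    id_cols = [
        "tree_id", "stand", "block",
        "browsing_y1", "browsing_y2", "insects_y1", "insects",
    ]
    df = df.copy()
    df["is_full_control"] = _full_control_mask(df)
    id_cols.append("is_full_control")
    frames = []
    for trait, (c0, c1, c2) in TRAIT_MEASUREMENTS.items():
        for year in years:
            sub = df[id_cols].copy()
            sub["trait"] = trait
            sub["year"] = year
            sub["start_size"] = df[c0].to_numpy(dtype=float)
            if year == 2016:
                inc = df[c1].to_numpy(dtype=float) - df[c0].to_numpy(dtype=float)
            else:
                inc = df[c2].to_numpy(dtype=float) - df[c1].to_numpy(dtype=float)
            sub["increment"] = inc
            sub["unit"] = TRAIT_UNITS[trait]
            frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["trait", "year", "tree_id"], kind="stable").reset_index(drop=True)


def available_years(df: pd.DataFrame) -> tuple[int, ...]:
    """Seasons with complete measurements in a wide table (2017 requires the
    end-of-2017 columns to be filled for every tree)."""
    y2_cols = [cols[2] for cols in TRAIT_MEASUREMENTS.values()]
    if df[y2_cols].notna().all(axis=None):
        return (2016, 2017)
    return (2016,)


def browsing_factor(table: pd.DataFrame, year: int) -> pd.Series:
    """The browsing factor relevant to a model year (2 levels in 2016, 4 in 2017)."""
    return table["browsing_y1"] if year == 2016 else table["browsing_y2"]


def insect_factor(table: pd.DataFrame, year: int) -> pd.Series:
    """The insect factor relevant to a model year (no/yes in 2016, once/twice in 2017)."""
    return table["insects_y1"] if year == 2016 else table["insects"]


def experimental_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Drop full-control trees (never treated, outside the factorial design)."""
    if "is_full_control" in table.columns:
        return table[~table["is_full_control"].astype(bool)]
    return table


def cell_means(table: pd.DataFrame, trait: str, year: int) -> pd.DataFrame:
    """Unweighted treatment-cell means of growth increments for one trait-year.

    Full-control trees are excluded.  Returns a tidy frame with columns
    year, browsing, insects, trait, mean, n.
    """
    table = experimental_rows(table)
    sub = table[(table["trait"] == trait) & (table["year"] == int(year))]
    if sub.empty:
        raise ValidationError(f"no rows for trait={trait}, year={year}")
    g = sub.assign(
        browsing=browsing_factor(sub, year), insect_level=insect_factor(sub, year)
    ).groupby(["browsing", "insect_level"], observed=True)["increment"]
    out = g.agg(["mean", "count"]).reset_index()
    out.columns = ["browsing", "insects", "mean", "n"]
    out.insert(0, "year", int(year))
    out.insert(3, "trait", trait)
    return out
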