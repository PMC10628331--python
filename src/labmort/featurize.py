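"""SDL standardization and patient-day feature construction.

A raw result X for item k is standardized to its standard-deviation level

    SDL = |X - mu_k| / sigma_k

using the item's robust reference mean and SD from the value summary list.
SDL >= 2 defines Over2SD and SDL >= 3 defines Over3SD (both thresholds
inclusive).  Each patient-day of testing is then collapsed to one feature row
with 44 predictors -- sex, age, dialysis, 4 location indicators, 31
requesting-department indicators, and six aggregates of the day's SDL values
(item count, Over2SD/Over3SD counts and rates, mean SDL) -- plus a binary
label that is positive when the day falls within 7 days before the patient's
death (offsets 0..7 inclusive) and negative otherwise, including for patients
with no recorded death.

By construction no feature can be missing: every aggregate is defined for any
day with at least one scorable item, and days with none are omitted (and
counted) rather than imputed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lis_data import DEPARTMENTS, LOCATIONS, Cohort, age_at
from .value_summary import ValueSummaryEntry, ValueSummaryList

logger = logging.getLogger(__name__)


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


LOCATION_COLUMNS = tuple(f"loc_{_slug(l)}" for l in LOCATIONS)
DEPARTMENT_COLUMNS = tuple(f"dept_{_slug(d)}" for d in DEPARTMENTS)
AGGREGATE_COLUMNS = ("count_item", "count_over2sd", "count_over3sd",
                     "rate_over2sd", "rate_over3sd", "mean_sdl")

#: The 44 predictor columns, in stable order; the label column comes last.
FEATURE_COLUMNS: tuple[str, ...] = (
    ("sex_male", "age_years", "dialysis")
    + LOCATION_COLUMNS
    + DEPARTMENT_COLUMNS
    + AGGREGATE_COLUMNS
)
LABEL_COLUMN = "label"
ID_COLUMNS = ("patient_id", "test_date")

assert len(FEATURE_COLUMNS) == 44


@dataclass(frozen=True)
class SDLValue:
    """One standardized result: SDL magnitude and its threshold flags."""

    sdl: float
    over2sd: bool
    over3sd: bool


def compute_sdl(x: float, entry: ValueSummaryEntry) -> SDLValue:
    """Standardize a single value against its item's summary entry.

    Raises ValueError for degenerate entries (sigma_k = 0); callers that
    aggregate whole days skip such items with a counted warning instead.
    """
    if entry.sigma <= 0.0:
        raise ValueError(f"item {entry.item_code!r} is degenerate (sigma=0)")
    sdl = abs(x - entry.mu) / entry.sigma
    return SDLValue(sdl=sdl, over2sd=sdl >= 2.0, over3sd=sdl >= 3.0)


def label_outcome(test_date, death_date) -> int:
    """1 if ``test_date`` falls within 7 days before death, else 0.

    ``death_date`` may be None/NaT for patients with no record of death.
    A test after the recorded death date is invalid input.
    """
    if death_date is None or pd.isna(death_date):
        return 0
    offset = (pd.Timestamp(death_date) - pd.Timestamp(test_date)).days
    if offset < 0:
        raise ValueError("test_date after death_date")
    return int(offset <= 7)


@dataclass
class FeaturizeReport:
    """Bookkeeping from a build_feature_table run."""

    n_results: int = 0
    n_skipped_uncovered: int = 0
    n_skipped_degenerate: int = 0
    n_days_dropped: int = 0
    n_rows: int = 0


def build_feature_table(cohort: Cohort, summary: ValueSummaryList,
                        return_report: bool = False) -> pd.DataFrame:
    """Collapse a cohort into the patient-day feature table.

    Returns a DataFrame with ``patient_id``, ``test_date``, the 44 columns of
    :data:`FEATURE_COLUMNS` and the ``label`` column last.  Results whose item
    is absent from the summary, or degenerate there, are skipped and counted;
    a patient-day left with zero scorable items is omitted and counted.
    """
    report = FeaturizeReport(n_results=len(cohort.results))
    res = cohort.results

    frame = summary.frame()
    mu = res["item_code"].map(frame["mu"])
    sigma = res["item_code"].map(frame["sigma"])
    covered = ~sigma.isna()
    usable = covered & (sigma > 0)
    report.n_skipped_uncovered = int((~covered).sum())
    report.n_skipped_degenerate = int((covered & ~usable).sum())
    if report.n_skipped_uncovered or report.n_skipped_degenerate:
        logger.warning("featurize: skipped %d uncovered and %d degenerate results",
                       report.n_skipped_uncovered, report.n_skipped_degenerate)

    scored = res[usable].copy()
    if scored.empty:
        raise ValueError("no scorable results: summary covers no usable items")
    sdl = (scored["value"] - mu[usable]).abs() / sigma[usable]
    scored["sdl"] = sdl
    scored["over2sd"] = sdl >= 2.0
    scored["over3sd"] = sdl >= 3.0

    total_days = res[["patient_id", "test_date"]].drop_duplicates()
    agg = (scored.groupby(["patient_id", "test_date"], sort=True)
           .agg(count_item=("sdl", "size"),
                count_over2sd=("over2sd", "sum"),
                count_over3sd=("over3sd", "sum"),
                mean_sdl=("sdl", "mean"))
           .reset_index())
    agg["rate_over2sd"] = agg["count_over2sd"] / agg["count_item"]
    agg["rate_over3sd"] = agg["count_over3sd"] / agg["count_item"]
    report.n_days_dropped = len(total_days) - len(agg)
    if report.n_days_dropped:
        logger.warning("featurize: omitted %d patient-days with no scorable items",
                       report.n_days_dropped)

    rows = agg.merge(cohort.contexts, on=["patient_id", "test_date"],
                     how="left", validate="many_to_one")
    if rows["department"].isna().any():
        raise ValueError("some patient-days lack a test context")
    unknown = set(rows["department"]) - set(DEPARTMENTS)
    if unknown:
        raise ValueError(f"unknown departments: {sorted(unknown)}")
    unknown = set(rows["location"]) - set(LOCATIONS)
    if unknown:
        raise ValueError(f"unknown locations: {sorted(unknown)}")

    rows = rows.merge(cohort.patients, on="patient_id", how="left",
                      validate="many_to_one")
    rows["sex_male"] = (rows["sex"] == "male").astype(int)
    rows["age_years"] = age_at(rows["test_date"], rows["birth_date"]).astype(float)
    rows["dialysis"] = rows["dialysis"].astype(int)

    offset = (rows["death_date"] - rows["test_date"]).dt.days
    if (offset < 0).any():
        raise ValueError("tests dated after the patient's death date")
    rows[LABEL_COLUMN] = ((offset >= 0) & (offset <= 7)).fillna(False).astype(int)

    for col, loc in zip(LOCATION_COLUMNS, LOCATIONS):
        rows[col] = (rows["location"] == loc).astype(int)
    for col, dep in zip(DEPARTMENT_COLUMNS, DEPARTMENTS):
        rows[col] = (rows["department"] == dep).astype(int)

    out = rows[list(ID_COLUMNS) + list(FEATURE_COLUMNS) + [LABEL_COLUMN]].copy()
    for col in ("count_item", "count_over2sd", "count_over3sd"):
        out[col] = out[col].astype(int)
    if out.isna().any().any():
        raise AssertionError("feature table contains missing values")
    report.n_rows = len(out)
    if return_report:
        return out, report
    return out


def write_feature_table(features: pd.DataFrame, path) -> None:
    """Write features.csv with the documented stable column order."""
    df = features.copy()
    df["test_date"] = pd.to_datetime(df["test_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)
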