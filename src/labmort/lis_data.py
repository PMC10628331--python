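"""Cohort data model, delimited-text IO, exclusion filters and a synthetic LIS generator.

The atomic record is one numeric laboratory result: (patient_id, test_date,
item_code, value).  A "test" throughout this package means one
(patient_id, test_date) pair -- one day of laboratory testing for one
patient -- which is the unit the prediction models classify.

Files are comma-separated UTF-8 with a header row and ISO-8601 dates:

* ``results.csv``:  patient_id,test_date,item_code,value
* ``patients.csv``: patient_id,sex,birth_date,death_date,dialysis
* ``contexts.csv``: patient_id,test_date,department,location
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Requesting-department vocabulary (30 named departments plus "Others").
DEPARTMENTS: tuple[str, ...] = (
    "Obstetrics and gynecology",
    "Immuno-Rheumatology",
    "Cardiology",
    "Nephrology",
    "Emergency room",
    "Urology",
    "Endocrinology",
    "Gastroenterology",
    "Hematology",
    "Anesthesiology",
    "Oncology",
    "Respiratory medicine",
    "Internal medicine",
    "Breast surgery",
    "General surgery",
    "Infectious disease",
    "Cardiovascular surgery",
    "Orthopedics",
    "Dermatology",
    "Neurosurgery",
    "Neurology",
    "Psychiatry",
    "Thoracic surgery",
    "Ophthalmology",
    "Plastic surgery",
    "Neurovascular",
    "Palliative care",
    "Otorhinolaryngology",
    "Oral surgery",
    "Radiology",
    "Others",
)

# Relative test volume by requesting department in a 12-month urban
# teaching-hospital cohort; used as sampling weights by the generator.
_DEPARTMENT_COUNTS = np.array(
    [36946, 22013, 20785, 15464, 12044, 11815, 11772, 11509, 10493, 10110,
     10004, 9351, 9177, 8480, 6167, 5821, 4518, 4423, 3345, 3114, 2313,
     1329, 1324, 1158, 942, 774, 693, 686, 212, 156, 373],
    dtype=float,
)
DEPARTMENT_WEIGHTS: np.ndarray = _DEPARTMENT_COUNTS / _DEPARTMENT_COUNTS.sum()

#: Patient-location vocabulary.
LOCATIONS: tuple[str, ...] = (
    "outpatient", "general_ward", "intensive_care", "palliative_care",
)
# Baseline location mix (outpatient-dominated); final-week days are shifted
# towards intensive/palliative care.
LOCATION_WEIGHTS: np.ndarray = np.array([169743, 42089, 10944, 646], dtype=float)
LOCATION_WEIGHTS = LOCATION_WEIGHTS / LOCATION_WEIGHTS.sum()
TERMINAL_LOCATION_WEIGHTS: np.ndarray = np.array([0.10, 0.45, 0.35, 0.10])

RESULT_COLUMNS = ("patient_id", "test_date", "item_code", "value")
PATIENT_COLUMNS = ("patient_id", "sex", "birth_date", "death_date", "dialysis")
CONTEXT_COLUMNS = ("patient_id", "test_date", "department", "location")

# Healthy-population means and SDs for the critical-value panel items, in the
# units of the corresponding critical-value thresholds.  Each item's nearest
# critical bound sits roughly 2.5-3.5 SD from the mean, so threshold breaches
# are rare in well patients but common once values are grossly deranged.
REFERENCE_PANEL: dict[str, tuple[float, float]] = {
    "glucose": (100.0, 18.0),
    "creatinine": (0.9, 0.7),
    "total_bilirubin": (0.8, 1.4),
    "alkaline_phosphatase": (250.0, 250.0),
    "lactate_dehydrogenase": (220.0, 260.0),
    "aspartate_aminotransferase": (40.0, 320.0),
    "alanine_aminotransferase": (30.0, 320.0),
    "amylase": (80.0, 300.0),
    "creatine_kinase": (150.0, 1600.0),
    "calcium": (9.3, 1.0),
    "sodium": (140.0, 6.0),
    "potassium": (4.2, 0.55),
    "white_blood_cell_count": (7.5, 1.8),
    "hemoglobin": (12.5, 1.5),
    "platelet_count": (250.0, 67.0),
    "neutrophil_count": (4.5, 1.35),
    "lymphocyte_rate": (30.0, 13.0),
    "atypical_lymphocyte_rate": (1.0, 3.0),
    "eosinocyte_rate": (3.0, 5.5),
    "pt_inr": (1.1, 0.95),
    "activated_partial_thromboplastin_time": (32.0, 64.0),
    "fibrinogen": (310.0, 70.0),
}


class CohortError(ValueError):
    """Malformed cohort input (missing columns, empty files, bad vocabulary)."""


@dataclass
class Cohort:
    """In-memory laboratory cohort: results, patients and per-day test context.

    Attributes
    ----------
    results : DataFrame with columns patient_id, test_date, item_code, value.
    patients : DataFrame with columns patient_id, sex, birth_date, death_date,
        dialysis.  death_date is NaT for survivors.
    contexts : DataFrame with columns patient_id, test_date, department,
        location; exactly one row per (patient_id, test_date).
    n_dropped : rows discarded during reading because a cell failed type
        coercion.
    """

    results: pd.DataFrame
    patients: pd.DataFrame
    contexts: pd.DataFrame
    n_dropped: int = 0

    def validate(self) -> "Cohort":
        """Check referential integrity; raise :class:`CohortError` on failure."""
        known = set(self.patients["patient_id"])
        missing = set(self.results["patient_id"]) - known
        if missing:
            raise CohortError(f"results reference unknown patients: {sorted(missing)[:5]}")
        day_keys = pd.MultiIndex.from_frame(self.contexts[["patient_id", "test_date"]])
        if day_keys.duplicated().any():
            raise CohortError("contexts must have exactly one row per (patient_id, test_date)")
        result_days = pd.MultiIndex.from_frame(self.results[["patient_id", "test_date"]])
        if not result_days.isin(day_keys).all():
            raise CohortError("some result days have no test context")
        if not np.isfinite(self.results["value"].to_numpy(dtype=float)).all():
            raise CohortError("non-finite laboratory values")
        # Death before a patient's first test suggests corrupted extraction,
        # but readers only warn (post-mortem rows are rejected at featurization).
        died = self.patients.dropna(subset=["death_date"])
        if len(died):
            first = self.results.groupby("patient_id")["test_date"].min()
            joined = died.set_index("patient_id").join(first.rename("first_test"), how="inner")
            bad = joined[joined["death_date"] < joined["first_test"]]
            if len(bad):
                logger.warning("%d patients have death_date before first test", len(bad))
        return self

    @property
    def n_patient_days(self) -> int:
        return len(self.results[["patient_id", "test_date"]].drop_duplicates())

    def copy(self) -> "Cohort":
        return Cohort(self.results.copy(), self.patients.copy(), self.contexts.copy(),
                      self.n_dropped)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise CohortError(f"{path}: missing required column '{col}'")


def _read_csv(path, required) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    if df.empty and df.columns.empty:
        raise CohortError(f"{path}: empty file")
    _require_columns(df, required, path)
    if df.empty:
        raise CohortError(f"{path}: no data rows")
    return df


def read_cohort(results_path, patients_path, contexts_path) -> Cohort:
    """Read the three cohort CSVs and return a validated :class:`Cohort`.

    Rows whose cells fail type coercion (non-numeric value, unparseable date)
    are dropped; the count is recorded on ``Cohort.n_dropped`` and logged.
    A missing required column or an empty file is a hard error.
    """
    results = _read_csv(results_path, RESULT_COLUMNS)
    patients = _read_csv(patients_path, PATIENT_COLUMNS)
    contexts = _read_csv(contexts_path, CONTEXT_COLUMNS)

    n_dropped = 0

    results["value"] = pd.to_numeric(results["value"], errors="coerce")
    results["test_date"] = pd.to_datetime(results["test_date"], errors="coerce")
    bad = results["value"].isna() | results["test_date"].isna() | ~np.isfinite(results["value"].fillna(np.inf))
    n_dropped += int(bad.sum())
    results = results[~bad].reset_index(drop=True)

    patients["birth_date"] = pd.to_datetime(patients["birth_date"], errors="coerce")
    patients["death_date"] = pd.to_datetime(patients.get("death_date"), errors="coerce")
    patients["dialysis"] = pd.to_numeric(patients["dialysis"], errors="coerce")
    bad = patients["birth_date"].isna() | patients["dialysis"].isna() | ~patients["sex"].isin(["male", "female"])
    n_dropped += int(bad.sum())
    patients = patients[~bad].reset_index(drop=True)
    patients["dialysis"] = patients["dialysis"].astype(int)

    contexts["test_date"] = pd.to_datetime(contexts["test_date"], errors="coerce")
    bad = contexts["test_date"].isna()
    n_dropped += int(bad.sum())
    contexts = contexts[~bad].reset_index(drop=True)

    if n_dropped:
        logger.warning("read_cohort: dropped %d malformed rows", n_dropped)
    return Cohort(results, patients, contexts, n_dropped=n_dropped).validate()


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write the three cohort CSVs under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in ("results", "patients", "contexts")}

    res = cohort.results.copy()
    res["test_date"] = pd.to_datetime(res["test_date"]).dt.strftime("%Y-%m-%d")
    res.to_csv(paths["results"], index=False, columns=list(RESULT_COLUMNS))

    pat = cohort.patients.copy()
    pat["birth_date"] = pd.to_datetime(pat["birth_date"]).dt.strftime("%Y-%m-%d")
    pat["death_date"] = pd.to_datetime(pat["death_date"]).dt.strftime("%Y-%m-%d")
    pat.to_csv(paths["patients"], index=False, columns=list(PATIENT_COLUMNS))

    ctx = cohort.contexts.copy()
    ctx["test_date"] = pd.to_datetime(ctx["test_date"]).dt.strftime("%Y-%m-%d")
    ctx.to_csv(paths["contexts"], index=False, columns=list(CONTEXT_COLUMNS))
    return paths


def age_at(test_date, birth_date):
    """Age in whole years (floor) at ``test_date``; vectorised over Series."""
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(test_date, dtype="datetime64[ns]")))
    b = pd.DatetimeIndex(np.atleast_1d(np.asarray(birth_date, dtype="datetime64[ns]")))
    years = t.year - b.year
    before_birthday = (t.month < b.month) | ((t.month == b.month) & (t.day < b.day))
    out = years - before_birthday.astype(int)
    if np.isscalar(test_date) or isinstance(test_date, (pd.Timestamp, str)):
        return int(out[0])
    return np.asarray(out)


def apply_exclusions(cohort: Cohort, min_age_years: int = 18,
                     excluded_items: set[str] | frozenset[str] = frozenset()) -> Cohort:
    """Apply the cohort-level exclusion rules and return a new Cohort.

    Removes, in order: (a) all results from patient-days where the patient's
    age at test is below ``min_age_years``; (b) results whose item_code is in
    ``excluded_items`` (site-specific check-up / constant items); (c) results
    for any item_code measured exactly once across the whole remaining cohort.
    Running the age and vocabulary filters first makes the operation
    idempotent: deleting every result of a once-measured item cannot change
    any other item's count.
    """
    res = cohort.results.merge(
        cohort.patients[["patient_id", "birth_date"]], on="patient_id", how="left")
    age = age_at(res["test_date"], res["birth_date"])
    keep = age >= min_age_years
    if excluded_items:
        keep &= ~res["item_code"].isin(excluded_items)
    res = cohort.results[np.asarray(keep)]

    counts = res["item_code"].value_counts()
    once = counts[counts == 1].index
    if len(once):
        res = res[~res["item_code"].isin(once)]
    res = res.reset_index(drop=True)
    if res.empty:
        logger.warning("apply_exclusions: all results excluded")

    day_keys = pd.MultiIndex.from_frame(res[["patient_id", "test_date"]])
    ctx_keys = pd.MultiIndex.from_frame(cohort.contexts[["patient_id", "test_date"]])
    contexts = cohort.contexts[ctx_keys.isin(day_keys)].reset_index(drop=True)
    return Cohort(res, cohort.patients.copy(), contexts, cohort.n_dropped)


@dataclass
class SyntheticParams:
    """Configuration of the synthetic LIS cohort generator.

    Defaults emulate a 12-month adult cohort of an urban teaching hospital:
    a ~0.6% positive (within-7-days-of-death) patient-day rate, ages
    59 +/- 18.5 years, outpatient-dominated locations, department mix
    proportional to observed test volumes, and about 21 items per test day.
    Tests in a patient's final week carry more items (``effect_count``) and
    more extreme standardized deviations (``effect_sdl``).
    """

    n_patients: int = 5000
    start_date: str = "2018-07-01"
    n_days: int = 365
    n_item_types: int = 60
    positive_fraction: float = 0.006
    tolerance: float = 0.5            # relative tolerance on realized fraction
    mean_extra_days: float = 3.0      # test days per patient = 1 + Poisson(this)
    mean_extra_items: float = 20.0    # items per day = 1 + Poisson(this)
    mean_extra_terminal_days: float = 1.5  # final-week days = 1 + Poisson(this)
    effect_count: float = 1.4         # item-count multiplier, final week
    effect_sdl: float = 2.0           # mean deviation multiplier, final week
    terminal_location_shift: bool = True  # final-week days skew to ICU/palliative
    heavy_tail_fraction: float = 0.02  # share of grossly abnormal results overall
    heavy_tail_scale: float = 4.0
    female_fraction: float = 0.59
    age_mean: float = 59.0
    age_sd: float = 18.5
    dialysis_fraction: float = 0.03

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticParams":
        return cls(**json.loads(text))


def _item_panel(n_item_types: int, rng: np.random.Generator):
    """Per-item (code, mean, sd): critical-value panel first, then generic items."""
    codes = list(REFERENCE_PANEL)[:n_item_types]
    mus = [REFERENCE_PANEL[c][0] for c in codes]
    sds = [REFERENCE_PANEL[c][1] for c in codes]
    for i in range(len(codes), n_item_types):
        mu = float(rng.uniform(1.0, 300.0))
        codes.append(f"item_{i + 1:03d}")
        mus.append(mu)
        sds.append(mu * float(rng.uniform(0.15, 0.40)))
    return codes, np.array(mus), np.array(sds)


def generate_synthetic_cohort(params: SyntheticParams | None = None,
                              seed: int = 0) -> Cohort:
    """Generate a reproducible synthetic laboratory cohort.

    Deceased patients receive a death_date; their ordinary test days are drawn
    at least 8 days before death, and an extra cluster of final-week test days
    (1 + Poisson(mean_extra_terminal_days), capped at 8 distinct days) carries
    the terminal signature: item counts inflated by ``effect_count`` and
    standardized deviations inflated by a per-day severity multiplier drawn
    uniformly from [1, 2*effect_sdl - 1] (mean ``effect_sdl``), so some final
    -week days are only mildly abnormal.  The number of deceased patients is
    set so the expected positive patient-day fraction equals
    ``positive_fraction``; the realized fraction must land within the relative
    ``tolerance`` or a ValueError is raised.
    """
    params = params or SyntheticParams()
    if not (0.0 < params.positive_fraction < 1.0):
        raise ValueError("positive_fraction must be in (0, 1)")
    if params.n_item_types < 2:
        raise ValueError("n_item_types must be >= 2")
    if params.effect_count < 0 or params.effect_sdl < 0:
        raise ValueError("effect multipliers must be >= 0")

    rng = np.random.default_rng(seed)
    start = pd.Timestamp(params.start_date)
    n = params.n_patients
    codes, item_mu, item_sd = _item_panel(params.n_item_types, rng)

    # --- patients -----------------------------------------------------------
    patient_ids = np.array([f"P{i + 1:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < params.female_fraction, "female", "male")
    ages = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18.5, 95.0)
    birth = start - pd.to_timedelta((ages * 365.25).astype(int), unit="D")
    dialysis = (rng.random(n) < params.dialysis_fraction).astype(int)

    # Expected days: D ordinary per patient, T terminal per deceased patient.
    D = 1.0 + params.mean_extra_days
    T = min(1.0 + params.mean_extra_terminal_days, 8.0)
    p = params.positive_fraction
    n_dead_exact = p * n * D / (T * (1.0 - p))
    n_dead = max(1, min(int(round(n_dead_exact)), n))
    # When even death for every patient cannot reach the target fraction,
    # shrink the deceased patients' ordinary-day count instead.
    dead_ordinary_lam = None
    if n_dead_exact > n:
        dead_ordinary_lam = T * (1.0 - p) / p
    dead_idx = rng.choice(n, size=n_dead, replace=False)
    is_dead = np.zeros(n, dtype=bool)
    is_dead[dead_idx] = True
    # Leave >= 70 days of pre-terminal history within the study period.
    death_offset = np.full(n, -1)
    death_offset[dead_idx] = rng.integers(70, params.n_days, size=n_dead)

    # --- patient-days -------------------------------------------------------
    day_pid: list[np.ndarray] = []
    day_off: list[np.ndarray] = []
    day_term: list[np.ndarray] = []
    n_ordinary = 1 + rng.poisson(params.mean_extra_days, size=n)
    if dead_ordinary_lam is not None:
        n_ordinary[is_dead] = rng.poisson(dead_ordinary_lam, size=int(is_dead.sum()))
    for i in range(n):
        hi = params.n_days if not is_dead[i] else max(1, death_offset[i] - 8)
        offs = np.unique(rng.integers(0, hi, size=n_ordinary[i])) \
            if n_ordinary[i] else np.empty(0, dtype=int)
        pid_rows = [offs]
        term_rows = [np.zeros(len(offs), dtype=bool)]
        if is_dead[i]:
            k = min(8, 1 + rng.poisson(params.mean_extra_terminal_days))
            toffs = death_offset[i] - rng.choice(8, size=k, replace=False)
            toffs = toffs[toffs >= 0]
            pid_rows.append(toffs)
            term_rows.append(np.ones(len(toffs), dtype=bool))
        offs_all = np.concatenate(pid_rows)
        day_pid.append(np.full(len(offs_all), i))
        day_off.append(offs_all)
        day_term.append(np.concatenate(term_rows))
    pid = np.concatenate(day_pid)
    off = np.concatenate(day_off)
    term = np.concatenate(day_term)
    n_day = len(pid)

    # --- per-day context ----------------------------------------------------
    dept = rng.choice(len(DEPARTMENTS), size=n_day, p=DEPARTMENT_WEIGHTS)
    loc = rng.choice(4, size=n_day, p=LOCATION_WEIGHTS)
    n_term = int(term.sum())
    if n_term and params.terminal_location_shift:
        loc[term] = rng.choice(4, size=n_term, p=TERMINAL_LOCATION_WEIGHTS)

    # --- per-day item draws -------------------------------------------------
    lam = np.where(term, params.mean_extra_items * params.effect_count,
                   params.mean_extra_items)
    n_items = np.minimum(1 + rng.poisson(lam), params.n_item_types)
    # choose n_items[d] distinct items per day: rank a uniform matrix per row
    u = rng.random((n_day, params.n_item_types))
    rank = u.argsort(axis=1).argsort(axis=1)
    mask = rank < n_items[:, None]
    day_idx, item_idx = np.nonzero(mask)

    z = rng.standard_normal(len(day_idx))
    tail = rng.random(len(day_idx)) < params.heavy_tail_fraction
    z[tail] *= params.heavy_tail_scale
    severity = np.ones(n_day)
    if n_term and params.effect_sdl > 1.0:
        severity[term] = rng.uniform(1.0, 2.0 * params.effect_sdl - 1.0, size=n_term)
    z *= severity[day_idx]
    values = item_mu[item_idx] + item_sd[item_idx] * z

    # --- assemble frames ----------------------------------------------------
    dates = start + pd.to_timedelta(off, unit="D")
    results = pd.DataFrame({
        "patient_id": patient_ids[pid[day_idx]],
        "test_date": dates[day_idx],
        "item_code": np.asarray(codes, dtype=object)[item_idx],
        "value": values,
    }).sort_values(["patient_id", "test_date", "item_code"], ignore_index=True)

    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    death_date[is_dead] = start + pd.to_timedelta(death_offset[is_dead], unit="D")
    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "sex": sex,
        "birth_date": birth,
        "death_date": death_date.to_numpy(),
        "dialysis": dialysis,
    })
    contexts = pd.DataFrame({
        "patient_id": patient_ids[pid],
        "test_date": dates,
        "department": np.asarray(DEPARTMENTS, dtype=object)[dept],
        "location": np.asarray(LOCATIONS, dtype=object)[loc],
    }).sort_values(["patient_id", "test_date"], ignore_index=True)

    # realized positive patient-day fraction
    death_by_pid = death_offset[pid].astype(float)
    pos = (death_by_pid >= 0) & (death_by_pid - off >= 0) & (death_by_pid - off <= 7)
    realized = pos.mean()
    if abs(realized - p) > params.tolerance * p:
        raise ValueError(
            f"realized positive fraction {realized:.4f} outside tolerance of {p:.4f}")
    logger.info("synthetic cohort: %d patients, %d patient-days, %.4f positive",
                n, n_day, realized)
    return Cohort(results, patients, contexts).validate()
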