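"""New-user cohort construction: eligibility rules, exposure and outcome.

The analytic cohort is a diabetes-free incident-statin-user cohort: entry is
the first statin dispensation (day 0), eligibility requires a one-year
statin-free washout, one year of coverage, age >= 40 and entry between 1998
and 2010; patients with any other lipid-lowering drug, antidiabetic drug
(ATC A10), diabetes diagnosis (ICD-9 250.x / ICD-10 E10.x-E14.x), long-term
care admission in the lookback year or on the entry day, or more than one
statin dispensation on the entry day, are excluded. Exposure is the potency
class of the index dispensation; the outcome is incident diabetes (drug or
diagnosis) within days 1..730 after entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import BINARY_COVARIATES

__all__ = [
    "STATINS",
    "HIGH_POTENCY_THRESHOLDS",
    "CohortRules",
    "ExclusionReport",
    "classify_exposure",
    "classify_outcome",
    "apply_inclusion_exclusion",
]

STATINS = frozenset({
    "simvastatin", "lovastatin", "pravastatin",
    "fluvastatin", "atorvastatin", "rosuvastatin",
})

#: Minimum daily dose (mg) that makes the index statin "high potency";
#: products absent from this map are always lower potency.
HIGH_POTENCY_THRESHOLDS: dict[str, float] = {
    "rosuvastatin": 10.0,
    "atorvastatin": 20.0,
    "simvastatin": 40.0,
}

#: Order in which eligibility rules are applied; a patient failing several
#: is counted under the first (deterministic flow chart).
RULE_ORDER = [
    "no_index_statin",
    "prior_statin",
    "insufficient_coverage",
    "age_under_40",
    "entry_year_out_of_range",
    "other_lipid_lowering",
    "antidiabetic_dispensation",
    "diabetes_diagnosis",
    "long_term_care",
    "multiple_index_statins",
]


@dataclass
class CohortRules:
    """Configuration of the eligibility, exposure and outcome rules."""

    washout_days: int = 365
    min_age: float = 40.0
    entry_years: tuple[int, int] = (1998, 2010)
    outcome_window: tuple[int, int] = (1, 730)
    other_lipid_lowering: frozenset[str] = frozenset(
        {"niacin", "cerivastatin", "ezetimibe", "cholestyramine",
         "fenofibrate", "gemfibrozil", "statin_combination"})
    antidiabetic_prefix: str = "A10"
    diabetes_icd_prefixes: tuple[str, ...] = ("250", "E10", "E11", "E12", "E13", "E14")
    #: Optional map covariate -> (table, code prefixes) used to derive flags
    #: from raw records when the patients table carries no flag columns.
    covariate_codes: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts plus the per-patient first-failed rule."""

    counts: pd.DataFrame  # columns: rule, n_excluded (RULE_ORDER order)
    log: pd.DataFrame     # columns: patient_id, rule


def classify_exposure(product: str, daily_dose: float) -> str:
    """Potency class of an index statin dispensation: ``high`` or ``lower``."""
    product = str(product).lower()
    if product not in STATINS:
        raise ValueError(f"unknown statin product: {product!r}")
    if daily_dose <= 0:
        raise ValueError("daily_dose must be positive")
    threshold = HIGH_POTENCY_THRESHOLDS.get(product)
    return "high" if threshold is not None and daily_dose >= threshold else "lower"


def _is_diabetes_code(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    up = codes.astype(str).str.upper()
    mask = pd.Series(False, index=codes.index)
    for pref in prefixes:
        mask |= up.str.startswith(pref.upper())
    return mask


def classify_outcome(dispensations: pd.DataFrame, diagnoses: pd.DataFrame,
                     patient_ids: np.ndarray | pd.Series,
                     rules: CohortRules | None = None) -> pd.Series:
    """Flag incident diabetes in the follow-up window for each patient.

    A patient is a case iff an antidiabetic dispensation (ATC ``A10``) or a
    diabetes diagnosis (ICD-9 250.x / ICD-10 E10.x-E14.x) is recorded with
    ``days_relative_to_entry`` inside the outcome window (default 1..730).
    Absence of records means non-case.
    """
    rules = rules or CohortRules()
    lo, hi = rules.outcome_window
    case_ids: set = set()
    if len(dispensations):
        d = dispensations
        in_win = d["days_relative_to_entry"].between(lo, hi)
        is_ad = d["product"].astype(str).str.upper().str.startswith(
            rules.antidiabetic_prefix.upper())
        case_ids.update(d.loc[in_win & is_ad, "patient_id"])
    if len(diagnoses):
        g = diagnoses
        in_win = g["days_relative_to_entry"].between(lo, hi)
        is_dm = _is_diabetes_code(g["code"], rules.diabetes_icd_prefixes)
        case_ids.update(g.loc[in_win & is_dm, "patient_id"])
    ids = pd.Index(patient_ids, name="patient_id")
    return pd.Series(ids.isin(case_ids).astype(np.int64), index=ids, name="outcome")


def apply_inclusion_exclusion(dataset, rules: CohortRules | None = None
                              ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the eligibility rules and assemble the analytic cohort.

    Returns the cohort (one row per retained patient with exposure, outcome,
    demographics and the lookback covariate flags) and an
    :class:`ExclusionReport`. Rules run in :data:`RULE_ORDER`; entry-day
    records (day 0) count toward exclusions but not toward the outcome.
    Covariate flag columns on the patients table take precedence over
    derivation from raw records.
    """
    rules = rules or CohortRules()
    patients = dataset.patients
    for col in ("patient_id", "age", "entry_year"):
        if col not in patients.columns:
            raise ValueError(f"patients table missing required column {col!r}")
    disp = dataset.dispensations
    diag = getattr(dataset, "diagnoses", None)
    if diag is None:
        diag = pd.DataFrame(columns=["patient_id", "code", "days_relative_to_entry"])
    for col in ("patient_id", "product", "daily_dose", "days_relative_to_entry"):
        if len(disp) and col not in disp.columns:
            raise ValueError(f"dispensations table missing required column {col!r}")

    pid = patients["patient_id"].to_numpy()
    idx = pd.Index(pid)
    prod_lower = disp["product"].astype(str).str.lower() if len(disp) else pd.Series(dtype=str)
    days = disp["days_relative_to_entry"] if len(disp) else pd.Series(dtype=int)
    is_statin = prod_lower.isin(STATINS) if len(disp) else pd.Series(dtype=bool)

    def ids_where(mask: pd.Series) -> set:
        return set(disp.loc[mask, "patient_id"]) if len(disp) else set()

    index_statin_counts = (
        disp.loc[is_statin & (days == 0)].groupby("patient_id").size()
        if len(disp) else pd.Series(dtype=int))

    fail: dict[str, pd.Series] = {}
    fail["no_index_statin"] = ~idx.isin(index_statin_counts.index)
    fail["prior_statin"] = idx.isin(
        ids_where(is_statin & (days >= -rules.washout_days) & (days <= -1)))
    if "coverage_days" in patients.columns:
        fail["insufficient_coverage"] = (
            patients["coverage_days"].to_numpy() < rules.washout_days)
    else:
        fail["insufficient_coverage"] = np.zeros(len(patients), dtype=bool)
    fail["age_under_40"] = patients["age"].to_numpy() < rules.min_age
    fail["entry_year_out_of_range"] = ~patients["entry_year"].between(
        *rules.entry_years).to_numpy()
    lookback = (days >= -rules.washout_days) & (days <= 0) if len(disp) else None
    fail["other_lipid_lowering"] = idx.isin(
        ids_where(prod_lower.isin(rules.other_lipid_lowering) & lookback)
        if len(disp) else set())
    fail["antidiabetic_dispensation"] = idx.isin(
        ids_where(prod_lower.str.upper().str.startswith(
            rules.antidiabetic_prefix.upper()) & lookback)
        if len(disp) else set())
    if len(diag):
        dm = _is_diabetes_code(diag["code"], rules.diabetes_icd_prefixes)
        in_lb = diag["days_relative_to_entry"].between(-rules.washout_days, 0)
        fail["diabetes_diagnosis"] = idx.isin(set(diag.loc[dm & in_lb, "patient_id"]))
    else:
        fail["diabetes_diagnosis"] = np.zeros(len(patients), dtype=bool)
    if "long_term_care" in patients.columns:
        fail["long_term_care"] = patients["long_term_care"].to_numpy().astype(bool)
    else:
        fail["long_term_care"] = np.zeros(len(patients), dtype=bool)
    fail["multiple_index_statins"] = idx.isin(
        index_statin_counts.index[index_statin_counts > 1])

    excluded = np.zeros(len(patients), dtype=bool)
    rows = []
    log_frames = []
    for rule in RULE_ORDER:
        hit = np.asarray(fail[rule]) & ~excluded
        rows.append({"rule": rule, "n_excluded": int(hit.sum())})
        if hit.any():
            log_frames.append(pd.DataFrame({"patient_id": pid[hit], "rule": rule}))
        excluded |= hit
    report = ExclusionReport(
        counts=pd.DataFrame(rows),
        log=(pd.concat(log_frames, ignore_index=True) if log_frames
             else pd.DataFrame(columns=["patient_id", "rule"])),
    )

    kept = patients.loc[~excluded].copy().reset_index(drop=True)

    # Exposure: flag column takes precedence, else classify the index statin.
    if "exposure" not in kept.columns:
        index_disp = (disp.loc[is_statin & (days == 0)]
                      .drop_duplicates("patient_id").set_index("patient_id"))
        sub = index_disp.loc[kept["patient_id"]]
        kept["exposure"] = [
            classify_exposure(p, d)
            for p, d in zip(sub["product"], sub["daily_dose"])
        ]
    # Outcome: flag column takes precedence, else scan follow-up records.
    if "outcome" not in kept.columns:
        kept["outcome"] = classify_outcome(
            disp, diag, kept["patient_id"], rules).to_numpy()

    # Covariate flags: columns take precedence; else derive from raw records
    # via rules.covariate_codes; else zero-fill with a warning.
    missing = [c for c in BINARY_COVARIATES if c not in kept.columns]
    derived, zero_filled = [], []
    for cov in missing:
        if cov in rules.covariate_codes:
            table_name, prefixes = rules.covariate_codes[cov]
            table = {"dispensations": disp, "diagnoses": diag,
                     "events": dataset.events}[table_name]
            code_col = "product" if table_name == "dispensations" else "code"
            day_col = ("days_relative_to_entry"
                       if "days_relative_to_entry" in table.columns
                       else "days_before_entry")
            if len(table):
                codes = table[code_col].astype(str).str.upper()
                m = pd.Series(False, index=table.index)
                for pref in prefixes:
                    m |= codes.str.startswith(pref.upper())
                if day_col == "days_relative_to_entry":
                    m &= table[day_col].between(-rules.washout_days, 0)
                hit_ids = set(table.loc[m, "patient_id"])
            else:
                hit_ids = set()
            kept[cov] = kept["patient_id"].isin(hit_ids).astype(np.int64)
            derived.append(cov)
        else:
            kept[cov] = 0
            zero_filled.append(cov)
    if zero_filled:
        warnings.warn(
            "covariate flags absent and not derivable, zero-filled: "
            + ", ".join(zero_filled), stacklevel=2)

    cohort_cols = (["patient_id", "exposure", "outcome", "age", "entry_year"]
                   + BINARY_COVARIATES)
    return kept[cohort_cols], report
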