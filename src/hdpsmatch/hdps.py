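"""High-dimensional propensity score engine.

Implements empirical covariate selection from coded claims data: the
one-year lookback is structured into six data dimensions; within each
dimension the most prevalent codes are kept (default 200 per dimension);
each code is expanded into up to three recurrence indicators (occurred at
least once / at least the median count / at least the 75th-percentile count
among patients with the code); candidates are ranked by the absolute log of
the Bross bias multiplier

    bias = (PC1 * (RR - 1) + 1) / (PC0 * (RR - 1) + 1)

where PC1/PC0 are the candidate's prevalences among exposed/unexposed and
RR >= 1 is the (inverted if needed) crude candidate-outcome risk ratio; the
top candidates (default 500) joined with a small forced covariate set
(demographics, poverty, entry year, utilization) form the hdPS design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .propensity import CovariateMatrix, ScoreSet, fit_propensity, year_indicators

__all__ = [
    "DIMENSION_LABELS",
    "DataDimension",
    "structure_dimensions",
    "select_prevalent_codes",
    "expand_recurrence",
    "bross_bias_multiplier",
    "rank_by_bias",
    "HdpsCovariateSelector",
    "build_hdps_design",
    "fit_hdps",
    "HDPS_FORCED_COLUMNS",
]

DIMENSION_LABELS: dict[int, str] = {
    1: "outpatient drugs",
    2: "claim procedure codes",
    3: "claim diagnostic codes",
    4: "physician specialty",
    5: "hospital inpatient procedures",
    6: "hospital inpatient diagnoses",
}

#: Forced (investigator) covariates of the hdPS model, besides entry-year
#: indicators: only demographics, poverty and utilization — no clinical flags.
HDPS_FORCED_COLUMNS: list[str] = [
    "male", "age", "poverty",
    "ge1_hospitalisation", "ge5_outpatient_visits", "ge5_distinct_drugs",
]

_LEVEL_ORDER = {"once": 0, "sporadic": 1, "frequent": 2}


@dataclass
class DataDimension:
    """Per-patient code-count table for one data dimension."""

    dimension_id: int
    label: str
    counts: pd.DataFrame  # index patient_id, columns codes, integer counts

    def __post_init__(self) -> None:
        if self.dimension_id not in DIMENSION_LABELS:
            raise ValueError(f"dimension_id {self.dimension_id} outside 1..6")
        if len(self.counts) and (self.counts.to_numpy() < 0).any():
            raise ValueError("negative code counts")


def structure_dimensions(dataset, cohort: pd.DataFrame) -> dict[int, DataDimension]:
    """Count lookback events per patient x code within each dimension.

    Only events with ``days_before_entry`` in 1..365 and patients in the
    cohort contribute; cohort patients with no events appear with zero
    counts. Events tagged with a dimension id outside 1..6 are an error.
    """
    events = dataset.events
    ids = pd.Index(cohort["patient_id"], name="patient_id")
    dims: dict[int, DataDimension] = {}
    if len(events):
        bad = set(events["dimension_id"].unique()) - set(DIMENSION_LABELS)
        if bad:
            raise ValueError(f"events carry dimension_id outside 1..6: {sorted(bad)}")
        window = events["days_before_entry"].between(1, 365)
        events = events.loc[window & events["patient_id"].isin(ids)]
    for d, label in DIMENSION_LABELS.items():
        sub = events.loc[events["dimension_id"] == d] if len(events) else events
        if len(sub):
            counts = (sub.groupby(["patient_id", "code"]).size()
                      .unstack(fill_value=0).reindex(ids, fill_value=0))
            counts.columns = counts.columns.astype(str)
        else:
            counts = pd.DataFrame(index=ids)
        dims[d] = DataDimension(dimension_id=d, label=label, counts=counts)
    return dims


def select_prevalent_codes(dimension: DataDimension, k: int = 200) -> list[str]:
    """Top-``k`` codes by prevalence, ranked by min(p, 1-p) descending.

    Prevalence p is the fraction of cohort patients with count >= 1.
    Codes present in no one or everyone carry no information and are never
    selected; ties break on the code string ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if dimension.counts.shape[1] == 0:
        return []
    p = (dimension.counts > 0).mean(axis=0)
    eligible = p[(p > 0.0) & (p < 1.0)]
    score = np.minimum(eligible, 1.0 - eligible)
    order = sorted(eligible.index, key=lambda c: (-score[c], c))
    return order[:k]


def expand_recurrence(counts: pd.Series, code: str) -> list[tuple[str, str, int]]:
    """Recurrence indicators for one code: (code, level, threshold) triples.

    Thresholds are nearest-rank quantiles of the counts among patients with
    at least one occurrence: once = 1, sporadic = median, frequent = 75th
    percentile. Indicators with identical thresholds collapse to the
    lowest level (distinct columns only).
    """
    nz = np.sort(counts.to_numpy()[counts.to_numpy() > 0])
    if nz.size == 0:
        return []
    med = int(nz[int(np.ceil(0.5 * nz.size)) - 1])
    q75 = int(nz[int(np.ceil(0.75 * nz.size)) - 1])
    out: list[tuple[str, str, int]] = []
    seen: set[int] = set()
    for level, thr in [("once", 1), ("sporadic", med), ("frequent", q75)]:
        if thr not in seen:
            out.append((code, level, thr))
            seen.add(thr)
    return out


def bross_bias_multiplier(pc1: float, pc0: float, rr_cd: float) -> float:
    """Multiplicative confounding bias of a binary covariate (Bross)."""
    if rr_cd < 1.0:
        raise ValueError("rr_cd must be >= 1 (invert before calling)")
    return (pc1 * (rr_cd - 1.0) + 1.0) / (pc0 * (rr_cd - 1.0) + 1.0)


def rank_by_bias(candidates: pd.DataFrame, values: np.ndarray,
                 exposure: np.ndarray, outcome: np.ndarray,
                 n_select: int = 500, zero_cell: str = "zero") -> pd.DataFrame:
    """Rank candidate covariates by |log Bross bias| and flag the top ones.

    ``candidates`` has one row per candidate (dimension_id, code, level,
    threshold); ``values`` is the aligned n_patients x n_candidates binary
    matrix. Candidates with an undefined risk ratio (a zero margin in the
    candidate-by-outcome table) score 0 under ``zero_cell="zero"`` or get a
    0.5 continuity correction under ``zero_cell="continuity"``. Ties break
    on (dimension_id, code, level) ascending; the top ``n_select`` distinct
    columns are flagged selected.
    """
    if zero_cell not in ("zero", "continuity"):
        raise ValueError("zero_cell must be 'zero' or 'continuity'")
    exposure = np.asarray(exposure, dtype=bool)
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or not outcome.any():
        raise ValueError("need at least one case and one non-case")
    out = candidates.copy().reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("no candidate covariates; empty selection", stacklevel=2)
        for col in ("prevalence", "pc1", "pc0", "rr_cd", "bias_mult", "abs_log_bias"):
            out[col] = pd.Series(dtype=float)
        out["selected"] = pd.Series(dtype=bool)
        return out
    V = np.asarray(values, dtype=bool)
    n1, n0 = int(exposure.sum()), int((~exposure).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both exposure groups to rank candidates")
    out["prevalence"] = V.mean(axis=0)
    out["pc1"] = V[exposure].sum(axis=0) / n1
    out["pc0"] = V[~exposure].sum(axis=0) / n0

    c1 = V.sum(axis=0).astype(float)              # patients with covariate
    c0 = len(outcome) - c1
    y1 = (V & outcome[:, None]).sum(axis=0).astype(float)   # cases among them
    y0 = outcome.sum() - y1
    if zero_cell == "continuity":
        zero = (c1 == 0) | (c0 == 0) | (y1 == 0) | (y0 == 0)
        y1 = np.where(zero, y1 + 0.5, y1)
        y0 = np.where(zero, y0 + 0.5, y0)
        c1 = np.where(zero, c1 + 1.0, c1)
        c0 = np.where(zero, c0 + 1.0, c0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = (y1 / c1) / (y0 / c0)
    undefined = ~np.isfinite(rr) | (rr <= 0.0)
    rr = np.where(undefined, np.nan, rr)
    rr = np.where(rr < 1.0, 1.0 / rr, rr)         # invert toward >= 1
    bias = np.where(
        np.isnan(rr), 1.0,
        (out["pc1"].to_numpy() * (rr - 1.0) + 1.0)
        / (out["pc0"].to_numpy() * (rr - 1.0) + 1.0))
    out["rr_cd"] = rr
    out["bias_mult"] = bias
    out["abs_log_bias"] = np.abs(np.log(bias))
    out.loc[np.isnan(rr), "abs_log_bias"] = 0.0

    out["_level_ord"] = out["level"].map(_LEVEL_ORDER)
    out = out.sort_values(
        by=["abs_log_bias", "dimension_id", "code", "_level_ord"],
        ascending=[False, True, True, True], kind="mergesort",
    ).drop(columns="_level_ord").reset_index(drop=True)
    out["selected"] = np.arange(len(out)) < n_select
    return out


class HdpsCovariateSelector(BaseEstimator, TransformerMixin):
    """Empirical covariate selection for the hdPS (scikit-learn style).

    Parameters
    ----------
    n_prevalent:
        Codes kept per dimension by the prevalence screen.
    n_select:
        Empirical covariates kept by the bias ranking (distinct columns,
        counted after duplicate-threshold collapse).
    zero_cell:
        Handling of candidates with a zero margin in the candidate-outcome
        table: ``"zero"`` ranks them last, ``"continuity"`` applies a 0.5
        correction.

    Attributes
    ----------
    candidates_ : pd.DataFrame
        All candidates with prevalences, risk ratio, bias multiplier,
        |log bias| and the selection flag, in rank order.
    selected_ : pd.DataFrame
        The selected subset of ``candidates_``.
    """

    def __init__(self, n_prevalent: int = 200, n_select: int = 500,
                 zero_cell: str = "zero"):
        self.n_prevalent = n_prevalent
        self.n_select = n_select
        self.zero_cell = zero_cell

    def fit(self, dimensions: dict[int, DataDimension], exposure, outcome
            ) -> "HdpsCovariateSelector":
        rows, cols = [], []
        for d in sorted(dimensions):
            dim = dimensions[d]
            for code in select_prevalent_codes(dim, self.n_prevalent):
                counts = dim.counts[code]
                for code_, level, thr in expand_recurrence(counts, code):
                    rows.append({"dimension_id": d, "code": code_,
                                 "level": level, "threshold": thr})
                    cols.append((counts.to_numpy() >= thr))
        candidates = pd.DataFrame(rows, columns=["dimension_id", "code",
                                                 "level", "threshold"])
        values = (np.column_stack(cols) if cols
                  else np.empty((len(next(iter(dimensions.values())).counts), 0), bool))
        self.candidates_ = rank_by_bias(
            candidates, values, np.asarray(exposure), np.asarray(outcome),
            n_select=self.n_select, zero_cell=self.zero_cell)
        self.selected_ = self.candidates_.loc[self.candidates_["selected"]]
        return self

    def transform(self, dimensions: dict[int, DataDimension]) -> pd.DataFrame:
        """Binary matrix of the selected empirical covariates."""
        index = next(iter(dimensions.values())).counts.index
        data = {}
        for row in self.selected_.itertuples(index=False):
            name = f"d{row.dimension_id}_{row.code}_{row.level}"
            dim = dimensions[row.dimension_id]
            if row.code in dim.counts.columns:
                col = (dim.counts[row.code] >= row.threshold).astype(np.int64)
            else:
                col = pd.Series(0, index=index, dtype=np.int64)
            data[name] = col.to_numpy()
        return pd.DataFrame(data, index=index)


def build_hdps_design(selected: pd.DataFrame, cohort: pd.DataFrame) -> CovariateMatrix:
    """Forced covariates + selected empirical binaries -> hdPS design.

    Forced set: sex, age, poverty, entry-year indicators and the three
    utilization flags; no investigator clinical covariates. Empirical
    columns colliding with a forced name are suffixed, not merged.
    """
    missing = [c for c in HDPS_FORCED_COLUMNS + ["entry_year", "exposure"]
               if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing covariate column(s): {missing}")
    forced = cohort[HDPS_FORCED_COLUMNS].copy()
    forced = pd.concat([forced, year_indicators(cohort["entry_year"])], axis=1)
    forced.index = pd.Index(cohort["patient_id"], name="patient_id")
    emp = selected.copy()
    emp.index = forced.index
    rename = {c: f"{c}_emp" for c in emp.columns if c in forced.columns}
    if rename:
        emp = emp.rename(columns=rename)
    frame = pd.concat([forced, emp], axis=1)
    exposure = (cohort["exposure"] == "high").to_numpy(dtype=np.int64)
    constant = [c for c in frame.columns if frame[c].nunique() <= 1]
    return CovariateMatrix(frame=frame, exposure=exposure, constant_columns=constant)


def fit_hdps(design: CovariateMatrix | pd.DataFrame, exposure=None,
             **estimator_kwargs) -> ScoreSet:
    """Fit the hdPS (same ML logistic estimator as the traditional PS)."""
    return fit_propensity(design, exposure, model_label="hdPS", **estimator_kwargs)
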