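"""Propensity-score estimation by maximum-likelihood logistic regression.

The propensity score is the conditional probability of high-potency
initiation given covariates, e(x) = P(T=1 | X=x), estimated by an
unpenalized logistic regression. The same estimator backs the traditional
(investigator-specified) PS and the hdPS — they differ only in the design
matrix fed to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "CovariateMatrix",
    "ScoreSet",
    "SeparationError",
    "LogisticPropensityModel",
    "build_ps_design",
    "fit_propensity",
    "PS_NONYEAR_COLUMNS",
]

#: Investigator covariate list (non-year columns): demographics and poverty,
#: utilization, drug dispensations (incl. acetaminophen) and comorbidities.
PS_NONYEAR_COLUMNS: list[str] = [
    "male", "age", "poverty",
    "ge1_hospitalisation", "ge5_outpatient_visits", "ge5_distinct_drugs",
    "loop_diuretics", "acetaminophen", "calcium_blockers", "beta_blockers",
    "arb", "acei",
    "hypertension", "hypercholesterolemia", "mi", "stroke", "pvd", "chf",
    "cabg", "pci",
]


class SeparationError(ValueError):
    """Perfect separation in the logistic fit; trim or simplify the design."""


@dataclass
class CovariateMatrix:
    """A score-model design: rows align with ``exposure``.

    Binary indicator columns plus continuous age; constant columns are
    flagged (and dropped with a warning at fit time).
    """

    frame: pd.DataFrame           # indexed by patient_id
    exposure: np.ndarray          # 0/1, 1 = high potency
    constant_columns: list[str]

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("design contains missing values")
        if len(self.frame) != len(self.exposure):
            raise ValueError("design and exposure lengths differ")


@dataclass
class ScoreSet:
    """Fitted per-patient scores plus model metadata."""

    patient_id: np.ndarray
    score: np.ndarray
    logit_score: np.ndarray
    coefficients: dict[str, float]
    converged: bool
    model_label: str = "PS"

    def __post_init__(self) -> None:
        if np.any(self.score <= 0.0) or np.any(self.score >= 1.0):
            raise ValueError("scores must lie strictly in (0, 1)")
        if not np.allclose(self.score, expit(self.logit_score), atol=1e-12):
            raise ValueError("score and logit_score inconsistent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "score": self.score,
            "logit_score": self.logit_score,
            "model_label": self.model_label,
        })


def year_indicators(entry_year: pd.Series) -> pd.DataFrame:
    """Entry-year dummies with the earliest year present as reference."""
    years = np.sort(entry_year.unique())
    out = {}
    for y in years[1:]:
        out[f"year_{y}"] = (entry_year == y).astype(np.int64)
    return pd.DataFrame(out, index=entry_year.index)


def build_ps_design(cohort: pd.DataFrame) -> CovariateMatrix:
    """Assemble the investigator-specified PS design from the cohort."""
    missing = [c for c in PS_NONYEAR_COLUMNS + ["entry_year", "exposure"]
               if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing covariate column(s): {missing}")
    frame = cohort[PS_NONYEAR_COLUMNS].copy()
    frame = pd.concat([frame, year_indicators(cohort["entry_year"])], axis=1)
    frame.index = pd.Index(cohort["patient_id"], name="patient_id")
    binary_cols = [c for c in frame.columns if c != "age"]
    bad = [c for c in binary_cols if not frame[c].isin([0, 1]).all()]
    if bad:
        raise ValueError(f"non-binary values in indicator column(s): {bad}")
    exposure = (cohort["exposure"] == "high").to_numpy(dtype=np.int64)
    constant = [c for c in frame.columns if frame[c].nunique() <= 1]
    return CovariateMatrix(frame=frame, exposure=exposure, constant_columns=constant)


class LogisticPropensityModel(BaseEstimator):
    """Maximum-likelihood logistic propensity model (scikit-learn style).

    Parameters
    ----------
    tol:
        Newton convergence tolerance (parameter change).
    max_iter:
        Maximum Newton iterations.
    drop_collinear:
        Drop constant and linearly dependent columns (with a warning)
        instead of failing; useful for small cohorts with empty strata.
    model_label:
        Label propagated into the resulting :class:`ScoreSet`.

    Attributes
    ----------
    coef_ : pd.Series
        Fitted coefficients for the retained columns.
    intercept_ : float
    converged_ : bool
    dropped_columns_ : list[str]
    n_iter_ : int
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100,
                 drop_collinear: bool = True, model_label: str = "PS"):
        self.tol = tol
        self.max_iter = max_iter
        self.drop_collinear = drop_collinear
        self.model_label = model_label

    # -- sklearn API ------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "LogisticPropensityModel":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=np.int64)
        if X.isna().any().any():
            raise ValueError("design contains missing values")
        if y.min() == y.max():
            raise ValueError("need at least one exposed and one unexposed patient")

        dropped: list[str] = []
        keep = X.columns.tolist()
        constant = [c for c in keep if X[c].nunique() <= 1]
        if constant:
            if not self.drop_collinear:
                raise ValueError(f"constant column(s) in design: {constant}")
            dropped += constant
            keep = [c for c in keep if c not in constant]
        Xv = X[keep].to_numpy(dtype=float)
        if keep:
            # rank check via pivoted QR on the centered design
            q, r, piv = scipy.linalg.qr(Xv - Xv.mean(0), mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            rank = int((diag > max(Xv.shape) * np.finfo(float).eps * diag[0]).sum()) \
                if diag.size and diag[0] > 0 else 0
            if rank < len(keep):
                extra = [keep[i] for i in piv[rank:]]
                if not self.drop_collinear:
                    raise ValueError(f"collinear column(s) in design: {extra}")
                dropped += extra
                keep = [c for c in keep if c not in extra]
                Xv = X[keep].to_numpy(dtype=float)
        if dropped:
            warnings.warn(f"dropped constant/collinear column(s): {dropped}",
                          stacklevel=2)

        design = sm.add_constant(Xv, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, design).fit(
                    method="newton", maxiter=self.max_iter, tol=self.tol, disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning):
            culprit = self._find_separating_column(X[keep], y)
            hint = f" (column {culprit!r})" if culprit else ""
            raise SeparationError(
                "perfect separation detected in the logistic fit"
                f"{hint}; consider trimming the cohort or simplifying the design"
            ) from None

        self.columns_ = keep
        self.dropped_columns_ = dropped
        self.intercept_ = float(res.params[0])
        self.coef_ = pd.Series(res.params[1:], index=keep)
        self.converged_ = bool(res.mle_retvals.get("converged", False))
        self.n_iter_ = int(res.mle_retvals.get("iterations", 0))
        if not self.converged_:
            warnings.warn("logistic fit did not converge", stacklevel=2)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor (logit of the score)."""
        X = pd.DataFrame(X)
        return self.intercept_ + X[self.columns_].to_numpy(dtype=float) @ self.coef_.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(np.int64)

    # -- domain surface ---------------------------------------------------
    def score_set(self, X: pd.DataFrame, patient_id=None) -> ScoreSet:
        lin = self.decision_function(X)
        if patient_id is None:
            patient_id = np.asarray(pd.DataFrame(X).index)
        coefs = {"const": self.intercept_, **self.coef_.to_dict()}
        return ScoreSet(
            patient_id=np.asarray(patient_id),
            score=expit(lin),
            logit_score=lin,
            coefficients=coefs,
            converged=self.converged_,
            model_label=self.model_label,
        )

    @staticmethod
    def _find_separating_column(X: pd.DataFrame, y: np.ndarray) -> str | None:
        for c in X.columns:
            v = X[c].to_numpy()
            if set(np.unique(v)) <= {0, 1}:
                for level in (0, 1):
                    sub = y[v == level]
                    if len(sub) and len(sub) < len(y) and sub.min() == sub.max():
                        other = y[v != level]
                        if len(other) and other.min() == other.max() \
                                and other[0] != sub[0]:
                            return c
        return None


def fit_propensity(design: CovariateMatrix | pd.DataFrame, exposure=None,
                   model_label: str = "PS", **estimator_kwargs) -> ScoreSet:
    """Fit the propensity model and return per-patient scores.

    Accepts either a :class:`CovariateMatrix` (exposure embedded) or a plain
    design frame plus an exposure vector. The ML score equation guarantees
    the mean fitted score equals the exposed fraction; this is asserted to
    1e-6 after a converged fit.
    """
    if isinstance(design, CovariateMatrix):
        frame, exposure = design.frame, design.exposure
    else:
        frame = pd.DataFrame(design)
        if exposure is None:
            raise ValueError("exposure required when design is a plain frame")
        exposure = np.asarray(exposure)
    model = LogisticPropensityModel(model_label=model_label, **estimator_kwargs)
    model.fit(frame, exposure)
    scores = model.score_set(frame)
    if model.converged_:
        imbalance = abs(float(scores.score.mean()) - float(np.mean(exposure)))
        if imbalance > 1e-6:
            raise RuntimeError(
                f"score equation violated (|mean score - exposed fraction| = {imbalance:.2e})")
    return scores
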