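"""Synthetic medico-administrative claims generator with known ground truth.

The generator emulates the structure of a new-user statin cohort drawn from
provincial claims data: one row per patient with demographics and 1-year
lookback covariate flags, six "data dimensions" of sparse lookback codes
(outpatient drugs, procedure and diagnostic claims, physician specialty,
inpatient procedures and diagnoses), a dispensation table carrying the index
statin, and a diagnosis table carrying post-entry diabetes records.

Ground truth is fully configurable: baseline covariate prevalences, the
covariate -> treatment and covariate -> outcome log-odds, the conditional
treatment-outcome log odds ratio, and the strength with which lookback codes
track the covariates and a latent illness-severity frailty. Defaults are
parameterized from the lower-potency column of the benchmark cohort's
baseline table, with treatment log-odds backed out of the marginal
covariate-by-potency odds ratios of the same table, so the default full
cohort shows imbalance of realistic magnitude.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .covariates import BINARY_COVARIATES

__all__ = [
    "SimulationConfig",
    "ClaimsDataset",
    "calibrate_intercept",
    "generate_population",
    "DEFAULT_PREVALENCES",
    "DEFAULT_TREATMENT_LOGODDS",
    "DEFAULT_OUTCOME_LOGODDS",
]

#: Baseline covariate prevalences (lower-potency column of the benchmark
#: baseline table). Poverty and acetaminophen are not printed there; the
#: values below are realistic for a publicly insured population aged 40+.
DEFAULT_PREVALENCES: dict[str, float] = {
    "male": 0.446,
    "poverty": 0.35,
    "ge5_outpatient_visits": 0.643,
    "ge1_hospitalisation": 0.225,
    "ge5_distinct_drugs": 0.571,
    "mi": 0.057,
    "stroke": 0.027,
    "hypertension": 0.417,
    "hypercholesterolemia": 0.334,
    "pvd": 0.021,
    "chf": 0.043,
    "cabg": 0.014,
    "pci": 0.029,
    "loop_diuretics": 0.063,
    "calcium_blockers": 0.244,
    "beta_blockers": 0.293,
    "arb": 0.135,
    "acei": 0.198,
    "acetaminophen": 0.30,
}

#: Covariate -> treatment log-odds, backed out of the marginal odds ratios
#: between each baseline flag and high-potency initiation in the benchmark
#: baseline table (log of OR_high/lower). ``age`` is per standardized
#: 10-year unit. Poverty/acetaminophen (not printed) get small effects.
DEFAULT_TREATMENT_LOGODDS: dict[str, float] = {
    "age": -0.11,
    "male": 0.365,
    "poverty": -0.10,
    "ge5_outpatient_visits": -0.372,
    "ge1_hospitalisation": 0.524,
    "ge5_distinct_drugs": 0.148,
    "mi": 0.957,
    "stroke": 0.381,
    "hypertension": 0.049,
    "hypercholesterolemia": 0.018,
    "pvd": 0.137,
    "chf": 0.403,
    "cabg": 0.506,
    "pci": 1.326,
    "loop_diuretics": 0.158,
    "calcium_blockers": -0.072,
    "beta_blockers": 0.275,
    "arb": 0.354,
    "acei": 0.348,
    "acetaminophen": 0.05,
}

#: Covariate -> outcome (incident diabetes within two years) log-odds.
#: Moderate clinical risk-factor effects (ORs ~1.1-1.5).
DEFAULT_OUTCOME_LOGODDS: dict[str, float] = {
    "age": 0.25,
    "male": 0.15,
    "poverty": 0.20,
    "ge5_outpatient_visits": 0.30,
    "ge1_hospitalisation": 0.30,
    "ge5_distinct_drugs": 0.40,
    "mi": 0.30,
    "stroke": 0.20,
    "hypertension": 0.40,
    "hypercholesterolemia": 0.30,
    "pvd": 0.20,
    "chf": 0.40,
    "cabg": 0.20,
    "pci": 0.20,
    "loop_diuretics": 0.30,
    "calcium_blockers": 0.20,
    "beta_blockers": 0.30,
    "arb": 0.20,
    "acei": 0.20,
    "acetaminophen": 0.10,
}

_HIGH_POTENCY_INDEX = [
    ("rosuvastatin", 10.0),
    ("rosuvastatin", 20.0),
    ("rosuvastatin", 40.0),
    ("atorvastatin", 20.0),
    ("atorvastatin", 40.0),
    ("atorvastatin", 80.0),
    ("simvastatin", 40.0),
    ("simvastatin", 80.0),
]
_LOWER_POTENCY_INDEX = [
    ("rosuvastatin", 5.0),
    ("atorvastatin", 10.0),
    ("simvastatin", 10.0),
    ("simvastatin", 20.0),
    ("pravastatin", 20.0),
    ("pravastatin", 40.0),
    ("fluvastatin", 40.0),
    ("fluvastatin", 80.0),
    ("lovastatin", 20.0),
    ("lovastatin", 40.0),
]

#: Characteristics that can "emit" claims codes (all binary table rows).
_CODE_PARENTS = [c for c in BINARY_COVARIATES if c not in ("poverty", "acetaminophen")]

#: Clinical covariates recorded ("definitionally") in a natural dimension:
#: drug dispensations in the outpatient-drug dimension, diagnoses in the
#: claim-diagnosis dimension, revascularisations in inpatient procedures.
#: Lookback covariate flags in real claims data are derived from these very
#: codes, so the first codes of those dimensions track their covariate with
#: near-perfect sensitivity and specificity.
_DEFINITIONAL_PARENTS: dict[int, list[str]] = {
    1: ["loop_diuretics", "calcium_blockers", "beta_blockers", "arb", "acei"],
    3: ["mi", "stroke", "hypertension", "hypercholesterolemia", "pvd", "chf"],
    5: ["cabg", "pci"],
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic claims generator.

    Parameters
    ----------
    n_patients:
        Cohort size (>= 2).
    seed:
        Seed for the single pseudo-random stream; draws happen in a fixed,
        documented order so a seed fully determines the dataset.
    baseline_prevalences:
        Marginal probability of each binary covariate.
    confounder_treatment_logodds, confounder_outcome_logodds:
        Log-odds of each covariate in the treatment (high-potency initiation)
        and outcome (2-year diabetes) models. The key ``age`` refers to age
        standardized per 10 years.
    true_treatment_logodds:
        Log of the conditional treatment-outcome odds ratio (the estimand).
    target_exposed_fraction, target_outcome_fraction:
        Marginal rates the model intercepts are calibrated to.
    n_codes_per_dimension:
        Number of distinct codes simulated in each of the six dimensions.
    code_confounder_loading:
        In [0, 1]; scales how strongly "loaded" codes track their parent
        covariate and the latent frailty. 0 makes every code pure noise.
    frailty_covariate_logodds:
        Log-odds of the standard-normal latent frailty in each covariate
        draw (covariates are independent given frailty).
    frailty_treatment_logodds, frailty_outcome_logodds:
        Direct frailty effects on treatment/outcome; nonzero values create
        unmeasured confounding that no score model can fully remove.
    """

    n_patients: int = 50_000
    seed: int = 0
    baseline_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    confounder_treatment_logodds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_LOGODDS))
    confounder_outcome_logodds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_LOGODDS))
    true_treatment_logodds: float = 0.0
    target_exposed_fraction: float = 0.344
    target_outcome_fraction: float = 0.032
    n_codes_per_dimension: dict[int, int] = field(
        default_factory=lambda: {d: 50 for d in range(1, 7)})
    code_confounder_loading: float = 0.9
    frailty_covariate_logodds: float = 0.6
    frailty_treatment_logodds: float = 0.0
    frailty_outcome_logodds: float = 0.0
    age_mean: float = 65.2
    age_sd: float = 11.0
    age_min: float = 40.0
    entry_year_range: tuple[int, int] = (1998, 2010)

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name, p in self.baseline_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]: {p}")
        for frac, label in [
            (self.target_exposed_fraction, "target_exposed_fraction"),
            (self.target_outcome_fraction, "target_outcome_fraction"),
        ]:
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{label} must be in (0, 1), got {frac}")
        if not 0.0 <= self.code_confounder_loading <= 1.0:
            raise ValueError("code_confounder_loading must be in [0, 1]")
        for d, k in self.n_codes_per_dimension.items():
            if d not in range(1, 7):
                raise ValueError(f"dimension id {d} outside 1..6")
            if k < 1:
                raise ValueError(f"n_codes_per_dimension[{d}] must be >= 1")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if self.entry_year_range[0] > self.entry_year_range[1]:
            raise ValueError("entry_year_range reversed")

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass
class ClaimsDataset:
    """Long-format claims tables.

    ``patients`` has one row per patient (demographics, covariate flags,
    exposure arm, outcome flag and, for synthetic data, the latent frailty).
    ``events`` carries dimension-coded lookback events (``days_before_entry``
    in 1..365), ``dispensations`` drug claims relative to entry day 0, and
    ``diagnoses`` dated diagnosis codes relative to entry.
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    dispensations: pd.DataFrame
    diagnoses: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["patient_id", "code", "days_relative_to_entry"]))

    def validate(self) -> None:
        pid = self.patients["patient_id"]
        if pid.duplicated().any():
            raise ValueError("patient_id not unique in patients table")
        known = set(pid)
        for name, table, col in [
            ("events", self.events, "patient_id"),
            ("dispensations", self.dispensations, "patient_id"),
            ("diagnoses", self.diagnoses, "patient_id"),
        ]:
            if len(table) and not set(table[col]).issubset(known):
                raise ValueError(f"{name} references unknown patient_id")
        if len(self.events):
            days = self.events["days_before_entry"]
            if (days < 1).any() or (days > 365).any():
                raise ValueError("events days_before_entry outside 1..365")

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(directory / "patients.csv", index=False)
        self.events.to_csv(directory / "events.csv", index=False)
        self.dispensations.to_csv(directory / "dispensations.csv", index=False)
        self.diagnoses.to_csv(directory / "diagnoses.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "ClaimsDataset":
        directory = Path(directory)
        kwargs = {}
        diag_path = directory / "diagnoses.csv"
        if diag_path.exists():
            kwargs["diagnoses"] = pd.read_csv(diag_path)
        return cls(
            patients=pd.read_csv(directory / "patients.csv"),
            events=pd.read_csv(directory / "events.csv"),
            dispensations=pd.read_csv(directory / "dispensations.csv"),
            **kwargs,
        )


def calibrate_intercept(linear_terms: np.ndarray, target_fraction: float) -> float:
    """Intercept ``b`` with ``mean(expit(b + linear_terms)) == target_fraction``.

    Solved by bisection on a bracket that is widened until the objective
    changes sign; the returned intercept reproduces the target fraction to
    within 1e-6 (the objective is continuous and strictly increasing in
    ``b``, so bisection converges unconditionally once bracketed).
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    terms = np.asarray(linear_terms, dtype=float)
    if not np.all(np.isfinite(terms)):
        raise ValueError("linear_terms contain non-finite values")

    def f(b: float) -> float:
        return float(np.mean(expit(b + terms))) - target_fraction

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(lo) <= 0.0 <= f(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise RuntimeError(
            f"intercept calibration failed to bracket target {target_fraction}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < 1e-9 or hi - lo < 1e-13:
            return mid
        if fm < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _logodds_vector(table: dict[str, float], name: str) -> float:
    return float(table.get(name, 0.0))


def generate_population(config: SimulationConfig) -> ClaimsDataset:
    """Draw a complete synthetic claims dataset.

    Deterministic given ``config.seed``. Draw order: latent frailty, age,
    entry year, binary covariates (canonical order), exposure, outcome,
    index-statin product, per-dimension code parameters and events
    (dimensions 1..6 in order), post-entry outcome records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    frailty = rng.standard_normal(n)

    a, b = (config.age_min - config.age_mean) / config.age_sd, np.inf
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                        size=n, random_state=rng)
    age_std = (age - 65.0) / 10.0

    y0, y1 = config.entry_year_range
    entry_year = rng.integers(y0, y1 + 1, size=n)

    gamma_f = config.frailty_covariate_logodds
    flags: dict[str, np.ndarray] = {}
    for name in BINARY_COVARIATES:
        p = config.baseline_prevalences.get(name, 0.0)
        if p <= 0.0:
            flags[name] = np.zeros(n, dtype=np.int64)
            continue
        if p >= 1.0:
            flags[name] = np.ones(n, dtype=np.int64)
            continue
        intercept = calibrate_intercept(gamma_f * frailty, p)
        flags[name] = (rng.random(n) < expit(intercept + gamma_f * frailty)).astype(np.int64)

    t_term = config.frailty_treatment_logodds * frailty \
        + _logodds_vector(config.confounder_treatment_logodds, "age") * age_std
    for name in BINARY_COVARIATES:
        beta = _logodds_vector(config.confounder_treatment_logodds, name)
        if beta:
            t_term = t_term + beta * flags[name]
    b0 = calibrate_intercept(t_term, config.target_exposed_fraction)
    exposed = rng.random(n) < expit(b0 + t_term)

    o_term = config.frailty_outcome_logodds * frailty \
        + _logodds_vector(config.confounder_outcome_logodds, "age") * age_std \
        + config.true_treatment_logodds * exposed
    for name in BINARY_COVARIATES:
        gamma = _logodds_vector(config.confounder_outcome_logodds, name)
        if gamma:
            o_term = o_term + gamma * flags[name]
    c0 = calibrate_intercept(o_term, config.target_outcome_fraction)
    outcome = (rng.random(n) < expit(c0 + o_term)).astype(np.int64)

    patient_id = np.arange(1, n + 1, dtype=np.int64)
    patients = pd.DataFrame({
        "patient_id": patient_id,
        "age": age,
        "entry_year": entry_year,
        "exposure": np.where(exposed, "high", "lower"),
        "outcome": outcome,
        "latent_frailty": frailty,
    })
    for name in BINARY_COVARIATES:
        patients[name] = flags[name]

    # Index statin dispensation at entry (day 0), consistent with the arm.
    hi_idx = rng.integers(0, len(_HIGH_POTENCY_INDEX), size=n)
    lo_idx = rng.integers(0, len(_LOWER_POTENCY_INDEX), size=n)
    hi_prod = np.array([p for p, _ in _HIGH_POTENCY_INDEX])
    hi_dose = np.array([d for _, d in _HIGH_POTENCY_INDEX])
    lo_prod = np.array([p for p, _ in _LOWER_POTENCY_INDEX])
    lo_dose = np.array([d for _, d in _LOWER_POTENCY_INDEX])
    product = np.where(exposed, hi_prod[hi_idx], lo_prod[lo_idx])
    dose = np.where(exposed, hi_dose[hi_idx], lo_dose[lo_idx])
    dispensations = pd.DataFrame({
        "patient_id": patient_id,
        "product": product,
        "daily_dose": dose,
        "days_relative_to_entry": np.zeros(n, dtype=np.int64),
    })

    events = _draw_events(config, rng, patient_id, flags, frailty)

    # Post-entry diabetes records for cases: half dispensation (ATC A10),
    # half diagnosis, anywhere in the 2-year follow-up window (days 1..730).
    case_ids = patient_id[outcome == 1]
    n_cases = len(case_ids)
    via_drug = rng.random(n_cases) < 0.5
    case_days = rng.integers(1, 731, size=n_cases)
    drug_rows = pd.DataFrame({
        "patient_id": case_ids[via_drug],
        "product": "A10_metformin",
        "daily_dose": 500.0,
        "days_relative_to_entry": case_days[via_drug],
    })
    dispensations = pd.concat([dispensations, drug_rows], ignore_index=True)
    diagnoses = pd.DataFrame({
        "patient_id": case_ids[~via_drug],
        "code": "E11.9",
        "days_relative_to_entry": case_days[~via_drug],
    })

    dataset = ClaimsDataset(patients=patients, events=events,
                            dispensations=dispensations, diagnoses=diagnoses)
    dataset.validate()
    return dataset


def _draw_events(config: SimulationConfig, rng: np.random.Generator,
                 patient_id: np.ndarray, flags: dict[str, np.ndarray],
                 frailty: np.ndarray) -> pd.DataFrame:
    """Lookback events for the six data dimensions.

    Codes come in three kinds. "Definitional" codes (the first codes of the
    dimensions in :data:`_DEFINITIONAL_PARENTS`) record their covariate the
    way claims-derived flags are defined from claims: sensitivity 0.98,
    false-positive rate 0.002. Remaining even-indexed codes are ordinary
    "loaded" proxies with a low rate without their parent covariate
    (specificity noise, log-uniform on 0.002..0.02) and a moderate rate
    with it (sensitivity, uniform on 0.3..0.9), plus a mild frailty
    modulation. Odd-indexed codes are pure noise with log-uniform base
    rates. ``code_confounder_loading`` interpolates every parent effect
    between 0 (pure noise) and the full sensitivity. Counts given
    occurrence are geometric on {1, 2, ...} (zero-truncated), which yields
    the skewed once/sporadic/frequent recurrence profile.
    """
    n = len(patient_id)
    loading = config.code_confounder_loading
    w_f = 0.8 * loading
    frames: list[pd.DataFrame] = []
    for dim in range(1, 7):
        k = config.n_codes_per_dimension.get(dim, 0)
        if k == 0:
            continue
        base = np.exp(rng.uniform(math.log(0.01), math.log(0.25), size=k))
        fp_rate = np.exp(rng.uniform(math.log(0.002), math.log(0.02), size=k))
        sens = rng.uniform(0.3, 0.9, size=k)
        codes = np.array([f"D{dim}_{j:03d}" for j in range(k)])
        logit_p = np.tile(logit(base), (n, 1))
        definitional = _DEFINITIONAL_PARENTS.get(dim, [])[:k]
        for j, parent in enumerate(definitional):
            logit_p[:, j] = (
                logit(0.002)
                + loading * (logit(0.98) - logit(0.002)) * flags[parent]
                + w_f * frailty)
        for j in range(len(definitional), k):
            if (j - len(definitional)) % 2 != 0:
                continue  # noise code
            parent = _CODE_PARENTS[(j // 2 + (dim - 1) * 3) % len(_CODE_PARENTS)]
            logit_p[:, j] = (
                logit(fp_rate[j])
                + loading * (logit(sens[j]) - logit(fp_rate[j])) * flags[parent]
                + w_f * frailty)
        occur = rng.random((n, k)) < expit(logit_p)
        pat_idx, code_idx = np.nonzero(occur)
        if len(pat_idx) == 0:
            continue
        counts = rng.geometric(0.55, size=len(pat_idx))
        rep_pat = np.repeat(patient_id[pat_idx], counts)
        rep_code = np.repeat(codes[code_idx], counts)
        days = rng.integers(1, 366, size=len(rep_pat))
        frames.append(pd.DataFrame({
            "patient_id": rep_pat,
            "dimension_id": np.full(len(rep_pat), dim, dtype=np.int64),
            "code": rep_code,
            "days_before_entry": days,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "dimension_id", "code", "days_before_entry"])
    return pd.concat(frames, ignore_index=True)
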