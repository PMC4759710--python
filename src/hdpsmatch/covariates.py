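"""Canonical covariate vocabulary shared across the pipeline.

Names follow the investigator covariate list of the Quebec incident-statin
study design this package reimplements: demographics, one-year medical
resource utilization, drug-dispensation and comorbidity flags, all assessed
in the 365-day lookback before cohort entry.
"""

from __future__ import annotations

#: All binary patient-level covariates carried by the analytic cohort, in the
#: canonical draw/report order. ``male`` encodes sex (1 = male).
BINARY_COVARIATES: list[str] = [
    "male",
    "poverty",
    "ge5_outpatient_visits",
    "ge1_hospitalisation",
    "ge5_distinct_drugs",
    "mi",
    "stroke",
    "hypertension",
    "hypercholesterolemia",
    "pvd",
    "chf",
    "cabg",
    "pci",
    "loop_diuretics",
    "calcium_blockers",
    "beta_blockers",
    "arb",
    "acei",
    "acetaminophen",
]

#: The 18 characteristics examined in the balance tables, in fixed report
#: order (age first, then the binary flags). Poverty and acetaminophen are
#: score-model covariates but not balance-table rows.
TABLE1_CHARACTERISTICS: list[str] = [
    "age",
    "male",
    "ge5_outpatient_visits",
    "ge1_hospitalisation",
    "mi",
    "stroke",
    "hypertension",
    "hypercholesterolemia",
    "pvd",
    "chf",
    "cabg",
    "pci",
    "loop_diuretics",
    "calcium_blockers",
    "beta_blockers",
    "arb",
    "acei",
    "ge5_distinct_drugs",
]

#: Human-readable labels used in reports.
COVARIATE_LABELS: dict[str, str] = {
    "age": "Age",
    "male": "Male sex",
    "ge5_outpatient_visits": "At least 5 medical outpatient visits",
    "ge1_hospitalisation": "At least 1 hospitalisation",
    "mi": "Myocardial infarction",
    "stroke": "Stroke",
    "hypertension": "Hypertension",
    "hypercholesterolemia": "Hypercholesterolemia",
    "pvd": "Peripheral vascular disease",
    "chf": "Congestive heart failure",
    "cabg": "Coronary artery bypass graft",
    "pci": "Percutaneous coronary intervention",
    "loop_diuretics": "Dispensation of loop diuretics",
    "calcium_blockers": "Dispensation of calcium blockers",
    "beta_blockers": "Dispensation of beta-blockers",
    "arb": "Dispensation of angiotensin receptor blockers",
    "acei": "Dispensation of angiotensin converting enzyme inhibitors",
    "ge5_distinct_drugs": "At least 5 different drugs dispensed",
    "poverty": "Poverty-level status",
    "acetaminophen": "Dispensation of acetaminophen",
}
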