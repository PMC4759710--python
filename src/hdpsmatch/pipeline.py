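"""End-to-end comparison pipeline: simulate -> cohort -> PS and hdPS ->
trim + match -> balance tables and unadjusted odds ratios.

Produces a flow-chart count table (patients entering, trimmed and matched
per arm and per method), balance tables for the full cohort and both
matched sub-cohorts, a side-by-side ASDD comparison, and the three effect
estimates. All stages are deterministic given the simulation seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import apply_inclusion_exclusion
from .covariates import TABLE1_CHARACTERISTICS
from .diagnostics import EffectEstimate, balance_table, estimate_or, outcome_cells
from .hdps import (HdpsCovariateSelector, build_hdps_design, fit_hdps,
                   structure_dimensions)
from .matching import MatchedPairs, match_scores
from .propensity import ScoreSet, build_ps_design, fit_propensity
from .simulate import ClaimsDataset, SimulationConfig, generate_population

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]

_CSV_FLOAT = "%.10g"


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    exclusions: pd.DataFrame
    scores_ps: ScoreSet
    scores_hdps: ScoreSet
    match_ps: MatchedPairs
    match_hdps: MatchedPairs
    balance_full: pd.DataFrame
    balance_ps: pd.DataFrame
    balance_hdps: pd.DataFrame
    summary_full: dict
    summary_ps: dict
    summary_hdps: dict
    effects: dict[str, EffectEstimate]
    flowchart: pd.DataFrame
    asdd_comparison: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        """Write all report tables as CSV plus a markdown summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format=_CSV_FLOAT)
        self.cohort.to_csv(out / "cohort.csv", **kw)
        self.exclusions.to_csv(out / "exclusions.csv", **kw)
        self.scores_ps.to_frame().to_csv(out / "ps_scores.csv", **kw)
        self.scores_hdps.to_frame().to_csv(out / "hdps_scores.csv", **kw)
        self.match_ps.pairs.to_csv(out / "pairs_ps.csv", **kw)
        self.match_hdps.pairs.to_csv(out / "pairs_hdps.csv", **kw)
        self.balance_full.to_csv(out / "balance_full.csv", **kw)
        self.balance_ps.to_csv(out / "balance_ps.csv", **kw)
        self.balance_hdps.to_csv(out / "balance_hdps.csv", **kw)
        self.flowchart.to_csv(out / "flowchart.csv", **kw)
        self.asdd_comparison.to_csv(out / "asdd_comparison.csv", **kw)
        effects = pd.DataFrame([
            {"method": k, "odds_ratio": e.odds_ratio, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "cases_high": e.cells[0],
             "noncases_high": e.cells[1], "cases_lower": e.cells[2],
             "noncases_lower": e.cells[3],
             "continuity_corrected": e.continuity_corrected}
            for k, e in self.effects.items()
        ])
        effects.to_csv(out / "effects.csv", **kw)
        (out / "report.md").write_text(self._report_md())

    def _report_md(self) -> str:
        lines = ["# PS vs hdPS matching comparison", "", "## Flow chart", ""]
        lines.append(self.flowchart.to_string(index=False))
        lines += ["", "## Balance (mean ASDD over the 18 characteristics)", ""]
        for label, summ in [("Full cohort", self.summary_full),
                            ("PS-matched", self.summary_ps),
                            ("hdPS-matched", self.summary_hdps)]:
            lines.append(
                f"- {label}: mean {summ['mean_asdd']:.3f} "
                f"(range {summ['min_asdd']:.3f}-{summ['max_asdd']:.3f}), "
                f"{summ['n_unbalanced']} of {len(self.balance_full)} above 0.1")
        lines += ["", "## Odds ratios (2-year diabetes, high vs lower potency)", ""]
        for k, e in self.effects.items():
            lines.append(f"- {k}: OR {e.odds_ratio:.3f} "
                         f"(95% CI {e.ci_low:.3f}-{e.ci_high:.3f})")
        lines += ["", "## ASDD comparison", "", self.asdd_comparison.to_string(index=False), ""]
        return "\n".join(lines)


def _matched_cohort(cohort: pd.DataFrame, match: MatchedPairs) -> pd.DataFrame:
    ids = pd.concat([match.pairs["high_id"], match.pairs["lower_id"]])
    return cohort[cohort["patient_id"].isin(set(ids))]


def run_pipeline(config: SimulationConfig | None = None,
                 dataset: ClaimsDataset | None = None,
                 caliper_mult: float = 0.2,
                 threshold: float = 0.1,
                 n_prevalent: int = 200,
                 n_select: int = 500,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full comparison on a simulated (or supplied) claims dataset."""
    t0 = time.perf_counter()
    if dataset is None:
        if config is None:
            raise ValueError("provide a SimulationConfig or a ClaimsDataset")
        logger.info("simulating %d patients (seed %d)", config.n_patients, config.seed)
        dataset = generate_population(config)
    logger.info("building cohort [%.1fs]", time.perf_counter() - t0)
    cohort, report = apply_inclusion_exclusion(dataset)

    logger.info("fitting PS [%.1fs]", time.perf_counter() - t0)
    scores_ps = fit_propensity(build_ps_design(cohort))
    match_ps = match_scores(scores_ps, cohort["exposure"].to_numpy(),
                            caliper_mult=caliper_mult)

    logger.info("fitting hdPS [%.1fs]", time.perf_counter() - t0)
    dims = structure_dimensions(dataset, cohort)
    selector = HdpsCovariateSelector(n_prevalent=n_prevalent, n_select=n_select)
    exposure01 = (cohort["exposure"] == "high").to_numpy()
    selector.fit(dims, exposure01, cohort["outcome"].to_numpy())
    hdps_design = build_hdps_design(selector.transform(dims), cohort)
    scores_hdps = fit_hdps(hdps_design)
    match_hdps = match_scores(scores_hdps, cohort["exposure"].to_numpy(),
                              caliper_mult=caliper_mult)

    logger.info("balance and effects [%.1fs]", time.perf_counter() - t0)
    balance_full, summary_full = balance_table(cohort, threshold=threshold)
    cohort_ps = _matched_cohort(cohort, match_ps)
    cohort_hdps = _matched_cohort(cohort, match_hdps)
    balance_ps, summary_ps = balance_table(cohort_ps, threshold=threshold)
    balance_hdps, summary_hdps = balance_table(cohort_hdps, threshold=threshold)

    effects = {
        "full": estimate_or(outcome_cells(cohort), "full"),
        "ps_matched": estimate_or(outcome_cells(cohort_ps), "PS-matched"),
        "hdps_matched": estimate_or(outcome_cells(cohort_hdps), "hdPS-matched"),
    }

    n_high = int((cohort["exposure"] == "high").sum())
    n_lower = int((cohort["exposure"] == "lower").sum())
    flowchart = pd.DataFrame([
        {"stage": "entering", "high": n_high, "lower": n_lower},
        {"stage": "trimmed_ps", "high": match_ps.n_trimmed_high,
         "lower": match_ps.n_trimmed_lower},
        {"stage": "matched_ps", "high": match_ps.n_pairs, "lower": match_ps.n_pairs},
        {"stage": "trimmed_hdps", "high": match_hdps.n_trimmed_high,
         "lower": match_hdps.n_trimmed_lower},
        {"stage": "matched_hdps", "high": match_hdps.n_pairs,
         "lower": match_hdps.n_pairs},
    ])

    asdd_comparison = pd.DataFrame({
        "covariate": TABLE1_CHARACTERISTICS,
        "full": balance_full["asdd"].to_numpy(),
        "ps_matched": balance_ps["asdd"].to_numpy(),
        "hdps_matched": balance_hdps["asdd"].to_numpy(),
    })

    result = PipelineResult(
        cohort=cohort, exclusions=report.counts,
        scores_ps=scores_ps, scores_hdps=scores_hdps,
        match_ps=match_ps, match_hdps=match_hdps,
        balance_full=balance_full, balance_ps=balance_ps,
        balance_hdps=balance_hdps,
        summary_full=summary_full, summary_ps=summary_ps,
        summary_hdps=summary_hdps,
        effects=effects, flowchart=flowchart, asdd_comparison=asdd_comparison,
    )
    if out_dir is not None:
        result.write(out_dir)
    logger.info("pipeline done [%.1fs]", time.perf_counter() - t0)
    return result
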