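"""hdPS engine: dimensions, prevalence screen, recurrence, bias ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from hdpsmatch.hdps import (DataDimension, HdpsCovariateSelector,
                            bross_bias_multiplier, build_hdps_design,
                            expand_recurrence, fit_hdps, rank_by_bias,
                            select_prevalent_codes, structure_dimensions)
from hdpsmatch.propensity import SeparationError, fit_propensity
from hdpsmatch.simulate import SimulationConfig, generate_population

from conftest import EMPTY_DIAG, EMPTY_DISP, make_dataset, toy_patient


def _dim(counts: dict[str, list[int]], dimension_id=1) -> DataDimension:
    frame = pd.DataFrame(counts, index=pd.Index(
        range(1, len(next(iter(counts.values()))) + 1), name="patient_id"))
    return DataDimension(dimension_id=dimension_id, label="test", counts=frame)


class TestStructureDimensions:
    def test_counts_and_window(self):
        cohort = pd.DataFrame({"patient_id": [1, 2]})
        events = [
            {"patient_id": 1, "dimension_id": 1, "code": "C01", "days_before_entry": 10},
            {"patient_id": 1, "dimension_id": 1, "code": "C01", "days_before_entry": 20},
            {"patient_id": 1, "dimension_id": 1, "code": "C01", "days_before_entry": 30},
            {"patient_id": 2, "dimension_id": 1, "code": "C01", "days_before_entry": 400},
        ]
        ds = make_dataset([toy_patient(1), toy_patient(2)], events_rows=events)
        dims = structure_dimensions(ds, cohort)
        assert dims[1].counts.loc[1, "C01"] == 3
        assert dims[1].counts.loc[2, "C01"] == 0      # outside lookback window
        assert set(dims) == set(range(1, 7))

    def test_empty_events_all_zero(self):
        cohort = pd.DataFrame({"patient_id": [1, 2]})
        ds = make_dataset([toy_patient(1), toy_patient(2)])
        dims = structure_dimensions(ds, cohort)
        assert all(d.counts.shape[1] == 0 for d in dims.values())
        with pytest.warns(UserWarning, match="no candidate"):
            sel = HdpsCovariateSelector().fit(
                dims, np.array([True, False]), np.array([1, 0]))
        # degenerate input: nothing selectable
        assert len(sel.selected_) == 0

    def test_unknown_dimension_rejected(self):
        cohort = pd.DataFrame({"patient_id": [1]})
        ds = make_dataset([toy_patient(1)], events_rows=[
            {"patient_id": 1, "dimension_id": 9, "code": "X", "days_before_entry": 5}])
        with pytest.raises(ValueError, match="1..6"):
            structure_dimensions(ds, cohort)


class TestPrevalenceScreen:
    def test_ranking_and_lexical_tie_break(self):
        # prevalences X: 0.6, Y: 0.4, Z: 0.01 -> scores 0.4, 0.4, 0.01
        n = 100
        dim = _dim({
            "X": [1] * 60 + [0] * 40,
            "Y": [1] * 40 + [0] * 60,
            "Z": [1] * 1 + [0] * 99,
        })
        assert select_prevalent_codes(dim, k=2) == ["X", "Y"]
        assert select_prevalent_codes(dim, k=10) == ["X", "Y", "Z"]

    def test_degenerate_prevalences_excluded(self):
        dim = _dim({"all": [1, 1, 1], "none": [0, 0, 0], "ok": [1, 0, 0]})
        assert select_prevalent_codes(dim, k=5) == ["ok"]


class TestRecurrenceExpansion:
    def test_nearest_rank_thresholds(self):
        counts = pd.Series([1, 1, 2, 3, 10, 0, 0])
        trips = expand_recurrence(counts, "C")
        assert trips == [("C", "once", 1), ("C", "sporadic", 2), ("C", "frequent", 3)]
        # indicator semantics: count >= threshold
        assert [(3 >= t) for _, _, t in trips] == [True, True, True]
        assert [(1 >= t) for _, _, t in trips] == [True, False, False]

    def test_degenerate_all_single_occurrences_collapse(self):
        counts = pd.Series([1, 1, 1, 0])
        assert expand_recurrence(counts, "C") == [("C", "once", 1)]


class TestBiasRanking:
    def test_bross_formula_values(self):
        bm = bross_bias_multiplier(0.2, 0.1, 2.0)
        assert bm == pytest.approx(1.2 / 1.1, abs=1e-12)
        assert abs(math.log(bm)) == pytest.approx(0.08701, abs=1e-4)
        assert bross_bias_multiplier(0.3, 0.3, 5.0) == pytest.approx(1.0)
        assert bross_bias_multiplier(0.9, 0.1, 1.0) == pytest.approx(1.0)

    @staticmethod
    def _random_instance(seed, n=400, m=30):
        rng = np.random.default_rng(seed)
        exposure = rng.random(n) < 0.4
        outcome = rng.random(n) < 0.2
        V = rng.random((n, m)) < rng.uniform(0.05, 0.6, size=m)
        cand = pd.DataFrame({
            "dimension_id": rng.integers(1, 7, m),
            "code": [f"c{j:02d}" for j in range(m)],
            "level": rng.choice(["once", "sporadic", "frequent"], m),
            "threshold": 1,
        })
        return cand, V, exposure, outcome

    @staticmethod
    def _oracle_rank(cand, V, exposure, outcome):
        """Brute-force enumeration of the Bross ranking, plain python."""
        level_ord = {"once": 0, "sporadic": 1, "frequent": 2}
        rows = []
        for j in range(V.shape[1]):
            v = V[:, j]
            pc1 = v[exposure].mean()
            pc0 = v[~exposure].mean()
            n1, n0 = v.sum(), (~v).sum()
            y1 = (v & outcome).sum()
            y0 = (~v & outcome).sum()
            if n1 == 0 or n0 == 0 or y1 == 0 or y0 == 0:
                alb = 0.0
            else:
                rr = (y1 / n1) / (y0 / n0)
                if rr < 1.0:
                    rr = 1.0 / rr
                alb = abs(math.log((pc1 * (rr - 1) + 1) / (pc0 * (rr - 1) + 1)))
            r = cand.iloc[j]
            rows.append((-alb, r["dimension_id"], r["code"], level_ord[r["level"]]))
        return sorted(range(len(rows)), key=lambda j: rows[j])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_ranking_matches_bruteforce_oracle(self, seed):
        cand, V, exposure, outcome = self._random_instance(seed)
        ranked = rank_by_bias(cand, V, exposure, outcome, n_select=10)
        oracle = self._oracle_rank(cand, V, exposure, outcome)
        assert list(ranked["code"]) == [cand["code"].iloc[j] for j in oracle]
        # selection flags the top n_select of the same order
        assert list(ranked["selected"]) == [i < 10 for i in range(len(cand))]

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_abs_log_bias_invariant_under_label_swap(self, seed):
        cand, V, exposure, outcome = self._random_instance(seed)
        a = rank_by_bias(cand, V, exposure, outcome).set_index("code")
        b = rank_by_bias(cand, V, ~exposure, outcome).set_index("code")
        assert np.allclose(a["abs_log_bias"], b.loc[a.index, "abs_log_bias"],
                           atol=1e-12)

    def test_zero_cell_scores_zero(self):
        # covariate present only among cases -> undefined RR -> rank score 0
        exposure = np.array([1, 1, 0, 0], bool)
        outcome = np.array([1, 1, 0, 0], bool)
        V = np.array([[1], [1], [0], [0]], bool)
        cand = pd.DataFrame({"dimension_id": [1], "code": ["c"],
                             "level": ["once"], "threshold": [1]})
        ranked = rank_by_bias(cand, V, exposure, outcome)
        assert ranked["abs_log_bias"].iloc[0] == 0.0
        assert np.isnan(ranked["rr_cd"].iloc[0])

    def test_rerun_is_stable(self, small_dataset, small_cohort):
        dims = structure_dimensions(small_dataset, small_cohort)
        exp = (small_cohort["exposure"] == "high").to_numpy()
        out = small_cohort["outcome"].to_numpy()
        s1 = HdpsCovariateSelector(n_select=30).fit(dims, exp, out)
        s2 = HdpsCovariateSelector(n_select=30).fit(dims, exp, out)
        pd.testing.assert_frame_equal(s1.candidates_, s2.candidates_)


class TestHdpsDesignAndFit:
    def test_forced_set_plus_selected_columns(self, small_dataset, small_cohort):
        dims = structure_dimensions(small_dataset, small_cohort)
        sel = HdpsCovariateSelector(n_select=25).fit(
            dims, (small_cohort["exposure"] == "high").to_numpy(),
            small_cohort["outcome"].to_numpy())
        emp = sel.transform(dims)
        design = build_hdps_design(emp, small_cohort)
        year_cols = [c for c in design.frame.columns if c.startswith("year_")]
        n_forced = 6 + len(year_cols)
        assert design.frame.shape[1] == n_forced + emp.shape[1]
        assert emp.shape[1] == 25
        # no investigator clinical flags beyond the forced set
        assert "mi" not in design.frame.columns
        assert {"male", "age", "poverty", "ge1_hospitalisation",
                "ge5_outpatient_visits", "ge5_distinct_drugs"} \
            <= set(design.frame.columns)

    def test_estimator_equivalence_with_ps(self, small_cohort):
        from hdpsmatch.propensity import build_ps_design
        design = build_ps_design(small_cohort)
        ps = fit_propensity(design)
        hd = fit_hdps(design)
        assert np.allclose(ps.score, hd.score, atol=0)
        assert (ps.model_label, hd.model_label) == ("PS", "hdPS")

    def test_separation_by_selected_covariate_is_named(self, small_cohort):
        design = pd.DataFrame(
            {"d1_leak_once": (small_cohort["exposure"] == "high").to_numpy(int)},
            index=small_cohort["patient_id"])
        with pytest.raises(SeparationError, match="d1_leak_once"):
            fit_hdps(design, (small_cohort["exposure"] == "high").to_numpy())

    def test_planted_confounder_proxies_outrank_noise(self):
        """Codes emitted by confounders carry more Bross bias than noise.

        Loaded codes (definitional + proxy) should show larger mean
        |log bias multiplier| and better median rank than pure-noise codes,
        averaged over replicates.
        """
        from hdpsmatch.cohort import apply_inclusion_exclusion
        from hdpsmatch.simulate import _DEFINITIONAL_PARENTS
        diffs, rank_gaps = [], []
        for seed in (101, 102, 103):
            cfg = SimulationConfig(
                n_patients=6000, seed=seed,
                n_codes_per_dimension={d: 10 for d in range(1, 7)})
            ds = generate_population(cfg)
            cohort, _ = apply_inclusion_exclusion(ds)
            dims = structure_dimensions(ds, cohort)
            sel = HdpsCovariateSelector().fit(
                dims, (cohort["exposure"] == "high").to_numpy(),
                cohort["outcome"].to_numpy())
            cand = sel.candidates_.copy()
            cand["rank"] = np.arange(len(cand))

            def is_loaded(row):
                n_def = len(_DEFINITIONAL_PARENTS.get(row.dimension_id, []))
                j = int(row.code.split("_")[1])
                return j < n_def or (j - n_def) % 2 == 0

            loaded_mask = cand.apply(is_loaded, axis=1)
            per_code = cand.groupby("code").agg(
                alb=("abs_log_bias", "mean"), rank=("rank", "median"))
            loaded_codes = set(cand.loc[loaded_mask, "code"])
            lo = per_code.loc[per_code.index.isin(loaded_codes)]
            noi = per_code.loc[~per_code.index.isin(loaded_codes)]
            diffs.append(lo["alb"].mean() - noi["alb"].mean())
            rank_gaps.append(noi["rank"].median() - lo["rank"].median())
        assert np.mean(diffs) > 0
        assert np.mean(rank_gaps) > 0
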