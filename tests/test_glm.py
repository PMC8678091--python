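import itertools

import numpy as np
import pandas as pd
import pytest

from taskcoact import (
    GroundTruth,
    ResponseModel,
    Trial,
    TrialSchedule,
    behavioral_summary,
    build_model_frame,
    full_term_set,
    generate_responses,
    sidak_adjust,
)
from taskcoact.errors import DesignError
from taskcoact.glm import term_label


def make_cells(n_rois=4, n_sub=4, seed=0, sigma_z=0.3):
    """Full-factorial cell grid with random fisher_z, no responses yet."""
    rois = [f"roi_{j:03d}" for j in range(1, n_rois + 1)]
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        for cond, phase, probe, roi in itertools.product(
            ("morning", "evening"), ("encoding", "retrieval"),
            ("positive", "lure"), rois,
        ):
            rows.append(
                {
                    "subject": f"sub-{s:02d}", "session": cond, "task": "global",
                    "phase": phase, "probe": probe, "roi": roi,
                    "fisher_z": rng.normal(0.0, sigma_z), "n_events": 25,
                }
            )
    return pd.DataFrame(rows)


def simulated_cells(behavior, n_rois=4, n_sub=4, seed=0):
    cells = make_cells(n_rois=n_rois, n_sub=n_sub, seed=seed)
    truth = GroundTruth.constant(
        sorted(cells["roi"].unique()), behavior=behavior, seed=seed
    )
    return generate_responses(cells, truth, seed=seed + 1)


SMALL_TERMS = [(), ("probe",), ("corr",), ("corr", "probe")]


class TestTermSet:
    def test_a_priori_exclusions(self):
        terms = full_term_set()
        assert ("phase",) not in terms
        assert ("roi",) not in terms
        assert ("phase", "probe") not in terms
        assert ("probe", "roi") not in terms
        assert ("probe",) in terms
        assert ("condition",) in terms
        assert ("probe", "condition") in terms

    def test_marginality_closure(self):
        terms = set(full_term_set())
        for t in terms:
            if "corr" not in t:
                continue
            rest = [c for c in t if c != "corr"]
            for k in range(len(rest)):
                for sub in itertools.combinations(rest, k):
                    assert tuple(
                        c for c in ("corr", "phase", "probe", "condition", "roi")
                        if c in ("corr",) + sub
                    ) in terms

    def test_maximal_terms_present(self):
        terms = full_term_set()
        assert ("corr", "phase", "probe", "roi") in terms
        assert ("corr", "phase", "condition", "roi") in terms
        assert ("corr", "probe", "condition", "roi") in terms
        assert ("corr", "phase", "probe", "condition") in terms


class TestModelFrame:
    def test_negative_probe_rows_excluded(self):
        cells = make_cells()
        extra = cells.iloc[:4].copy()
        extra["probe"] = "negative"
        extra["response"] = "no"
        cells = generate_responses(
            cells, GroundTruth.constant(sorted(cells.roi.unique())), seed=0
        )
        frame = build_model_frame(pd.concat([cells, extra], ignore_index=True))
        assert set(frame.data["probe"]) == {"lure", "positive"}

    def test_outcome_codes_no_as_one(self):
        cells = simulated_cells({(): 5.0})  # almost surely all "no"
        frame = build_model_frame(cells)
        assert frame.data["y"].mean() > 0.95

    def test_factorial_row_bound(self):
        cells = simulated_cells({(): 0.0}, n_rois=90, n_sub=1)
        frame = build_model_frame(cells)
        assert frame.n_obs <= 2 * 2 * 2 * 90 * 2

    def test_empty_input_raises(self):
        with pytest.raises(DesignError):
            build_model_frame(pd.DataFrame())

    def test_single_level_factor_named_in_error(self):
        cells = simulated_cells({(): 0.0})
        cells = cells[cells["session"] == "morning"]
        with pytest.raises(DesignError, match="condition"):
            build_model_frame(cells)

    def test_df_counting_from_level_products(self):
        cells = simulated_cells({(): 0.0}, n_rois=90)
        frame = build_model_frame(cells)
        assert frame.term_df(("corr", "phase", "probe", "roi")) == 89
        assert frame.term_df(("corr", "condition")) == 1
        assert frame.term_df(("corr",)) == 1
        assert frame.term_df(("probe", "condition")) == 1


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        cells = simulated_cells({(): 0.0}, n_sub=8, seed=3)
        frame = build_model_frame(cells)
        n = frame.n_obs
        frame.data.loc[: n // 2 - 1, "y"] = 1.0
        frame.data.loc[n // 2 :, "y"] = 0.0
        res = ResponseModel(frame, terms=[()]).fit()
        assert res.params.iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_aic_definition(self):
        cells = simulated_cells({(): 0.2, ("corr",): 0.5}, n_sub=6)
        res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        assert res.aic == pytest.approx(2 * res.k_params - 2 * res.llf, abs=1e-9)

    def test_coefficient_recovery_within_3_se(self):
        beta = {(): 0.3, ("corr",): 0.8, ("probe",): -0.2, ("corr", "probe"): 0.4}
        cells = pd.concat(
            [make_cells(n_rois=2, n_sub=200, seed=s) for s in range(2)],
            ignore_index=True,
        )
        truth = GroundTruth.constant(sorted(cells.roi.unique()), behavior=beta)
        cells = generate_responses(cells, truth, seed=42)
        res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        # sum coding: probe codes +1 for 'lure' (alphabetically first), so
        # model coefficients estimate the generator's directly
        expected = {
            "(Intercept)": 0.3,
            "probe[lure]": -0.2,
            "corr": 0.8,
            "corr:probe[lure]": 0.4,
        }
        for name, b in expected.items():
            est, se = res.params[name], res.bse[name]
            assert abs(est - b) < 3 * se, (name, est, b, se)

    def test_weighting_by_events_changes_fit(self):
        cells = simulated_cells({(): 0.1, ("corr",): 0.6}, n_sub=10)
        cells["n_events"] = np.tile([1, 50], len(cells) // 2)
        a = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        b = ResponseModel.from_cells(
            cells, terms=SMALL_TERMS, weight_by_events=True
        ).fit()
        assert not np.allclose(a.params, b.params)


class TestType3:
    def test_chisq_equals_two_delta_loglik_of_independent_refits(self):
        cells = simulated_cells({(): 0.1, ("corr",): 0.7}, n_sub=10, seed=5)
        res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        tab = res.type3().set_index("term")
        # brute-force oracle: refit both models from scratch
        full = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        reduced = ResponseModel.from_cells(
            cells, terms=[(), ("probe",), ("corr", "probe")]
        ).fit()
        oracle = 2.0 * (full.llf - reduced.llf)
        assert tab.loc["corr", "chisq"] == pytest.approx(oracle, abs=1e-6)

    def test_p_values_in_unit_interval(self):
        cells = simulated_cells({(): 0.1, ("corr",): 0.7}, n_sub=10, seed=6)
        tab = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit().type3()
        assert ((tab["p"] > 0) & (tab["p"] <= 1)).all()
        assert (tab["chisq"] >= 0).all()
        assert (tab["df"] >= 1).all()


class TestReduceAIC:
    def test_null_term_deleted_in_most_seeds(self):
        wins = 0
        for seed in range(20):
            cells = simulated_cells(
                {(): 0.2, ("corr",): 1.0}, n_sub=12, seed=seed
            )
            res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
            final, trace = res.reduce_aic()
            if ("corr", "probe") not in final.model.terms:
                wins += 1
        assert wins >= 18

    def test_strong_terms_stop_reduction_immediately(self):
        cells = simulated_cells(
            {(): 0.2, ("corr",): 2.0, ("probe",): 1.5, ("corr", "probe"): 1.5},
            n_sub=60, seed=2,
        )
        res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        final, trace = res.reduce_aic()
        deleted = trace[trace["action"] == "deleted"]
        assert len(deleted) == 0

    def test_aic_non_increasing_in_greedy_mode(self):
        cells = simulated_cells({(): 0.1}, n_sub=10, seed=7)
        res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        _, trace = res.reduce_aic(require_improvement=True)
        deleted = trace[trace["action"] == "deleted"]
        assert (deleted["aic_after"] <= deleted["aic_before"] + 1e-9).all()

    def test_marginality_protects_subterms(self):
        cells = simulated_cells({(): 0.1, ("corr",): 0.5}, n_sub=8, seed=8)
        res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        deletable = res._deletable(res.model.terms)
        assert ("corr",) not in deletable  # protected by corr:probe
        assert ("corr", "probe") in deletable


class TestTrends:
    def test_sidak_closed_form(self):
        assert sidak_adjust(0.01, 5) == pytest.approx(0.049010, abs=1e-6)
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2, abs=1e-12)

    def test_sidak_monotone_in_family_size(self):
        p = 0.03
        vals = [float(sidak_adjust(p, m)) for m in range(1, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_adjusted_p_at_least_raw(self):
        cells = simulated_cells({(): 0.1, ("corr",): 0.8}, n_sub=10, seed=9)
        res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        tab = res.trend_contrasts(by=["probe"])
        assert (tab["p_adj"] >= tab["p_value"] - 1e-12).all()
        assert ((tab["ci_lo"] <= tab["estimate"])
                & (tab["estimate"] <= tab["ci_hi"])).all()

    def test_unknown_by_factor_raises(self):
        cells = simulated_cells({(): 0.1}, n_sub=4)
        res = ResponseModel.from_cells(cells, terms=SMALL_TERMS).fit()
        with pytest.raises(KeyError):
            res.trends(by=["chronotype"])

    def test_single_roi_effect_yields_smallest_adjusted_p(self):
        """When only one ROI carries a probe-specific correlation slope,
        that ROI's lure-positive trend contrast should dominate the family."""
        terms = [
            (), ("probe",), ("corr",), ("corr", "probe"), ("corr", "roi"),
            ("corr", "probe", "roi"),
        ]
        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            beta = {
                (): 0.2,
                ("corr",): 0.3,
                ("corr", "probe", "roi"): {"roi_001": 2.0},
            }
            cells = simulated_cells(beta, n_rois=6, n_sub=25, seed=100 + rep)
            res = ResponseModel.from_cells(cells, terms=terms).fit()
            tab = res.trend_contrasts(by=["probe", "roi"],
                                      contrast_factor="probe")
            best_roi = tab.loc[tab["p_adj"].idxmin(), "roi"]
            hits += best_roi == "roi_001"
        assert hits >= 0.9 * n_reps


class TestBehavioralSummary:
    def toy_schedule(self, specs):
        trials = []
        t = 0.0
        tid = 0
        for probe, response, rt in specs:
            trials.append(Trial(tid, t, 1800.0, "encoding"))
            tid += 1
            t += 4000.0
            trials.append(
                Trial(tid, t, 2000.0, "retrieval", probe=probe,
                      response=response, reaction_time_ms=rt)
            )
            tid += 1
            t += 8000.0
        n_volumes = int(np.ceil(t / 1800.0)) + 2
        return TrialSchedule(trials=trials, n_volumes=n_volumes, tr_ms=1800.0)

    def test_hand_counted_proportions(self):
        sched = self.toy_schedule(
            [("positive", "yes", 1000.0)] * 3 + [("positive", "no", 1200.0)]
        )
        tab = behavioral_summary(sched).set_index(["probe", "response_type"])
        assert tab.loc[("positive", "hits"), "proportion"] == pytest.approx(0.75)
        assert tab.loc[("positive", "misses"), "proportion"] == pytest.approx(0.25)

    def test_all_correct_gives_zero_error_rates(self):
        sched = self.toy_schedule(
            [("positive", "yes", 900.0)] * 2 + [("lure", "no", 1100.0)] * 2
            + [("negative", "no", 800.0)]
        )
        tab = behavioral_summary(sched).set_index(["probe", "response_type"])
        assert tab.loc[("positive", "misses"), "proportion"] == 0.0
        assert tab.loc[("lure", "false_alarms"), "proportion"] == 0.0
        assert tab.loc[("negative", "false_alarms"), "proportion"] == 0.0

    def test_proportions_sum_to_one_per_probe(self, default_schedule):
        tab = behavioral_summary(default_schedule)
        sums = tab.groupby("probe")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_missing_category_reported_with_zero_count(self):
        sched = self.toy_schedule([("positive", "yes", 900.0)])
        tab = behavioral_summary(sched).set_index(["probe", "response_type"])
        assert tab.loc[("lure", "false_alarms"), "n"] == 0
        assert np.isnan(tab.loc[("lure", "false_alarms"), "rt_mean_ms"])
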