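"""Composite score arithmetic, classification boundaries, cutoff evaluation
and subgroup benefit metrics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from minerva_nsclc import (
    ClinicalRecord,
    ConfigError,
    DegenerateDataError,
    FeatureMatrix,
    InteractionResult,
    MinervaScorer,
    PUBLISHED_WEIGHTS,
    ScoreResult,
    attainable_scores,
    benefit_summary,
    classify,
    compute_score,
    default_adjuvant_config,
    evaluate_cutoffs,
    published_weights,
    refit_weights,
    screen_interactions,
    SIGNATURE_FEATURES,
)
from minerva_nsclc.io import build_feature_matrix, filter_variants
from minerva_nsclc.simulate import feature_definitions_for, generate_cohort


def profile_matrix(*profiles):
    """FeatureMatrix over the five signature features from 0/1 profiles."""
    return FeatureMatrix(
        [f"P{i}" for i in range(len(profiles))],
        list(SIGNATURE_FEATURES),
        np.array(profiles, dtype=np.int8),
    )


class TestPublishedWeights:
    def test_values(self):
        w = published_weights()
        assert w.source == "published"
        assert w.weights["RB1_alt"] == 2.88
        assert w.weights["MYC_gain"] == -1.98
        assert sum(w.weights.values()) == pytest.approx(-6.19)

    def test_five_features(self):
        assert set(published_weights().weights) == set(SIGNATURE_FEATURES)


class TestRefitWeights:
    def ok(self, fid, z, converged=True):
        return InteractionResult(fid, 20, 10, math.exp(z), 1.0, 9.0, z, 0.01, converged)

    def test_single_entry(self):
        w = refit_weights([self.ok("RB1_alt", 2.88)])
        assert w.weights == {"RB1_alt": 2.88} and w.source == "refit"

    def test_empty_selection_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            refit_weights([])

    def test_non_converged_rejected(self):
        with pytest.raises(ConfigError, match="converged"):
            refit_weights([self.ok("X", 2.0, converged=False)])

    def test_weight_recovery_across_seeds(self):
        """Cohorts generated at n=171 with the published effect sizes: mean
        interaction z per feature over 50 seeds lands within +-1.0 of the
        published weight (marginal screening attenuates the strongest
        copy-number markers but stays inside the band)."""
        sums = {f: [] for f in SIGNATURE_FEATURES}
        for seed in range(50):
            cfg = default_adjuvant_config(seed=seed)
            clinical, calls, _ = generate_cohort(cfg)
            fm = build_feature_matrix(
                clinical, filter_variants(calls), feature_definitions_for(cfg)
            )
            results, _ = screen_interactions(fm, clinical)
            for r in results:
                if r.status == "OK":
                    sums[r.feature_id].append(r.z)
        for f, zs in sums.items():
            assert zs, f"feature {f} never tested"
            assert abs(np.mean(zs) - PUBLISHED_WEIGHTS[f]) < 1.0


class TestComputeScore:
    def test_worked_profiles(self):
        fm = profile_matrix(
            [1, 1, 0, 0, 0],  # RB1 + NKX2-1
            [0, 0, 0, 0, 0],  # wild-type
            [0, 1, 1, 1, 0],  # NKX2-1 + CDK4 + TP53e45
            [1, 0, 0, 0, 0],  # RB1 only
        )
        s = compute_score(published_weights(), fm).scores
        assert s.iloc[0] == pytest.approx(0.16)
        assert s.iloc[1] == 0.0
        assert s.iloc[2] == pytest.approx(-7.09)
        assert s.iloc[3] == pytest.approx(2.88)

    def test_missing_feature_column_treated_wild_type(self, caplog):
        fm = FeatureMatrix(["P1"], ["RB1_alt"], np.array([[1]]))
        s = compute_score(published_weights(), fm).scores
        assert s.iloc[0] == pytest.approx(2.88)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), min_size=5, max_size=5),
           st.lists(st.booleans(), min_size=5, max_size=5))
    def test_additive_over_disjoint_profiles(self, a, b):
        a = np.array(a, dtype=np.int8)
        b = np.array(b, dtype=np.int8) & ~a  # force disjoint
        fm = profile_matrix(a, b, a | b)
        s = compute_score(published_weights(), fm).scores
        assert s.iloc[2] == pytest.approx(s.iloc[0] + s.iloc[1], abs=1e-12)


class TestClassify:
    def test_boundaries(self):
        fm = profile_matrix([0, 0, 0, 0, 0])
        scores = pd.Series([0.16, -7.09, -0.5, 0.5, 0.0],
                           index=[f"P{i}" for i in range(5)])
        res = classify(ScoreResult(scores=scores))
        assert res.subgroups.tolist() == ["TP", "HTP", "HTP", "CP", "TP"]

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ConfigError):
            classify(ScoreResult(scores=pd.Series([0.0])), cutoffs=(0.5, -0.5))
        with pytest.raises(ConfigError):
            classify(ScoreResult(scores=pd.Series([0.0])), cutoffs=(0.0, 0.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=20))
    def test_partition_and_monotone_in_score(self, values):
        res = classify(ScoreResult(scores=pd.Series(values)))
        assert res.subgroups.isin(["HTP", "TP", "CP"]).all()
        order = {"HTP": 0, "TP": 1, "CP": 2}
        ranks = res.subgroups.map(order)
        idx = np.argsort(values, kind="stable")
        assert (np.diff(ranks.to_numpy()[idx]) >= 0).all()


class TestAttainableScores:
    def test_subset_sums_enumerated(self):
        # independent enumeration of the 2^5 profile sums
        vals = list(PUBLISHED_WEIGHTS.values())
        expected = sorted(
            {
                round(sum(c), 10)
                for r in range(6)
                for c in itertools.combinations(vals, r)
            }
        )
        got = attainable_scores()
        assert got == expected
        assert len(got) == 32
        assert min(got) == pytest.approx(-9.07)  # all four negative features
        assert max(got) == pytest.approx(2.88)
        # the printed cohort minimum is an observed combination, not the
        # theoretical minimum
        assert -7.09 == pytest.approx(
            PUBLISHED_WEIGHTS["NKX2-1_gain"]
            + PUBLISHED_WEIGHTS["CDK4_gain"]
            + PUBLISHED_WEIGHTS["TP53_e45_mis"]
        )


def two_arm_records(times_tki, ev_tki, times_chemo, ev_chemo):
    recs = []
    for i, (t, e) in enumerate(zip(times_tki, ev_tki)):
        recs.append(ClinicalRecord(f"T{i}", "TKI", float(t), bool(e)))
    for i, (t, e) in enumerate(zip(times_chemo, ev_chemo)):
        recs.append(ClinicalRecord(f"C{i}", "CHEMO", float(t), bool(e)))
    return recs


class TestBenefitSummary:
    def make_scored(self, records, score=0.0):
        ids = [r.patient_id for r in records]
        scores = pd.Series(score, index=ids)
        return classify(ScoreResult(scores=scores))

    def test_printed_subgroup_arithmetic(self):
        """Arms constructed so KM at 24 months equals the printed 70.3% and
        11.0% and medians the printed 34.5 / 9.1 months: the benefit metrics
        reproduce the printed 6.4-fold ratio and 25.4-month difference."""
        # TKI arm: 1000 patients; 297 events at t=12 -> S(24)=0.703;
        # 250 more at t=34.5 -> S = 0.703*(1 - 250/703) <= 0.5 (median 34.5)
        times_tki = [12.0] * 297 + [34.5] * 250 + [60.0] * 453
        ev_tki = [True] * 547 + [False] * 453
        # chemo arm: 500 events at t=9.1 (median), 390 at t=12 -> S(24)=0.11
        times_chemo = [9.1] * 500 + [12.0] * 390 + [60.0] * 110
        ev_chemo = [True] * 890 + [False] * 110
        records = two_arm_records(times_tki, ev_tki, times_chemo, ev_chemo)
        benefits = benefit_summary(self.make_scored(records), records)
        tp = next(b for b in benefits if b.subgroup == "TP")
        assert tp.rate_tki == pytest.approx(0.703)
        assert tp.rate_chemo == pytest.approx(0.110)
        assert round(tp.rate_ratio, 1) == 6.4
        assert tp.median_tki == 34.5 and tp.median_chemo == 9.1
        assert round(tp.median_diff, 1) == 25.4

    def test_identical_arms_null_benefit(self):
        t = [5.0, 10.0, 15.0, 20.0, 30.0]
        e = [True, True, False, True, False]
        records = two_arm_records(t, e, t, e)
        benefits = benefit_summary(self.make_scored(records), records)
        tp = next(b for b in benefits if b.subgroup == "TP")
        assert tp.rate_ratio == pytest.approx(1.0)
        assert tp.median_diff == 0.0
        assert tp.logrank_p == pytest.approx(1.0)

    def test_swapped_arms_symmetry(self, adjuvant_cohort):
        scored = MinervaScorer().fit(None).score_result(adjuvant_cohort.fm)
        fwd = benefit_summary(scored, adjuvant_cohort.clinical)
        swapped = [
            ClinicalRecord(
                r.patient_id, "CHEMO" if r.arm == "TKI" else "TKI",
                r.dfs_months, r.dfs_event, r.os_months, r.os_event,
                r.age, r.sex, r.smoking, r.stage, r.n_stage,
            )
            for r in adjuvant_cohort.clinical
        ]
        rev = benefit_summary(scored, swapped)
        for f, r in zip(fwd, rev):
            if not (f.defined and r.defined):
                continue
            if math.isfinite(f.rate_ratio) and math.isfinite(r.rate_ratio):
                assert r.rate_ratio == pytest.approx(1 / f.rate_ratio)
            if f.median_diff is not None and r.median_diff is not None:
                assert r.median_diff == pytest.approx(-f.median_diff)

    def test_empty_subgroup_undefined(self):
        records = two_arm_records([5.0, 8.0], [True, True], [4.0, 6.0], [True, False])
        scores = pd.Series([-1.0, -1.0, -1.0, -1.0],
                           index=[r.patient_id for r in records])
        benefits = benefit_summary(classify(ScoreResult(scores=scores)), records)
        cp = next(b for b in benefits if b.subgroup == "CP")
        assert not cp.defined


class TestEvaluateCutoffs:
    def test_constant_scores_rejected(self, adjuvant_cohort):
        scores = pd.Series(0.0, index=adjuvant_cohort.fm.patient_ids)
        with pytest.raises(DegenerateDataError, match="constant"):
            evaluate_cutoffs(ScoreResult(scores=scores), adjuvant_cohort.clinical)

    def test_degenerate_zero_pair_flagged(self, adjuvant_cohort):
        scored = MinervaScorer().fit(None).score_result(adjuvant_cohort.fm)
        table = evaluate_cutoffs(scored, adjuvant_cohort.clinical)
        row = table[(table["low"] == 0.0) & (table["high"] == 0.0)].iloc[0]
        assert "TP empty" in row["flags"]
        assert row["n_TP"] == 0

    def test_published_cutoffs_rank_near_top(self):
        """(-0.5, 0.5) ranks first or second by the separation statistic in
        most synthetic cohorts generated with the published effects."""
        ranks = []
        for seed in range(5):
            cfg = default_adjuvant_config(seed=seed)
            clinical, calls, _ = generate_cohort(cfg)
            fm = build_feature_matrix(clinical, calls, feature_definitions_for(cfg))
            scored = MinervaScorer().fit(None).score_result(fm)
            table = evaluate_cutoffs(scored, clinical)
            pos = table.index[(table["low"] == -0.5) & (table["high"] == 0.5)][0]
            ranks.append(pos)
        assert np.mean(ranks) <= 1.0


class TestMinervaScorerEstimator:
    def test_sklearn_contract(self, adjuvant_cohort):
        from sklearn.base import clone

        est = MinervaScorer(cutoffs=(-1.0, 1.0))
        est2 = clone(est)
        assert est2.get_params()["cutoffs"] == (-1.0, 1.0)
        est2.set_params(cutoffs=(-0.5, 0.5)).fit(None)
        X = adjuvant_cohort.fm.to_frame()
        labels = est2.predict(X)
        scores = est2.decision_function(X)
        assert set(labels) <= {"HTP", "TP", "CP"}
        assert (labels[scores <= -0.5] == "HTP").all()
        assert est2.transform(X).shape == (len(X), 1)

    def test_refit_mode_requires_y(self, adjuvant_cohort):
        with pytest.raises(ConfigError, match="refit"):
            MinervaScorer(weights="refit").fit(adjuvant_cohort.fm)

    def test_refit_mode_matches_screen(self, adjuvant_cohort):
        est = MinervaScorer(weights="refit").fit(
            adjuvant_cohort.fm, adjuvant_cohort.clinical
        )
        _, selected = screen_interactions(adjuvant_cohort.fm, adjuvant_cohort.clinical)
        assert est.weights_.weights == {r.feature_id: r.z for r in selected}

    def test_custom_weight_mapping(self):
        fm = profile_matrix([1, 0, 0, 0, 0])
        est = MinervaScorer(weights={"RB1_alt": 1.5}).fit(None)
        assert est.decision_function(fm)[0] == pytest.approx(1.5)
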