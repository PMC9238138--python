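"""Evaluation machinery: stratified splits, permuted-label null, metrics,
nested search, paired statistics, FDR, summary grid."""

import numpy as np
import pandas as pd
import pytest

from omicsbench.evaluation import (
    DEFAULT_ALPHAS,
    DEFAULT_L1_RATIOS,
    EvalConfig,
    ExperimentResult,
    call_summary_grid,
    compute_metrics,
    concordance_index,
    fdr_correct,
    make_cv_splits,
    nested_grid_search,
    paired_delta_test,
    permute_labels_stratified,
    run_gene_experiment,
)


def _cohort_df(spec):
    # spec: list of (cancer_type, sample_type, count)
    rows = []
    for ct, st, k in spec:
        rows += [(ct, st)] * k
    idx = [f"S{i}" for i in range(len(rows))]
    df = pd.DataFrame(rows, columns=["cancer_type", "sample_type"], index=idx)
    df["n_mutations"] = 100
    return df


class TestMakeCvSplits:
    def test_exact_divisibility_balanced_folds(self):
        df = _cohort_df([("A", "Primary", 40), ("B", "Primary", 40)])
        plan = make_cv_splits(df, df.index, seed=1)
        for (rep, fold), test in plan.assignments.items():
            counts = df.loc[test, "cancer_type"].value_counts()
            assert counts["A"] == 10 and counts["B"] == 10

    def test_folds_partition_samples(self):
        df = _cohort_df([("A", "Primary", 33), ("B", "Primary", 21)])
        plan = make_cv_splits(df, df.index, seed=2)
        for rep in range(2):
            all_test = np.concatenate(
                [plan.assignments[(rep, f)].to_numpy() for f in range(4)]
            )
            assert sorted(all_test) == sorted(df.index)

    def test_small_stratum_merged(self):
        df = _cohort_df([("A", "Primary", 50), ("A", "Recurrent", 2)])
        plan = make_cv_splits(df, df.index, seed=3)  # must not crash
        assert len(plan.assignments) == 8

    def test_deterministic(self):
        df = _cohort_df([("A", "Primary", 30), ("B", "Primary", 30)])
        a = make_cv_splits(df, df.index, seed=4)
        b = make_cv_splits(df, df.index, seed=4)
        for key in a.assignments:
            assert a.assignments[key].equals(b.assignments[key])

    def test_too_few_samples_error(self):
        df = _cohort_df([("A", "Primary", 3)])
        with pytest.raises(ValueError, match="fewer"):
            make_cv_splits(df, df.index, seed=1)


class TestPermuteLabels:
    def _setup(self, rng, n=120):
        idx = pd.Index([f"S{i}" for i in range(n)])
        labels = pd.Series(rng.integers(0, 2, n), index=idx)
        ct = pd.Series(rng.choice(["A", "B", "C"], n), index=idx)
        return labels, ct, idx[: n // 2], idx[n // 2 :]

    def test_all_zero_cell_unchanged(self, rng):
        labels, ct, tr, te = self._setup(rng)
        labels.loc[tr[ct.loc[tr] == "A"]] = 0
        out = permute_labels_stratified(labels, ct, (tr, te), seed=1)
        cell = tr[ct.loc[tr] == "A"]
        assert (out.loc[cell] == 0).all()

    def test_counts_preserved_exactly(self, rng):
        labels, ct, tr, te = self._setup(rng)
        for seed in range(20):
            out = permute_labels_stratified(labels, ct, (tr, te), seed=seed)
            for part in (tr, te):
                for t in ("A", "B", "C"):
                    cell = part[ct.loc[part] == t]
                    assert out.loc[cell].sum() == labels.loc[cell].sum()

    def test_two_sample_cell_uniform(self):
        idx = pd.Index(["S0", "S1"])
        labels = pd.Series([1, 0], index=idx)
        ct = pd.Series(["A", "A"], index=idx)
        hits = sum(
            permute_labels_stratified(labels, ct, (idx, pd.Index([])), seed=s)["S0"]
            for s in range(1000)
        )
        assert abs(hits / 1000 - 0.5) < 0.05


class TestComputeMetrics:
    def test_perfect_ranking(self):
        aupr, auroc = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert aupr == 1.0 and auroc == 1.0

    def test_constant_scores_tie_convention(self):
        labels = [1, 0, 0, 1, 0, 0, 0, 0, 0, 0]
        aupr, auroc = compute_metrics(np.ones(10), labels)
        assert auroc == 0.5
        assert aupr == pytest.approx(0.2)  # prevalence

    def test_hand_example_matches_enumeration(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        labels = [1, 0, 1, 0]
        aupr, auroc = compute_metrics(scores, labels)
        # ranked positives at ranks 1 and 3: AP = (1/1 + 2/3) / 2
        assert aupr == pytest.approx((1.0 + 2.0 / 3.0) / 2.0)
        assert auroc == pytest.approx(3.0 / 4.0)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([0.5, 0.6], [1, 1])


def _make_results(gene, mset, condition, auprs):
    return [
        ExperimentResult(gene=gene, modality_set=mset, replicate=r, fold=f,
                         condition=condition, aupr=auprs[r * 4 + f], auroc=0.5,
                         alpha=0.01, l1_ratio=0.5, n_test_positives=10)
        for r in range(2) for f in range(4)
    ]


class TestPairedDeltaTest:
    def test_identical_inputs(self):
        a = _make_results("G", "m", "true_labels", [0.5] * 8)
        b = _make_results("G", "m", "permuted_labels", [0.5] * 8)
        call = paired_delta_test(a, b)
        assert call.mean_delta_aupr == 0.0 and call.p_value == 1.0

    def test_constant_shift_with_jitter(self, rng):
        jitter = rng.normal(0, 1e-6, 8)
        a = _make_results("G", "m", "true_labels", list(0.6 + jitter))
        b = _make_results("G", "m", "permuted_labels", [0.5] * 8)
        call = paired_delta_test(a, b)
        assert call.p_value < 1e-6
        assert call.mean_delta_aupr == pytest.approx(0.1, abs=1e-5)

    def test_symmetric_cancellation(self):
        a = _make_results("G", "m", "true_labels", [0.6] * 4 + [0.4] * 4)
        b = _make_results("G", "m", "permuted_labels", [0.5] * 8)
        call = paired_delta_test(a, b)
        assert call.mean_delta_aupr == pytest.approx(0.0)
        assert call.t_statistic == pytest.approx(0.0)
        assert call.p_value == pytest.approx(1.0)

    def test_key_mismatch_error(self):
        a = _make_results("G", "m", "true_labels", [0.5] * 8)
        b = _make_results("G", "m", "permuted_labels", [0.5] * 8)[:-1]
        with pytest.raises(ValueError, match="mismatch"):
            paired_delta_test(a, b)


class TestFdrCorrect:
    def _call(self, p, mset="m"):
        from omicsbench.evaluation import ComparisonCall
        return ComparisonCall(gene="G", modality_set=mset, comparison="vs_permuted",
                              mean_delta_aupr=0.1, t_statistic=1.0, p_value=p)

    def test_single_test_q_equals_p(self):
        calls = fdr_correct([self._call(0.03)])
        assert calls[0].q_value == pytest.approx(0.03)

    def test_hand_bh_computation(self):
        calls = fdr_correct([self._call(p) for p in (0.01, 0.02, 0.03, 0.04)])
        for c in calls:
            assert c.q_value == pytest.approx(0.04)

    def test_q_monotone_in_p(self, rng):
        ps = sorted(rng.random(20))
        calls = fdr_correct([self._call(p) for p in ps])
        qs = [c.q_value for c in calls]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(c.q_value >= c.p_value for c in calls)

    def test_families_corrected_separately(self):
        calls = [self._call(0.01, "a"), self._call(0.04, "a"),
                 self._call(0.01, "b")]
        fdr_correct(calls)
        assert calls[2].q_value == pytest.approx(0.01)  # family of one
        assert calls[0].q_value == pytest.approx(0.02)

    def test_nested_significance_sets(self):
        calls = fdr_correct([self._call(0.0005)])
        assert calls[0].significant_at == {0.05, 0.01, 0.001}


class TestCallSummaryGrid:
    def test_single_modality_self_equivalent(self):
        results = _make_results("G", "m", "true_labels", [0.8] * 8) + _make_results(
            "G", "m", "permuted_labels", [0.3, 0.31, 0.29, 0.3, 0.3, 0.32, 0.28, 0.3]
        )
        grid = call_summary_grid(results)
        row = grid.iloc[0]
        assert row["best_modality"] and row["equivalent_to_best"]
        assert row["well_predicted"]

    def test_negative_delta_never_well_predicted(self):
        # permuted beats true consistently: significant but wrong sign
        results = _make_results("G", "m", "true_labels",
                                [0.30, 0.31, 0.29, 0.30, 0.30, 0.32, 0.28, 0.30])
        results += _make_results("G", "m", "permuted_labels", [0.8] * 8)
        grid = call_summary_grid(results)
        assert grid.iloc[0]["mean_delta_aupr"] < 0
        assert not grid.iloc[0]["well_predicted"]

    def test_equal_modalities_both_equivalent(self, rng):
        results = []
        base = 0.7 + rng.normal(0, 0.01, 8)
        for m in ("a", "b"):
            results += _make_results("G", m, "true_labels", list(base + rng.normal(0, 0.01, 8)))
            results += _make_results("G", m, "permuted_labels", [0.3] * 8)
        grid = call_summary_grid(results)
        assert grid["equivalent_to_best"].all()


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(0)
    n = 160
    df = _cohort_df([("A", "Primary", 80), ("B", "Primary", 80)])
    X = pd.DataFrame(rng.normal(size=(n, 5)), index=df.index)
    y = pd.Series((rng.random(n) < 0.3).astype(int), index=df.index)
    y.iloc[:5] = 1  # ensure enough positives
    X.loc[y == 1, 0] += 2.0  # informative feature
    plan = make_cv_splits(df, df.index, seed=0)
    return X, y, plan


class TestNestedGridSearch:

    def test_degenerate_single_pair_grid(self, instance):
        X, y, plan = instance
        recs = nested_grid_search(X, y, plan, alphas=[0.01], l1_ratios=[0.5], seed=1)
        assert all(r["alpha"] == 0.01 and r["l1_ratio"] == 0.5 for r in recs)

    def test_default_grids_are_48_pairs(self):
        assert len(DEFAULT_ALPHAS) * len(DEFAULT_L1_RATIOS) == 48

    def test_eight_records_with_chosen_pairs_in_grid(self, instance):
        X, y, plan = instance
        alphas, l1s = (0.001, 0.1), (0.0, 1.0)
        recs = nested_grid_search(X, y, plan, alphas=alphas, l1_ratios=l1s, seed=2,
                                  model_kwargs=dict(max_iter=100, tol=1e-5))
        assert len(recs) == 8
        assert {(r["replicate"], r["fold"]) for r in recs} == {
            (r, f) for r in range(2) for f in range(4)
        }
        assert all(r["alpha"] in alphas and r["l1_ratio"] in l1s for r in recs)

    def test_strong_signal_prefers_small_alpha(self, instance):
        X, y, plan = instance
        recs = nested_grid_search(X, y, plan, alphas=(0.001, 10.0), l1_ratios=(0.5,),
                                  seed=3, model_kwargs=dict(max_iter=150, tol=1e-6))
        small = sum(r["alpha"] == 0.001 for r in recs)
        assert small >= 6


class TestRunGeneExperiment:
    def test_record_structure_and_pairing(self, small_planted_bundle):
        b = small_planted_bundle
        from omicsbench.features import build_covariates, standardize
        from omicsbench.labels import make_label_set

        ls = make_label_set(
            b["annotations"][0], b["mutations"], b["cnv"],
            b["cohort"].samples["cancer_type"], min_mutated=10, min_fraction=0.02,
        )
        m, _ = standardize(b["datasets"][0].matrix.loc[ls.included_samples])
        cov = build_covariates(b["cohort"].samples, ls.included_samples)
        X = pd.concat([m, cov], axis=1)
        cfg = EvalConfig(alphas=(0.01, 0.1), l1_ratios=(0.0, 1.0), seed=5,
                         max_iter=100, tol=1e-5)
        results = run_gene_experiment("G1", X, ls.labels, b["cohort"].samples, cfg,
                                      modality_set="expression")
        true = [r for r in results if r.condition == "true_labels"]
        perm = [r for r in results if r.condition == "permuted_labels"]
        assert len(true) == 8 and len(perm) == 8
        assert {(r.replicate, r.fold) for r in true} == {
            (r.replicate, r.fold) for r in perm
        }
        # paired comparison works end to end
        call = paired_delta_test(true, perm)
        assert call.mean_delta_aupr > 0  # planted signal


class TestConcordanceIndex:
    def test_perfect_anti_ordering(self):
        times = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # higher risk, shorter life
        assert concordance_index(scores, times, np.ones(5)) == 1.0

    def test_constant_scores_half(self):
        assert concordance_index(np.ones(6), np.arange(1.0, 7.0), np.ones(6)) == 0.5

    def test_hand_tabulated_six_triples(self):
        times = np.array([2.0, 4.0, 3.0, 5.0, 1.0, 6.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        scores = np.array([3.0, 1.0, 3.0, 0.5, 2.0, 0.0])
        num = den = 0.0
        for i in range(6):
            if events[i] != 1:
                continue
            for j in range(6):
                if i == j:
                    continue
                if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
                    den += 1
                    num += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
        assert concordance_index(scores, times, events) == pytest.approx(num / den)

    def test_no_admissible_pairs_error(self):
        with pytest.raises(ValueError, match="admissible"):
            concordance_index([1.0, 2.0], [1.0, 2.0], [0, 0])
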