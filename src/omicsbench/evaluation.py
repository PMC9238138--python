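"""Cross-validated benchmark orchestration and statistics.

The atomic experiment unit: for one target gene and one modality set, two
replicates of 4-fold cross-validation (splits stratified jointly by cancer
type and sample type) yield eight test-set performance records, once with
true mutation labels and once with labels permuted within each
(cancer type x train/test) cell — the permuted-label null preserves class
balance per cancer type exactly. Hyperparameters come from a 3-fold nested
grid search on the outer-training set scored by mean inner AUPR; the
permuted condition re-runs the full search so the null enjoys the same
model-selection flexibility.

Comparisons between conditions (or between modalities) are paired t-tests
over the eight fold-matched measurements, corrected by Benjamini-Hochberg
FDR within a declared family. A gene is "well-predicted" by a modality when
the true-vs-permuted test is significant at the corrected threshold with a
positive mean AUPR difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sksurv.metrics import concordance_index_censored
from statsmodels.stats.multitest import multipletests

from ._utils import child_seed, rng_for
from .models import CoxElasticNet, ElasticNetLogisticRegression

__all__ = [
    "SplitPlan",
    "ExperimentResult",
    "ComparisonCall",
    "EvalConfig",
    "make_cv_splits",
    "permute_labels_stratified",
    "compute_metrics",
    "nested_grid_search",
    "run_gene_experiment",
    "paired_delta_test",
    "fdr_correct",
    "call_summary_grid",
    "concordance_index",
    "run_survival_experiment",
]

#: Hyperparameter grids for mutation-status classification.
DEFAULT_ALPHAS = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0)
DEFAULT_L1_RATIOS = (0.0, 0.05, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
#: Penalty-strength grid for the elastic-net Cox survival models.
DEFAULT_COX_ALPHAS = (
    0.0, 1e-5, 1e-4, 5e-4, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 10.0, 100.0, 1000.0
)
SIGNIFICANCE_THRESHOLDS = (0.05, 0.01, 0.001)


@dataclass
class SplitPlan:
    """Stratified test-fold assignments for every (replicate, fold)."""

    n_folds: int
    n_replicates: int
    strata: pd.Series  # merged (cancer_type, sample_type) stratum per sample
    assignments: dict[tuple[int, int], pd.Index]
    seed: int

    def train_test(self, replicate: int, fold: int) -> tuple[pd.Index, pd.Index]:
        test = self.assignments[(replicate, fold)]
        train = self.strata.index.difference(test, sort=False)
        return train, test

    def keys(self) -> list[tuple[int, int]]:
        return sorted(self.assignments)


@dataclass(frozen=True)
class ExperimentResult:
    gene: str
    modality_set: str
    replicate: int
    fold: int
    condition: str  # {"true_labels", "permuted_labels"}
    aupr: float
    auroc: float
    alpha: float
    l1_ratio: float
    n_test_positives: int


@dataclass
class ComparisonCall:
    gene: str
    modality_set: str
    comparison: str  # e.g. "vs_permuted" or "vs_<other modality>"
    mean_delta_aupr: float
    t_statistic: float
    p_value: float
    q_value: float | None = None
    significant_at: set[float] = field(default_factory=set)
    degenerate: bool = False


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation-stage settings; defaults are the benchmark's standard
    conditions (2x4 outer CV, 3 inner folds, printed hyperparameter grids)."""

    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    l1_ratios: tuple[float, ...] = DEFAULT_L1_RATIOS
    n_folds: int = 4
    n_replicates: int = 2
    inner_folds: int = 3
    seed: int = 0
    max_iter: int = 200
    tol: float = 1e-7
    n_penalty_exempt: int = 0


def make_cv_splits(
    cohort_samples: pd.DataFrame,
    included_samples: pd.Index,
    seed: int,
    n_folds: int = 4,
    n_replicates: int = 2,
) -> SplitPlan:
    """Stratified (cancer type x sample type) fold assignments.

    Strata smaller than ``n_folds`` are merged into the same cancer type's
    largest stratum (or the overall largest if the whole type is small)
    before assignment. Replicates use distinct derived seeds.
    """
    if len(included_samples) < n_folds:
        raise ValueError(
            f"{len(included_samples)} samples is fewer than {n_folds} folds"
        )
    sub = cohort_samples.loc[included_samples]
    strata = sub["cancer_type"].astype(str) + "||" + sub["sample_type"].astype(str)
    counts = strata.value_counts()
    small = counts[counts < n_folds].index
    if len(small) > 0:
        big = counts[counts >= n_folds]
        global_target = big.index[0] if len(big) > 0 else counts.index[0]
        remap = {}
        for s in small:
            ctype = s.split("||", 1)[0]
            same_type = big[[i for i in big.index if i.startswith(ctype + "||")]]
            remap[s] = same_type.index[0] if len(same_type) > 0 else global_target
        strata = strata.replace(remap)

    assignments: dict[tuple[int, int], pd.Index] = {}
    codes = pd.factorize(strata)[0]
    for rep in range(n_replicates):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=child_seed(seed, "split", rep),
        )
        for fold, (_, test_pos) in enumerate(skf.split(np.zeros(len(codes)), codes)):
            assignments[(rep, fold)] = strata.index[test_pos]
    return SplitPlan(
        n_folds=n_folds, n_replicates=n_replicates, strata=strata,
        assignments=assignments, seed=seed,
    )


def permute_labels_stratified(
    labels: pd.Series,
    cancer_types: pd.Series,
    split: tuple[pd.Index, pd.Index],
    seed: int,
) -> pd.Series:
    """Permute labels uniformly within each (cancer type x train/test) cell.

    Per-cell positive counts are preserved exactly, so the null model faces
    the same class balance per cancer type as the true-label model.
    """
    train_idx, test_idx = split
    ct = cancer_types.reindex(labels.index)
    out = labels.copy()
    rng = rng_for(seed, "permute")
    for part_idx in (train_idx, test_idx):
        part_ct = ct.loc[part_idx]
        for t in sorted(part_ct.unique()):
            cell = part_idx[part_ct == t]
            out.loc[cell] = rng.permutation(labels.loc[cell].to_numpy())
    return out


def compute_metrics(scores, labels) -> tuple[float, float]:
    """(AUPR as average precision, AUROC with ties half-credited)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("metrics undefined: labels contain a single class")
    return (
        float(average_precision_score(labels, scores)),
        float(roc_auc_score(labels, scores)),
    )


def _select_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    alphas: Sequence[float],
    l1_ratios: Sequence[float],
    inner_folds: int,
    inner_seed: int,
    model_kwargs: dict,
) -> tuple[float, float]:
    """Inner stratified CV scoring each (alpha, l1_ratio) by mean AUPR.

    Inner folds lacking either class are skipped with a warning; if every
    inner fold skips, raises. Ties resolve to smaller alpha, then larger
    l1_ratio.
    """
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=inner_seed)
    pairs = [(a, l) for a in alphas for l in l1_ratios]
    sums = np.zeros(len(pairs))
    counts = np.zeros(len(pairs), dtype=int)
    any_fold = False
    for tr, va in skf.split(X, y):
        y_tr, y_va = y[tr], y[va]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_va)) < 2:
            warnings.warn("inner fold skipped: single-class labels", stacklevel=2)
            continue
        any_fold = True
        coef, intercept = None, 0.0
        for k, (a, l) in enumerate(pairs):
            model = ElasticNetLogisticRegression(alpha=a, l1_ratio=l, **model_kwargs)
            model.fit(X[tr], y_tr, coef_init=coef, intercept_init=intercept)
            coef, intercept = model.coef_, model.intercept_  # warm start
            aupr, _ = compute_metrics(model.decision_function(X[va]), y_va)
            sums[k] += aupr
            counts[k] += 1
    if not any_fold:
        raise ValueError("all inner folds had single-class labels")
    means = np.where(counts > 0, sums / np.maximum(counts, 1), -np.inf)
    best = max(
        range(len(pairs)), key=lambda k: (means[k], -pairs[k][0], pairs[k][1])
    )
    return pairs[best]


def nested_grid_search(
    X: pd.DataFrame,
    y: pd.Series,
    split_plan: SplitPlan,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    l1_ratios: Sequence[float] = DEFAULT_L1_RATIOS,
    seed: int = 0,
    inner_folds: int = 3,
    model_kwargs: dict | None = None,
    label_override: Callable[[tuple[int, int], pd.Index, pd.Index], pd.Series] | None = None,
) -> list[dict]:
    """Outer-fold evaluation with nested hyperparameter selection.

    For each (replicate, fold): select (alpha, l1_ratio) by inner CV on the
    outer-training set, refit on the full training set, evaluate once on the
    outer test set. ``label_override`` lets the caller substitute labels per
    split (the permuted-label condition) while reusing identical splits.
    Folds whose test set lacks a class are dropped with a warning.
    """
    model_kwargs = dict(model_kwargs or {})
    records: list[dict] = []
    for rep, fold in split_plan.keys():
        train_idx, test_idx = split_plan.train_test(rep, fold)
        y_use = y if label_override is None else label_override((rep, fold), train_idx, test_idx)
        X_tr = X.loc[train_idx].to_numpy(dtype=float)
        y_tr = y_use.loc[train_idx].to_numpy(dtype=float)
        X_te = X.loc[test_idx].to_numpy(dtype=float)
        y_te = y_use.loc[test_idx].to_numpy(dtype=float)
        if len(np.unique(y_te)) < 2:
            warnings.warn(
                f"outer fold (rep={rep}, fold={fold}) dropped: single-class test set",
                stacklevel=2,
            )
            continue
        a, l = _select_hyperparams(
            X_tr, y_tr, alphas, l1_ratios, inner_folds,
            child_seed(seed, "inner", rep, fold), model_kwargs,
        )
        model = ElasticNetLogisticRegression(alpha=a, l1_ratio=l, **model_kwargs)
        model.fit(X_tr, y_tr)
        aupr, auroc = compute_metrics(model.decision_function(X_te), y_te)
        records.append(
            dict(replicate=rep, fold=fold, alpha=a, l1_ratio=l, aupr=aupr,
                 auroc=auroc, n_test_positives=int(y_te.sum()))
        )
    return records


def run_gene_experiment(
    gene: str,
    X: pd.DataFrame,
    labels: pd.Series,
    cohort_samples: pd.DataFrame,
    config: EvalConfig,
    modality_set: str = "",
    split_plan: SplitPlan | None = None,
) -> list[ExperimentResult]:
    """Both conditions (true and permuted labels) on identical splits.

    Emits up to 8 records per condition (2 replicates x 4 folds with the
    default plan); dropped folds are the only source of fewer records.
    """
    if split_plan is None:
        split_plan = make_cv_splits(
            cohort_samples, labels.index, child_seed(config.seed, "splits", gene),
            n_folds=config.n_folds, n_replicates=config.n_replicates,
        )
    model_kwargs = dict(
        max_iter=config.max_iter, tol=config.tol,
        n_penalty_exempt=config.n_penalty_exempt,
    )
    ct = cohort_samples["cancer_type"]
    results: list[ExperimentResult] = []

    def permuted(key, train_idx, test_idx):
        rep, fold = key
        return permute_labels_stratified(
            labels, ct, (train_idx, test_idx),
            child_seed(config.seed, "permute", gene, rep, fold),
        )

    for condition, override in (("true_labels", None), ("permuted_labels", permuted)):
        recs = nested_grid_search(
            X, labels, split_plan,
            alphas=config.alphas, l1_ratios=config.l1_ratios,
            seed=child_seed(config.seed, "search", gene, condition),
            inner_folds=config.inner_folds, model_kwargs=model_kwargs,
            label_override=override,
        )
        results.extend(
            ExperimentResult(gene=gene, modality_set=modality_set,
                             condition=condition, **r)
            for r in recs
        )
    return results


def paired_delta_test(
    a_results: Sequence[ExperimentResult],
    b_results: Sequence[ExperimentResult],
    comparison: str = "vs_permuted",
    metric: str = "aupr",
) -> ComparisonCall:
    """Two-sided paired t-test on fold-matched metric differences (a - b).

    Both inputs must cover exactly the same (replicate, fold) keys; any
    mismatch is an error. All-zero deltas give t=0, p=1; otherwise a 1e-12
    variance floor guards degenerate spreads (flagged).
    """
    a_map = {(r.replicate, r.fold): getattr(r, metric) for r in a_results}
    b_map = {(r.replicate, r.fold): getattr(r, metric) for r in b_results}
    if set(a_map) != set(b_map):
        raise ValueError(
            f"paired keys mismatch: {sorted(set(a_map) ^ set(b_map))}"
        )
    keys = sorted(a_map)
    deltas = np.array([a_map[k] - b_map[k] for k in keys])
    n = deltas.size
    mean = float(deltas.mean())
    degenerate = False
    if np.all(deltas == 0.0):
        t_stat, p = 0.0, 1.0
        degenerate = True
    else:
        var = float(deltas.var(ddof=1))
        if var < 1e-12:
            var = 1e-12
            degenerate = True
        t_stat = mean / np.sqrt(var / n)
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    gene = a_results[0].gene if a_results else ""
    mset = a_results[0].modality_set if a_results else ""
    return ComparisonCall(
        gene=gene, modality_set=mset, comparison=comparison,
        mean_delta_aupr=mean, t_statistic=float(t_stat), p_value=p,
        degenerate=degenerate,
    )


def fdr_correct(
    calls: Iterable[ComparisonCall],
    family: Callable[[ComparisonCall], object] | None = None,
) -> list[ComparisonCall]:
    """Benjamini-Hochberg step-up within each family (default: one family
    per (modality_set, comparison)); attaches q-values and significance
    flags at the corrected 0.05 / 0.01 / 0.001 thresholds."""
    calls = list(calls)
    if family is None:
        family = lambda c: (c.modality_set, c.comparison)
    groups: dict[object, list[ComparisonCall]] = {}
    for c in calls:
        groups.setdefault(family(c), []).append(c)
    for members in groups.values():
        pvals = [c.p_value for c in members]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for c, q in zip(members, qvals):
            c.q_value = float(max(q, c.p_value))  # BH q never below p
            c.significant_at = {t for t in SIGNIFICANCE_THRESHOLDS if c.q_value <= t}
    return calls


def call_summary_grid(
    results: Sequence[ExperimentResult],
    corrected_threshold: float = 0.001,
    equivalence_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (gene x modality) summary: well-predicted and equivalent-to-best.

    well_predicted: significant vs the permuted baseline at the corrected
    threshold AND positive mean delta AUPR (the sign guard keeps
    permuted-better-than-true genes out). Baseline tests are BH-corrected
    within each modality family. best modality per gene = highest mean delta
    AUPR; equivalence = not significantly different from best under pairwise
    paired t-tests on fold deltas, BH-corrected within the gene.
    """
    by_key: dict[tuple[str, str, str], list[ExperimentResult]] = {}
    for r in results:
        by_key.setdefault((r.gene, r.modality_set, r.condition), []).append(r)

    pairs = sorted({(g, m) for g, m, _ in by_key})
    baseline_calls = []
    for g, m in pairs:
        true_r = by_key.get((g, m, "true_labels"), [])
        perm_r = by_key.get((g, m, "permuted_labels"), [])
        baseline_calls.append(paired_delta_test(true_r, perm_r, "vs_permuted"))
    fdr_correct(baseline_calls, family=lambda c: c.modality_set)
    call_map = {(c.gene, c.modality_set): c for c in baseline_calls}

    # fold-wise deltas (true - own permuted baseline) per gene x modality
    def deltas(g, m):
        t = {(r.replicate, r.fold): r.aupr for r in by_key[(g, m, "true_labels")]}
        p = {(r.replicate, r.fold): r.aupr for r in by_key[(g, m, "permuted_labels")]}
        keys = sorted(set(t) & set(p))
        return np.array([t[k] - p[k] for k in keys]), keys

    rows = []
    genes = sorted({g for g, _ in pairs})
    for g in genes:
        mods = sorted(m for gg, m in pairs if gg == g)
        mean_delta = {m: float(deltas(g, m)[0].mean()) for m in mods}
        best = max(mods, key=lambda m: mean_delta[m])
        # pairwise equivalence vs the best modality, BH within this gene
        pvals = {}
        for m in mods:
            if m == best:
                continue
            d_m, k_m = deltas(g, m)
            d_b, k_b = deltas(g, best)
            if k_m != k_b:
                raise ValueError(f"fold keys differ between {m} and {best} for {g}")
            dd = d_m - d_b
            if np.all(dd == 0.0):
                pvals[m] = 1.0
            else:
                var = max(float(dd.var(ddof=1)), 1e-12)
                t_stat = dd.mean() / np.sqrt(var / dd.size)
                pvals[m] = float(2.0 * stats.t.sf(abs(t_stat), df=dd.size - 1))
        if pvals:
            _, qvals, _, _ = multipletests(list(pvals.values()), method="fdr_bh")
            qmap = dict(zip(pvals, qvals))
        else:
            qmap = {}
        for m in mods:
            call = call_map[(g, m)]
            well = (call.q_value <= corrected_threshold) and (call.mean_delta_aupr > 0)
            equiv = (m == best) or (qmap.get(m, 1.0) > equivalence_alpha)
            rows.append(
                dict(gene=g, modality=m, mean_delta_aupr=mean_delta[m],
                     p_value=call.p_value, q_value=call.q_value,
                     well_predicted=bool(well), best_modality=best == m,
                     equivalent_to_best=bool(equiv))
            )
    return pd.DataFrame(rows)


def concordance_index(scores, times, events) -> float:
    """Censored concordance index; higher score must predict shorter
    survival. Ties in score credit 1/2; censored-before-comparison pairs are
    excluded."""
    events = np.asarray(events).astype(bool)
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if times.size == 0 or not events.any():
        raise ValueError("c-index undefined: no admissible pairs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cindex, concordant, discordant, tied_risk, _ = concordance_index_censored(
            events, times, scores
        )
    if np.isnan(cindex):
        raise ValueError("c-index undefined: no admissible pairs")
    return float(cindex)


def run_survival_experiment(
    feature_sets: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
    cohort_samples: pd.DataFrame,
    survival: pd.DataFrame,
    k_values: Sequence[int] = (10,),
    config: EvalConfig | None = None,
    cox_alphas: Sequence[float] = DEFAULT_COX_ALPHAS,
    l1_ratios: Sequence[float] = DEFAULT_L1_RATIOS,
) -> pd.DataFrame:
    """Cross-validated elastic-net Cox benchmark per modality and PC count.

    ``feature_sets`` maps modality name -> standardized sample x feature
    matrix (PC extraction happens here per k). A covariate-only baseline
    (age, log10 burden, one-hot cancer type) runs once. Splits are the same
    stratified 2x4 plan as mutation prediction; inner 3-fold selection is
    scored by c-index. Folds with zero test events are dropped with a
    warning.
    """
    from .features import pca_compress  # local import avoids cycle

    config = config or EvalConfig()
    index = survival.index
    plan = make_cv_splits(
        cohort_samples, index, child_seed(config.seed, "surv_splits"),
        n_folds=config.n_folds, n_replicates=config.n_replicates,
    )
    time = survival["time"]
    event = survival["event"]

    designs: list[tuple[str, int | None, pd.DataFrame]] = [
        ("covariates_only", None, covariates.loc[index].astype(float))
    ]
    for name, mat in feature_sets.items():
        for k in k_values:
            scores_k, _ = pca_compress(mat.loc[index], k)
            X = pd.concat([scores_k, covariates.loc[index].astype(float)], axis=1)
            designs.append((name, k, X))

    pairs = [(a, l) for a in cox_alphas for l in l1_ratios]
    rows = []
    for name, k, X in designs:
        for rep, fold in plan.keys():
            train_idx, test_idx = plan.train_test(rep, fold)
            if int(event.loc[test_idx].sum()) == 0 or int(event.loc[train_idx].sum()) == 0:
                warnings.warn(
                    f"survival fold (rep={rep}, fold={fold}) dropped: no events",
                    stacklevel=2,
                )
                continue
            X_tr = X.loc[train_idx].to_numpy(dtype=float)
            y_tr = (time.loc[train_idx].to_numpy(), event.loc[train_idx].to_numpy())
            # inner selection by mean c-index, stratified on event indicator
            skf = StratifiedKFold(
                n_splits=config.inner_folds, shuffle=True,
                random_state=child_seed(config.seed, "surv_inner", name, k, rep, fold),
            )
            sums = np.zeros(len(pairs))
            counts = np.zeros(len(pairs), dtype=int)
            ev_tr = y_tr[1].astype(int)
            for tr, va in skf.split(X_tr, ev_tr):
                if ev_tr[va].sum() == 0 or ev_tr[tr].sum() == 0:
                    continue
                coef = None
                for i, (a, l) in enumerate(pairs):
                    m = CoxElasticNet(alpha=a, l1_ratio=l, max_iter=config.max_iter,
                                      tol=config.tol,
                                      n_penalty_exempt=config.n_penalty_exempt)
                    m.fit(X_tr[tr], (y_tr[0][tr], y_tr[1][tr]), coef_init=coef)
                    coef = m.coef_
                    try:
                        ci = concordance_index(m.predict(X_tr[va]), y_tr[0][va], y_tr[1][va])
                    except ValueError:
                        continue
                    sums[i] += ci
                    counts[i] += 1
            means = np.where(counts > 0, sums / np.maximum(counts, 1), -np.inf)
            best = max(range(len(pairs)), key=lambda i: (means[i], -pairs[i][0], pairs[i][1]))
            a, l = pairs[best]
            model = CoxElasticNet(alpha=a, l1_ratio=l, max_iter=config.max_iter,
                                  tol=config.tol,
                                  n_penalty_exempt=config.n_penalty_exempt)
            model.fit(X_tr, y_tr)
            ci = concordance_index(
                model.predict(X.loc[test_idx].to_numpy(dtype=float)),
                time.loc[test_idx].to_numpy(), event.loc[test_idx].to_numpy(),
            )
            rows.append(dict(modality=name, k=k, replicate=rep, fold=fold,
                             cindex=ci, alpha=a, l1_ratio=l,
                             n_test_events=int(event.loc[test_idx].sum())))
    return pd.DataFrame(rows)
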