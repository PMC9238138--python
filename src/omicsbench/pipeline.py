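"""High-level pipeline runs: many genes x modality sets, end to end.

These functions glue labels -> features -> model -> evaluation for whole
gene lists, in the whole-dataset ("paper_faithful") preprocessing scope:
variability selection and standardization are fitted once on the full sample
intersection, then rows are sliced per gene. The leakage-safe per-fold scope
is available through the features module directly and is exercised in the
test suite's recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .evaluation import (
    EvalConfig,
    ExperimentResult,
    call_summary_grid,
    fdr_correct,
    paired_delta_test,
    run_gene_experiment,
    run_survival_experiment,
)
from .features import assemble_feature_matrix, build_covariates, standardize
from .labels import GeneAnnotation, make_label_set
from .synthetic import DEFAULT_PFI_TYPES, OmicsDataset, resolve_endpoint

__all__ = ["MutationBenchmarkOutput", "run_mutation_benchmark", "run_survival_benchmark"]


@dataclass
class MutationBenchmarkOutput:
    results: list[ExperimentResult]
    calls: list  # FDR-corrected vs-permuted ComparisonCalls
    grid: pd.DataFrame
    skipped: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def _preprocess(
    datasets: Sequence[OmicsDataset],
    mode: str,
    per_dataset_k,
) -> dict[str, pd.DataFrame]:
    """Whole-dataset preprocessing per modality (deviation-select +
    standardize for raw mode; the PCA happens at assembly for pca mode)."""
    from .features import pca_compress, select_top_mad

    out = {}
    for ds in datasets:
        m = ds.matrix
        k = per_dataset_k.get(ds.name) if isinstance(per_dataset_k, dict) else per_dataset_k
        if mode == "raw":
            if k is not None and k < m.shape[1]:
                m = select_top_mad(m, k)
            m, _ = standardize(m)
        elif mode == "pca":
            m, _ = standardize(m)
            m, _ = pca_compress(m, k if k is not None else m.shape[1])
            m = m.add_prefix(f"{ds.name}_")
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out[ds.name] = m
    return out


def run_mutation_benchmark(
    datasets: Sequence[OmicsDataset],
    clinical: pd.DataFrame,
    mutations: pd.DataFrame,
    cnv: pd.DataFrame,
    targets: Sequence[GeneAnnotation],
    config: EvalConfig | None = None,
    mode: str = "raw",
    per_dataset_k=None,
    min_mutated: int = 15,
    min_fraction: float = 0.05,
    combine: bool = False,
    corrected_threshold: float = 0.001,
    n_jobs: int = 1,
) -> MutationBenchmarkOutput:
    """Run every (target gene x modality set) experiment and summarize.

    ``combine=True`` concatenates all datasets into one multi-omics feature
    matrix (one modality_set named ``a+b+...``); otherwise each dataset is
    benchmarked on its own. Genes without a valid cancer type are skipped
    with a recorded reason; unexpected per-gene failures are collected in
    ``errors`` (nonzero CLI exit).
    """
    config = config or EvalConfig()
    processed = _preprocess(datasets, mode, per_dataset_k)
    if combine:
        joint = pd.concat(
            [processed[ds.name] for ds in datasets], axis=1
        )
        modality_sets = {"+".join(ds.name for ds in datasets): joint}
    else:
        modality_sets = {ds.name: processed[ds.name] for ds in datasets}

    burdens = clinical["n_mutations"]
    ctypes = clinical["cancer_type"]
    results: list[ExperimentResult] = []
    skipped: dict[str, str] = {}
    errors: dict[str, str] = {}

    def one_gene(target):
        # per-gene work unit; seeds derive from (config.seed, gene), so
        # results are independent of execution order and of n_jobs
        ls = make_label_set(
            target, mutations, cnv, ctypes, burdens,
            min_mutated=min_mutated, min_fraction=min_fraction,
        )
        if ls is None:
            return [], {target.gene: "no valid cancer types"}, {}
        cov = build_covariates(clinical, ls.included_samples)
        recs, errs = [], {}
        for mset_name, matrix in modality_sets.items():
            X = pd.concat([matrix.loc[ls.included_samples], cov], axis=1)
            try:
                recs.extend(
                    run_gene_experiment(
                        target.gene, X, ls.labels, clinical, config,
                        modality_set=mset_name,
                    )
                )
            except ValueError as exc:  # pragma: no cover - defensive
                errs[f"{target.gene}|{mset_name}"] = str(exc)
        return recs, {}, errs

    if n_jobs != 1:
        from joblib import Parallel, delayed

        gene_outputs = Parallel(n_jobs=n_jobs)(
            delayed(one_gene)(t) for t in targets
        )
    else:
        gene_outputs = [one_gene(t) for t in targets]
    for recs, skips, errs in gene_outputs:
        results.extend(recs)
        skipped.update(skips)
        errors.update(errs)

    by_key: dict[tuple[str, str], dict[str, list[ExperimentResult]]] = {}
    for r in results:
        by_key.setdefault((r.gene, r.modality_set), {}).setdefault(r.condition, []).append(r)
    calls = [
        paired_delta_test(conds.get("true_labels", []), conds.get("permuted_labels", []))
        for conds in by_key.values()
    ]
    fdr_correct(calls, family=lambda c: c.modality_set)
    grid = call_summary_grid(results, corrected_threshold=corrected_threshold)
    return MutationBenchmarkOutput(
        results=results, calls=calls, grid=grid, skipped=skipped, errors=errors
    )


def run_survival_benchmark(
    datasets: Sequence[OmicsDataset],
    clinical: pd.DataFrame,
    survival_raw: pd.DataFrame,
    k_values: Sequence[int] = (10,),
    config: EvalConfig | None = None,
    cox_alphas=None,
    l1_ratios=None,
    pfi_types=DEFAULT_PFI_TYPES,
) -> pd.DataFrame:
    """Survival benchmark: endpoint resolution, standardized-PCA features per
    modality and k, covariate-only baseline, c-index per fold."""
    from .evaluation import DEFAULT_COX_ALPHAS, DEFAULT_L1_RATIOS

    config = config or EvalConfig()
    survival = resolve_endpoint(survival_raw, clinical["cancer_type"], pfi_types)
    feature_sets = {}
    for ds in datasets:
        m, _ = standardize(ds.matrix)
        feature_sets[ds.name] = m
    covariates = build_covariates(clinical, survival.index)
    covariates["age"] = clinical.loc[survival.index, "age"].astype(float)
    return run_survival_experiment(
        feature_sets, covariates, clinical, survival,
        k_values=k_values, config=config,
        cox_alphas=cox_alphas if cox_alphas is not None else DEFAULT_COX_ALPHAS,
        l1_ratios=l1_ratios if l1_ratios is not None else DEFAULT_L1_RATIOS,
    )
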