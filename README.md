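# omicsbench

Benchmarking -omics readouts as predictors of cancer driver-gene mutation
status and patient survival.

## The problem

When a driver gene is mutated, the downstream consequences can surface in
gene expression, DNA methylation, protein abundance, microRNA levels, or
somatic mutation patterns. Which readout carries the strongest signature of
a given mutation — and whether several carry the *same* signature — matters
for anyone designing a functional-genomics study and choosing what to
profile. `omicsbench` frames this as a prediction benchmark: for each
recurrently mutated cancer gene, train a classifier on each -omics data
type to predict which tumors carry a non-silent mutation in that gene, and
compare the readouts by how well they predict.

The package is for computational-biology practitioners who want this
benchmark as a tested, reusable pipeline — runnable end-to-end on synthetic
cohorts with planted, controllable signal, and applicable to real
sample × feature tables in the same formats.

## The method

For gene *g* with binary labels *y* (mutation presence/absence, including
deep copy-number gains for oncogenes and losses for tumor suppressors) and
feature matrix *X* (one -omics readout plus one-hot cancer type and
log₁₀ mutation-burden covariates), an elastic-net logistic regression finds

&nbsp;&nbsp;&nbsp;&nbsp;ŵ = argmin<sub>w</sub> ℓ(X, y; w) + αλ‖w‖₁ + ½α(1−λ)‖w‖₂²

with ℓ the mean logistic negative log-likelihood, α the penalty strength
and λ the L1 fraction. Performance is AUPR over two replicates of 4-fold
cross-validation stratified by cancer type and sample type, with (α, λ)
chosen per fold by 3-fold nested grid search. Each gene × readout result is
compared against a *permuted-label null* — labels shuffled within each
(cancer type × train/test) cell, preserving class balance exactly, with the
full hyperparameter search re-run — using paired t-tests across the eight
fold-matched measurements and Benjamini–Hochberg FDR correction. A gene is
*well-predicted* by a readout when it beats its permuted baseline at the
corrected threshold with a positive mean AUPR difference. Parallel
machinery benchmarks survival prediction with elastic-net Cox models scored
by the censored concordance index against a covariate-only baseline, and
multi-omics "early integration" by concatenating feature blocks.

A synthetic cohort generator produces everything the pipeline consumes —
clinical tables, mutation and GISTIC-style CNV matrices, continuous /
bounded / nonnegative omics matrices with planted mutation signatures
(optionally mediated by a latent pathway activity shared across modalities,
which makes redundancy between readouts controllable), and censored
proportional-hazards survival times. See `docs/methods.md` for the model
details and generator assumptions.

## Worked example

```python
from omicsbench import (CohortSpec, GeneSpec, ModalitySpec, GeneAnnotation,
                        EvalConfig, generate_cohort, generate_mutation_data,
                        generate_omics, run_mutation_benchmark)

types = {"LUAD": 0.34, "BRCA": 0.33, "COAD": 0.33}
cohort = generate_cohort(CohortSpec(n_samples=800,
                                    cancer_types=tuple(types.items()), seed=0))
genes = [
    # a driver with a strong expression signature...
    GeneSpec(gene="TP53ish", per_type_mutation_prob={t: 0.25 for t in types},
             signal_modalities=frozenset({"expression"}),
             effect_size=2.0, n_signal_features=15),
    # ...and a gene whose mutations leave no trace in expression
    GeneSpec(gene="NULLish", per_type_mutation_prob={t: 0.25 for t in types}),
]
mutations, cnv = generate_mutation_data(cohort, genes, seed=0)
expr = generate_omics(cohort, mutations,
                      ModalitySpec(name="expression", n_features=40), genes, seed=0)

config = EvalConfig(alphas=(0.001, 0.01, 0.1), l1_ratios=(0.0, 0.5, 1.0), seed=0)
out = run_mutation_benchmark(
    [expr], cohort.samples, mutations, cnv,
    [GeneAnnotation(g.gene, "oncogene") for g in genes], config,
)
print(out.grid[["gene", "modality", "mean_delta_aupr", "q_value", "well_predicted"]]
      .to_string(index=False))
```

Output:

```
   gene   modality  mean_delta_aupr      q_value  well_predicted
NULLish expression         0.022932 1.419593e-01           False
TP53ish expression         0.749507 4.008063e-11            True
```

The planted driver beats its permuted-label baseline by 0.75 AUPR on
average across the eight folds (FDR-corrected q ≈ 4e-11, well below the
0.001 call threshold), while the no-signal gene shows a small,
non-significant difference — the permuted null absorbing whatever a
flexible classifier can squeeze out of noise.

## Command line

```bash
omicsbench simulate      --config cohort.yaml --out data/ --seed 1
omicsbench build-labels  --config run.yaml    --out labels/
omicsbench run-mutation  --config run.yaml    --out results/
omicsbench run-multiomics --config run.yaml   --out results_multi/
omicsbench run-survival  --config run.yaml    --out results_surv/
omicsbench summarize     --results results/   --out summary/
```

All tables are TSV with explicit headers; every run writes a JSON manifest
with its resolved configuration and a content hash, and every output is
reproducible bit-for-bit from (inputs, config, seed).

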