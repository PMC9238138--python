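import numpy as np
import pandas as pd
import pytest

from omicsbench.labels import GeneAnnotation
from omicsbench.synthetic import (
    CohortSpec,
    GeneSpec,
    ModalitySpec,
    generate_cohort,
    generate_mutation_data,
    generate_omics,
)

THREE_TYPES = ("LUAD", "BRCA", "COAD")


def make_bundle(
    n_samples=400,
    genes=(),
    n_features=30,
    seed=0,
    hypermutated_fraction=0.0,
    extra_modalities=(),
):
    """Small synthetic bundle: cohort + mutation/CNV matrices + omics."""
    spec = CohortSpec(
        n_samples=n_samples,
        cancer_types=(("LUAD", 0.34), ("BRCA", 0.33), ("COAD", 0.33)),
        hypermutated_fraction=hypermutated_fraction,
        seed=seed,
    )
    cohort = generate_cohort(spec)
    mutations, cnv = generate_mutation_data(cohort, list(genes), seed)
    datasets = [
        generate_omics(
            cohort, mutations, ModalitySpec(name="expression", n_features=n_features),
            list(genes), seed,
        )
    ]
    for m in extra_modalities:
        datasets.append(generate_omics(cohort, mutations, m, list(genes), seed))
    return cohort, mutations, cnv, datasets


@pytest.fixture(scope="session")
def small_planted_bundle():
    """400 samples, one gene planted in expression only (strong effect)."""
    genes = [
        GeneSpec(
            gene="G1",
            per_type_mutation_prob={t: 0.25 for t in THREE_TYPES},
            signal_modalities=frozenset({"expression"}),
            effect_size=2.0,
            n_signal_features=15,
        )
    ]
    cohort, mutations, cnv, datasets = make_bundle(genes=genes, seed=7)
    return dict(
        cohort=cohort, mutations=mutations, cnv=cnv, datasets=datasets,
        annotations=[GeneAnnotation(gene="G1", role="oncogene")],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
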