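"""Mutation-status label construction.

Binary labels for "is gene G mutated in sample i": a sample is positive if it
carries a non-silent somatic variant in the target gene, or a deep copy-number
gain for oncogenes, or a deep copy-number loss for tumor suppressors (genes
annotated as both qualify through either event). Hypermutated samples
(non-silent burden >= mean + 5 SD) are removed before labeling to limit
passenger-mutation false positives. A cancer type is "valid" for a gene when
it contributes at least ``min_mutated`` and at least ``min_fraction`` mutated
samples; experiments run only on samples from valid types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import rng_for

__all__ = [
    "GeneAnnotation",
    "LabelSet",
    "NON_SILENT_CLASSES",
    "detect_hypermutated",
    "maf_to_mutation_matrix",
    "merge_gene_sets",
    "build_mutation_labels",
    "compute_valid_cancer_types",
    "build_control_gene_set",
    "make_label_set",
]

#: Variant classes counted as non-silent when collapsing a MAF-like variant
#: table to a binary sample x gene matrix.
NON_SILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

ROLES = ("oncogene", "tsg", "both", "fusion_only")
_SOURCE_ROLE_TOKENS = {"oncogene", "tsg", "fusion"}


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    role: str
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"gene {self.gene}: unknown role {self.role!r}")


@dataclass
class LabelSet:
    """Labels for one target gene, restricted to its valid cancer types."""

    target_gene: str
    labels: pd.Series  # {0,1}, indexed by included samples
    included_samples: pd.Index
    valid_cancer_types: list[str]
    provenance: dict[str, int] = field(default_factory=dict)


def detect_hypermutated(
    burdens: Mapping[str, float] | pd.Series, n_sd: float = 5.0, ddof: int = 1
) -> set[str]:
    """Samples whose non-silent mutation count is >= mean + ``n_sd`` * SD.

    Mean and SD are computed over all samples before any exclusion; SD uses
    the sample (n-1) estimator by default. The threshold is inclusive, except
    in the degenerate all-equal case (SD = 0), where nothing is excluded.
    """
    s = pd.Series(burdens, dtype=float)
    if s.empty:
        raise ValueError("burdens is empty")
    if len(s) < 2:
        raise ValueError("need at least 2 samples")
    if (s < 0).any():
        raise ValueError("burdens must be nonnegative")
    sd = float(s.std(ddof=ddof))
    if sd == 0.0:
        return set()
    threshold = float(s.mean()) + n_sd * sd
    return set(s.index[s >= threshold])


def maf_to_mutation_matrix(
    variants: pd.DataFrame,
    samples: Sequence[str] | pd.Index | None = None,
    non_silent_classes: frozenset[str] | set[str] = NON_SILENT_CLASSES,
) -> pd.DataFrame:
    """Collapse a MAF-like variant table to a binary sample x gene matrix.

    ``variants`` needs columns ``sample, gene, variant_classification``; only
    rows whose class is in ``non_silent_classes`` count. ``samples`` extends
    the row axis to samples with zero non-silent variants (otherwise only
    samples present in the table appear).
    """
    required = {"sample", "gene", "variant_classification"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    hits = variants[variants["variant_classification"].isin(non_silent_classes)]
    matrix = (
        pd.crosstab(hits["sample"], hits["gene"]).clip(upper=1).astype(np.int8)
    )
    if samples is not None:
        matrix = matrix.reindex(pd.Index(samples), fill_value=0)
    genes = sorted(variants["gene"].unique())
    matrix = matrix.reindex(columns=genes, fill_value=0)
    matrix.index.name = "sample_id"
    matrix.columns.name = None
    return matrix


def merge_gene_sets(
    sources: Iterable[tuple[str, str, Iterable[str]]]
) -> list[GeneAnnotation]:
    """Union curated gene sets into one annotation list.

    Each record is ``(source_name, gene, role_tokens)`` with role tokens in
    {oncogene, tsg, fusion}. Genes annotated oncogene in one place and TSG in
    another resolve to ``both``; genes whose only annotation anywhere is
    ``fusion`` are dropped. Output sorted by gene symbol.
    """
    roles: dict[str, set[str]] = {}
    srcs: dict[str, set[str]] = {}
    for source_name, gene, tokens in sources:
        for tok in tokens:
            if tok not in _SOURCE_ROLE_TOKENS:
                raise ValueError(
                    f"unknown role token {tok!r} for gene {gene} in source {source_name}"
                )
            roles.setdefault(gene, set()).add(tok)
        srcs.setdefault(gene, set()).add(source_name)

    out: list[GeneAnnotation] = []
    for gene in sorted(roles):
        r = roles[gene] - {"fusion"}
        if not r:
            continue  # fusion-only
        role = "both" if r == {"oncogene", "tsg"} else next(iter(r))
        out.append(GeneAnnotation(gene=gene, role=role, sources=frozenset(srcs[gene])))
    return out


def build_mutation_labels(
    target: GeneAnnotation,
    mutations: pd.DataFrame,
    cnv: pd.DataFrame,
    excluded: set[str] | Iterable[str] = (),
    gain_threshold: int = 2,
    loss_threshold: int = -2,
) -> pd.Series:
    """Raw binary labels for one target gene (before validity filtering).

    Positive iff non-silent variant, OR CNV call >= ``gain_threshold`` for
    oncogene/both, OR CNV call <= ``loss_threshold`` for tsg/both. Defaults
    restrict to deep events (+/-2). Hypermutated samples are removed before
    labeling. The returned series carries variant/CNV provenance counts in
    ``attrs["provenance"]``.
    """
    g = target.gene
    if g not in mutations.columns or g not in cnv.columns:
        raise KeyError(f"gene {g!r} absent from mutation or CNV matrix")
    keep = mutations.index.difference(pd.Index(list(excluded)))
    mut = mutations.loc[keep, g].astype(bool)
    calls = cnv.loc[keep, g]

    cnv_pos = pd.Series(False, index=keep)
    if target.role in ("oncogene", "both"):
        cnv_pos |= calls >= gain_threshold
    if target.role in ("tsg", "both"):
        cnv_pos |= calls <= loss_threshold

    labels = (mut | cnv_pos).astype(np.int8)
    labels.name = g
    labels.attrs["provenance"] = {
        "n_from_variant": int(mut.sum()),
        "n_from_cnv": int(cnv_pos.sum()),
        "n_from_cnv_only": int((cnv_pos & ~mut).sum()),
    }
    return labels


def compute_valid_cancer_types(
    labels: pd.Series,
    cancer_types: pd.Series,
    min_mutated: int = 15,
    min_fraction: float = 0.05,
) -> list[str]:
    """Cancer types with >= ``min_mutated`` and >= ``min_fraction`` mutated
    samples for this gene (both bounds inclusive). Sorted by type name."""
    ct = cancer_types.reindex(labels.index)
    valid = []
    for t, idx in labels.groupby(ct).groups.items():
        sub = labels.loc[idx]
        n_pos = int(sub.sum())
        if n_pos >= min_mutated and n_pos / len(sub) >= min_fraction:
            valid.append(str(t))
    return sorted(valid)


def build_control_gene_set(
    mutations: pd.DataFrame,
    n_genes: int,
    mode: str,
    seed: int | None = None,
    pool: Sequence[str] | None = None,
) -> list[str]:
    """Control target-gene lists: ``most_mutated`` or ``random``.

    ``most_mutated`` ranks genes by total non-silent mutation count, ties
    broken by symbol order. ``random`` samples uniformly without replacement
    from ``pool`` (the caller's validity-filtered gene list; required), seeded.
    """
    if mode == "most_mutated":
        counts = mutations.sum(axis=0)
        if n_genes > len(counts):
            raise ValueError(f"pool of {len(counts)} genes smaller than {n_genes}")
        order = sorted(counts.index, key=lambda g: (-counts[g], g))
        return order[:n_genes]
    if mode == "random":
        if pool is None:
            raise ValueError("random mode requires a validity-filtered gene pool")
        pool = sorted(pool)
        if n_genes > len(pool):
            raise ValueError(f"pool of {len(pool)} genes smaller than {n_genes}")
        if n_genes == len(pool):
            return list(pool)
        if seed is None:
            raise ValueError("random mode requires a seed")
        rng = rng_for(seed, "control_genes")
        picked = rng.choice(len(pool), size=n_genes, replace=False)
        return [pool[i] for i in sorted(picked)]
    raise ValueError(f"unknown mode {mode!r}")


def make_label_set(
    target: GeneAnnotation,
    mutations: pd.DataFrame,
    cnv: pd.DataFrame,
    cancer_types: pd.Series,
    burdens: pd.Series | None = None,
    min_mutated: int = 15,
    min_fraction: float = 0.05,
    gain_threshold: int = 2,
    loss_threshold: int = -2,
) -> LabelSet | None:
    """End-to-end label construction for one gene.

    Applies the hypermutation filter (when ``burdens`` given), builds raw
    labels, computes valid cancer types, and restricts to their samples.
    Returns None when the gene has no valid cancer type (caller records the
    skip).
    """
    excluded = detect_hypermutated(burdens) if burdens is not None else set()
    raw = build_mutation_labels(
        target, mutations, cnv, excluded, gain_threshold, loss_threshold
    )
    valid = compute_valid_cancer_types(raw, cancer_types, min_mutated, min_fraction)
    if not valid:
        return None
    ct = cancer_types.reindex(raw.index)
    included = raw.index[ct.isin(valid)]
    return LabelSet(
        target_gene=target.gene,
        labels=raw.loc[included],
        included_samples=included,
        valid_cancer_types=valid,
        provenance=dict(raw.attrs.get("provenance", {})),
    )
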