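"""Readers/writers for the pipeline's delimited-table formats plus run
configuration and summaries.

All tables are TSV with an explicit header; matrices carry sample ids in the
first column (CNV is written genes x samples, the GISTIC orientation). Every
run directory gets a JSON manifest with the resolved configuration and its
content hash so outputs are reproducible bit-for-bit from (inputs, config,
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from ._utils import rng_for
from .evaluation import ComparisonCall, ExperimentResult
from .labels import GeneAnnotation
from .synthetic import OmicsDataset

__all__ = [
    "RunConfig",
    "DataBundle",
    "read_tables",
    "write_bundle",
    "write_results",
    "read_results",
    "summarize_run",
    "config_hash",
]

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Resolved run settings; unknown keys in the YAML are rejected."""

    data_dir: str = "."
    modalities: list[str] = field(default_factory=lambda: ["expression"])
    gene_set: str = "merged"  # merged | random | most_mutated | explicit
    genes: list[str] = field(default_factory=list)
    n_control_genes: int = 50
    mode: str = "raw"  # raw | pca
    per_dataset_k: dict[str, int] | None = None
    alphas: list[float] = field(default_factory=lambda: [0.0001, 0.001, 0.01, 0.1, 1.0, 10.0])
    l1_ratios: list[float] = field(default_factory=lambda: [0.0, 0.05, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    min_mutated: int = 15
    min_fraction: float = 0.05
    corrected_p: float = 0.001
    fit_scope: str = "paper_faithful"  # or leakage_safe
    pfi_types: list[str] = field(
        default_factory=lambda: sorted(
            {"BRCA", "DLBC", "LGG", "PCPG", "PRAD", "READ", "TGCT", "THCA", "THYM"}
        )
    )
    k_values: list[int] = field(default_factory=lambda: [10, 100, 500, 1000, 5000])
    cox_alphas: list[float] = field(
        default_factory=lambda: [0.0, 1e-5, 1e-4, 5e-4, 0.001, 0.005, 0.01, 0.05,
                                 0.1, 0.5, 1.0, 10.0, 100.0, 1000.0]
    )
    seed: int = 0
    max_iter: int = 200
    tol: float = 1e-7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def config_hash(config: RunConfig | dict) -> str:
    d = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DataBundle:
    """All input tables intersected to a common sample axis."""

    clinical: pd.DataFrame
    mutations: pd.DataFrame
    cnv: pd.DataFrame
    omics: dict[str, OmicsDataset]
    gene_annotations: list[GeneAnnotation]
    survival: pd.DataFrame | None = None
    dropped_per_type: pd.Series | None = None


def _read_matrix(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()[:5]
        raise ValueError(f"{name}: duplicate sample ids, e.g. {list(dups)}")
    bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad) > 0:
        raise ValueError(f"{name}: non-numeric columns {list(bad[:5])}")
    return df


def write_bundle(
    out_dir: str | Path,
    cohort,
    mutations: pd.DataFrame,
    cnv: pd.DataFrame,
    omics: Sequence[OmicsDataset],
    gene_annotations: Sequence[GeneAnnotation] = (),
    survival: pd.DataFrame | None = None,
    spec_sidecar: dict | None = None,
) -> None:
    """Write a generated cohort in the same formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.samples.to_csv(out / "clinical.tsv", sep="\t", float_format=_FLOAT_FMT)
    mutations.to_csv(out / "mutations.tsv", sep="\t")
    cnv.T.to_csv(out / "cnv.tsv", sep="\t")  # genes x samples, GISTIC-style
    for ds in omics:
        ds.matrix.to_csv(out / f"omics_{ds.name}.tsv", sep="\t", float_format=_FLOAT_FMT)
    if gene_annotations:
        pd.DataFrame(
            [
                dict(gene=a.gene, role=a.role, sources=",".join(sorted(a.sources)))
                for a in gene_annotations
            ]
        ).to_csv(out / "gene_annotations.tsv", sep="\t", index=False)
    if survival is not None:
        survival.to_csv(out / "survival.tsv", sep="\t", float_format=_FLOAT_FMT)
    if spec_sidecar is not None:
        (out / "bundle_spec.json").write_text(
            json.dumps(spec_sidecar, indent=2, sort_keys=True, default=str)
        )


def read_tables(config: RunConfig) -> DataBundle:
    """Load all tables and intersect sample axes across the modality set.

    The intersection spans the clinical table, the mutation matrix, and every
    requested modality; per-cancer-type dropped-sample counts are reported on
    the returned bundle. An empty intersection is an error naming the
    modalities involved.
    """
    d = Path(config.data_dir)
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t", index_col=0)
    if clinical.index.has_duplicates:
        raise ValueError("clinical: duplicate sample ids")
    mutations = _read_matrix(d / "mutations.tsv", "mutations")
    cnv = _read_matrix(d / "cnv.tsv", "cnv").T  # stored genes x samples
    omics: dict[str, OmicsDataset] = {}
    for name in config.modalities:
        m = _read_matrix(d / f"omics_{name}.tsv", name)
        omics[name] = OmicsDataset(name=name, matrix=m)

    common = clinical.index.intersection(mutations.index).intersection(cnv.index)
    for name, ds in omics.items():
        common = common.intersection(ds.matrix.index)
    if len(common) == 0:
        raise ValueError(
            "empty intersection across "
            + ", ".join(["clinical", "mutations", "cnv", *omics])
        )
    dropped = clinical.index.difference(common)
    dropped_per_type = (
        clinical.loc[dropped, "cancer_type"].value_counts()
        if len(dropped) > 0
        else pd.Series(dtype=int)
    )

    clinical = clinical.loc[common]
    mutations = mutations.loc[common]
    cnv = cnv.loc[common]
    for name in list(omics):
        omics[name] = OmicsDataset(name=name, matrix=omics[name].matrix.loc[common])

    annotations: list[GeneAnnotation] = []
    ann_path = d / "gene_annotations.tsv"
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t")
        for _, row in ann.iterrows():
            annotations.append(
                GeneAnnotation(
                    gene=row["gene"], role=row["role"],
                    sources=frozenset(str(row.get("sources", "")).split(",")),
                )
            )
    survival = None
    surv_path = d / "survival.tsv"
    if surv_path.exists():
        survival = pd.read_csv(surv_path, sep="\t", index_col=0).loc[common]
    return DataBundle(
        clinical=clinical, mutations=mutations, cnv=cnv, omics=omics,
        gene_annotations=annotations, survival=survival,
        dropped_per_type=dropped_per_type,
    )


def results_to_frame(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def calls_to_frame(calls: Sequence[ComparisonCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        d = dataclasses.asdict(c)
        d["significant_at"] = ",".join(str(t) for t in sorted(c.significant_at, reverse=True))
        rows.append(d)
    cols = ["gene", "modality_set", "comparison", "mean_delta_aupr", "t_statistic",
            "p_value", "q_value", "significant_at", "degenerate"]
    return pd.DataFrame(rows, columns=cols)


def write_results(
    results: Sequence[ExperimentResult],
    calls: Sequence[ComparisonCall],
    grid: pd.DataFrame | None,
    out_dir: str | Path,
    config: RunConfig | dict | None = None,
) -> dict[str, Path]:
    """Write the long-format results TSV, the calls TSV, the summary grid
    TSV, and a JSON manifest carrying the config hash. Numeric fields are
    written at 17 significant digits so a re-read reproduces them exactly."""
    if not results:
        raise ValueError("results is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["results"] = out / "results.tsv"
    results_to_frame(results).to_csv(paths["results"], sep="\t", index=False,
                                     float_format=_FLOAT_FMT)
    paths["calls"] = out / "calls.tsv"
    calls_to_frame(calls).to_csv(paths["calls"], sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
    if grid is not None:
        paths["grid"] = out / "summary_grid.tsv"
        grid.to_csv(paths["grid"], sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest: dict[str, Any] = {"n_results": len(results), "n_calls": len(calls)}
    if config is not None:
        manifest["config"] = config.to_dict() if isinstance(config, RunConfig) else config
        manifest["config_hash"] = config_hash(config)
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return paths


def read_results(out_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        Path(out_dir) / "results.tsv", sep="\t", float_precision="round_trip"
    )


def summarize_run(
    results: Sequence[ExperimentResult] | pd.DataFrame,
    calls: Sequence[ComparisonCall],
    grid: pd.DataFrame | None = None,
    seed: int = 0,
    n_boot: int = 2000,
) -> dict[str, pd.DataFrame]:
    """Volcano table, per-modality distribution summary with bootstrapped 95%
    CIs of the median delta AUPR (percentile bootstrap, seeded), and
    well-predicted counts per modality."""
    volcano = pd.DataFrame(
        [
            dict(gene=c.gene, modality_set=c.modality_set,
                 mean_delta_aupr=c.mean_delta_aupr,
                 neg_log10_p=float(-np.log10(max(c.p_value, 1e-300))),
                 q_value=c.q_value)
            for c in calls
            if c.comparison == "vs_permuted"
        ]
    )
    rng = rng_for(seed, "bootstrap")
    rows = []
    for mset, sub in volcano.groupby("modality_set"):
        x = sub["mean_delta_aupr"].to_numpy()
        boots = np.median(
            x[rng.integers(0, len(x), size=(n_boot, len(x)))], axis=1
        )
        rows.append(dict(modality_set=mset, n_genes=len(x),
                         median_delta_aupr=float(np.median(x)),
                         ci_low=float(np.percentile(boots, 2.5)),
                         ci_high=float(np.percentile(boots, 97.5))))
    modality_summary = pd.DataFrame(rows)
    counts = None
    if grid is not None and len(grid) > 0:
        counts = (
            grid.groupby("modality")["well_predicted"].sum().rename("n_well_predicted")
            .reset_index()
        )
    out = {"volcano": volcano, "modality_summary": modality_summary}
    if counts is not None:
        out["well_predicted_counts"] = counts
    return out
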