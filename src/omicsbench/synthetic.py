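"""Synthetic multi-omics cohort generator.

Emulates the statistical structure of a pan-cancer tumor atlas at whatever
scale a test or benchmark needs: several cancer types with distinct baseline
-omics profiles, per-gene per-type mutation prevalence, modality-specific
planted mutation signatures (with controllable cross-modality redundancy),
GISTIC-style thresholded copy-number events coupled to driver roles,
long-tailed mutation burden with hypermutated outliers, bounded
methylation-style values with missingness, and survival times under a
proportional-hazards model.

The generative family is a Gaussian latent-factor model with additive mean
shifts for mutated samples, so the detectability of a planted signal by a
linear classifier is analytically controllable. Every generator is a pure
function of (spec, seed); a master seed expands to per-component child seeds
by a fixed hash derivation (see ``_utils.child_seed``), so components can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._utils import check_proportions, rng_for

__all__ = [
    "CohortSpec",
    "GeneSpec",
    "ModalitySpec",
    "SurvivalCoefficients",
    "Cohort",
    "OmicsDataset",
    "generate_cohort",
    "generate_mutation_data",
    "generate_omics",
    "generate_survival",
    "resolve_endpoint",
    "DEFAULT_PFI_TYPES",
]

#: Cancer types whose clinical endpoint defaults to progression-free interval
#: (few observed deaths); all other types use overall survival.
DEFAULT_PFI_TYPES = frozenset(
    {"BRCA", "DLBC", "LGG", "PCPG", "PRAD", "READ", "TGCT", "THCA", "THYM"}
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level parameters.

    Mutation burden (non-silent count per sample) is log10-normal;
    a random ``hypermutated_fraction`` of samples has its count multiplied
    by ``hypermutated_multiplier`` to create the heavy upper tail that the
    5-SD hypermutation filter must catch.
    """

    n_samples: int = 2000
    cancer_types: tuple[tuple[str, float], ...] = (
        ("LUAD", 0.34),
        ("BRCA", 0.33),
        ("COAD", 0.33),
    )
    sample_types: tuple[tuple[str, float], ...] = (
        ("Primary Tumor", 0.92),
        ("Metastatic", 0.08),
    )
    burden_log10_mean: float = 2.0
    burden_log10_sd: float = 0.4
    hypermutated_fraction: float = 0.02
    hypermutated_multiplier: float = 30.0
    age_mean: float = 60.0
    age_sd: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples: must be >= 1")
        check_proportions(self.cancer_types, "cancer_types")
        check_proportions(self.sample_types, "sample_types")
        if not 0.0 <= self.hypermutated_fraction <= 0.2:
            raise ValueError("hypermutated_fraction: must be in [0, 0.2]")
        if self.hypermutated_multiplier <= 1.0:
            raise ValueError("hypermutated_multiplier: must be > 1")


@dataclass(frozen=True)
class GeneSpec:
    """Per-gene generative parameters.

    ``effect_size`` is the additive shift (in noise-SD units) applied to
    ``n_signal_features`` features of each modality in ``signal_modalities``
    for samples carrying a non-silent mutation in the gene. ``effect_size=0``
    defines a null gene.

    Cross-modality redundancy is controllable through ``signal_latent_sd``:
    when zero (default), each modality receives the mutation indicator as a
    deterministic shift, so extra modalities contribute independent replicate
    measurements (concatenating them genuinely reduces noise). When positive,
    the shift is mediated by a per-sample latent pathway activity
    z = effect_size * mutated + N(0, signal_latent_sd), drawn once per gene
    and shared by every modality the gene signals in — each modality then
    reads out the same latent, and the label information is capped by the
    latent's own spread no matter how many modalities are combined.
    """

    gene: str
    role: str = "oncogene"  # {oncogene, tsg, both, fusion_only}
    per_type_mutation_prob: Mapping[str, float] = field(default_factory=dict)
    cnv_gain_prob: float = 0.0
    cnv_loss_prob: float = 0.0
    signal_modalities: frozenset[str] = frozenset()
    effect_size: float = 0.0
    n_signal_features: int = 20
    signal_latent_sd: float = 0.0

    def validate(self, cancer_types: set[str]) -> None:
        for t, p in self.per_type_mutation_prob.items():
            if t not in cancer_types:
                raise ValueError(
                    f"gene {self.gene}: cancer type {t!r} absent from cohort"
                )
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"gene {self.gene}: probability out of [0,1]")
        for p in (self.cnv_gain_prob, self.cnv_loss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"gene {self.gene}: CNV probability out of [0,1]")
        if self.effect_size < 0:
            raise ValueError(f"gene {self.gene}: effect_size must be >= 0")


@dataclass(frozen=True)
class ModalitySpec:
    """One -omics readout's generative parameters.

    ``kind`` controls the output range: ``continuous`` (expression-like),
    ``bounded01`` (methylation-beta-like, logistic squashing of the latent
    Gaussian), ``nonnegative`` (signature-exposure-like, softplus-like via
    exponential of a damped latent).
    """

    name: str
    kind: str = "continuous"  # {continuous, bounded01, nonnegative}
    n_features: int = 100
    n_latent_factors: int = 5
    type_effect_sd: float = 1.0
    factor_sd: float = 0.5
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    n_high_missing_samples: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError(f"modality {self.name}: n_features must be >= 1")
        if self.kind not in {"continuous", "bounded01", "nonnegative"}:
            raise ValueError(f"modality {self.name}: unknown kind {self.kind!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"modality {self.name}: missing_rate out of [0,1]")


@dataclass(frozen=True)
class SurvivalCoefficients:
    """Log-hazard-ratio coefficients of the proportional-hazards generator."""

    age: float = 0.0
    log10_burden: float = 0.0
    factors: tuple[float, ...] = ()


@dataclass
class Cohort:
    """Per-sample metadata table plus the spec that produced it.

    ``samples`` is indexed by sample id with columns
    ``cancer_type, sample_type, n_mutations, age, hypermutated``.
    """

    samples: pd.DataFrame
    spec: CohortSpec

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index


@dataclass
class OmicsDataset:
    """One modality's samples x features matrix (may contain NaN before
    preprocessing) plus generation metadata."""

    name: str
    matrix: pd.DataFrame
    kind: str = "continuous"
    preprocessing_state: list[str] = field(default_factory=list)
    latent_factors: pd.DataFrame | None = None

    @property
    def feature_ids(self) -> pd.Index:
        return self.matrix.columns


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort of samples from the stated mixture proportions."""
    spec.validate()
    rng = rng_for(spec.seed, "cohort")
    n = spec.n_samples

    type_names = [t for t, _ in spec.cancer_types]
    type_props = np.array([p for _, p in spec.cancer_types], dtype=float)
    cancer_type = rng.choice(type_names, size=n, p=type_props / type_props.sum())

    st_names = [t for t, _ in spec.sample_types]
    st_props = np.array([p for _, p in spec.sample_types], dtype=float)
    sample_type = rng.choice(st_names, size=n, p=st_props / st_props.sum())

    burden = 10.0 ** rng.normal(spec.burden_log10_mean, spec.burden_log10_sd, n)
    hyper = np.zeros(n, dtype=bool)
    n_hyper = int(round(spec.hypermutated_fraction * n))
    if n_hyper > 0:
        idx = rng.choice(n, size=n_hyper, replace=False)
        hyper[idx] = True
        burden[idx] *= spec.hypermutated_multiplier
    burden = np.maximum(np.rint(burden).astype(np.int64), 0)

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 100.0)

    ids = [f"S{i:05d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "cancer_type": cancer_type,
            "sample_type": sample_type,
            "n_mutations": burden,
            "age": age,
            "hypermutated": hyper,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return Cohort(samples=samples, spec=spec)


def generate_mutation_data(
    cohort: Cohort, genes: Sequence[GeneSpec], seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the binary non-silent mutation matrix and CNV call matrix.

    Returns ``(mutations, cnv)``, both samples x genes. Mutations are
    per-gene per-type Bernoulli; hypermutated samples get an elevated
    genome-wide rate ``p' = 1 - (1-p)^m`` (probability of at least one hit
    under m-fold exposure), which keeps null genes (p = 0) exactly null.
    CNV calls are in {-2, 0, +2} (deep events), drawn independently of point
    mutations; a single uniform draw decides gain vs loss so the two are
    mutually exclusive per sample.
    """
    if cohort.samples.empty:
        raise ValueError("cohort is empty")
    symbols = [g.gene for g in genes]
    if len(set(symbols)) != len(symbols):
        raise ValueError("gene symbols must be unique")
    types_present = set(cohort.samples["cancer_type"].unique())
    for g in genes:
        g.validate(types_present)

    rng = rng_for(seed, "mutations")
    n = len(cohort.samples)
    ctype = cohort.samples["cancer_type"].to_numpy()
    hyper = cohort.samples["hypermutated"].to_numpy()
    m = cohort.spec.hypermutated_multiplier

    mut = np.zeros((n, len(genes)), dtype=np.int8)
    cnv = np.zeros((n, len(genes)), dtype=np.int8)
    for j, g in enumerate(genes):
        p = np.array([g.per_type_mutation_prob.get(t, 0.0) for t in ctype])
        p = np.where(hyper, 1.0 - (1.0 - p) ** m, p)
        mut[:, j] = rng.random(n) < p
        u = rng.random(n)
        cnv[:, j] = np.where(
            u < g.cnv_gain_prob,
            2,
            np.where(u < g.cnv_gain_prob + g.cnv_loss_prob, -2, 0),
        )
    index = cohort.sample_ids
    return (
        pd.DataFrame(mut, index=index, columns=symbols),
        pd.DataFrame(cnv, index=index, columns=symbols),
    )


def generate_omics(
    cohort: Cohort,
    mutations: pd.DataFrame,
    modality: ModalitySpec,
    genes: Sequence[GeneSpec],
    seed: int,
) -> OmicsDataset:
    """Generate one modality's matrix with planted mutation signatures.

    Matrix = per-(cancer type, feature) baseline offsets + low-rank latent
    factor structure + i.i.d. feature noise; for every gene listing this
    modality, a fixed random subset of features gets an additive
    ``effect_size * noise_sd`` shift in mutated samples. ``bounded01``
    matrices pass the latent values through a logistic squashing map.
    """
    modality.validate()
    rng = rng_for(seed, "omics", modality.name)
    n = len(cohort.samples)
    p = modality.n_features
    ctype = cohort.samples["cancer_type"]
    type_names = sorted(ctype.unique())

    offsets = rng.normal(0.0, modality.type_effect_sd, size=(len(type_names), p))
    type_idx = np.searchsorted(type_names, ctype.to_numpy())
    scores = rng.normal(0.0, 1.0, size=(n, modality.n_latent_factors))
    loadings = rng.normal(0.0, modality.factor_sd, size=(modality.n_latent_factors, p))
    x = offsets[type_idx] + scores @ loadings
    x += rng.normal(0.0, modality.noise_sd, size=(n, p))

    # planted mutation signatures; gene order fixed by symbol so feature
    # subsets do not depend on caller's list ordering
    for g in sorted(genes, key=lambda g: g.gene):
        if modality.name not in g.signal_modalities or g.effect_size == 0:
            continue
        k = min(g.n_signal_features, p)
        feat = rng.choice(p, size=k, replace=False)
        mutated = mutations[g.gene].to_numpy().astype(bool)
        if g.signal_latent_sd > 0:
            # shared latent pathway activity: one draw per (gene, sample),
            # identical across modalities (rng keyed by gene, not modality)
            z = g.effect_size * mutated + rng_for(
                seed, "signal_latent", g.gene
            ).normal(0.0, g.signal_latent_sd, n)
            x[:, feat] += z[:, None] * modality.noise_sd
        else:
            x[np.ix_(mutated, feat)] += g.effect_size * modality.noise_sd

    if modality.kind == "bounded01":
        x = expit(x)
    elif modality.kind == "nonnegative":
        x = np.exp(0.25 * x)

    if modality.missing_rate > 0 or modality.n_high_missing_samples > 0:
        rate = np.full(n, modality.missing_rate)
        if modality.n_high_missing_samples > 0:
            hi = rng.choice(n, size=min(modality.n_high_missing_samples, n), replace=False)
            rate[hi] = min(1.0, 10.0 * max(modality.missing_rate, 0.01))
        mask = rng.random((n, p)) < rate[:, None]
        x = x.astype(float)
        x[mask] = np.nan

    cols = [f"{modality.name}_f{j}" for j in range(p)]
    matrix = pd.DataFrame(x, index=cohort.sample_ids, columns=cols)
    factors = pd.DataFrame(
        scores,
        index=cohort.sample_ids,
        columns=[f"{modality.name}_factor{j}" for j in range(modality.n_latent_factors)],
    )
    return OmicsDataset(
        name=modality.name, matrix=matrix, kind=modality.kind, latent_factors=factors
    )


def _calibrated_censor_rate(times: np.ndarray, censoring_rate: float) -> float:
    """Exponential censoring rate mu with E[fraction censored] ~= censoring_rate.

    Solves mean_i exp(-mu * T_i) = 1 - censoring_rate (the probability that
    an independent Exp(mu) censor time exceeds each drawn event time).
    """
    target = 1.0 - censoring_rate

    def f(log_mu: float) -> float:
        return float(np.mean(np.exp(-np.exp(log_mu) * times))) - target

    lo, hi = -30.0, 30.0
    return float(np.exp(brentq(f, lo, hi, xtol=1e-10)))


def generate_survival(
    cohort: Cohort,
    latent_factors: pd.DataFrame | None,
    coefficients: SurvivalCoefficients,
    censoring_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Draw censored survival endpoints under exponential proportional hazards.

    Linear predictor: beta_age*age + beta_burden*log10(count+1) + gamma.factors
    (centered before exponentiation; centering only rescales the baseline
    hazard). Emits OS-like and PFI-like endpoint pairs driven by the same
    linear predictor (PFI events occur on a 3x faster clock), so the
    per-cancer-type endpoint rule is exercisable downstream via
    :func:`resolve_endpoint`.
    """
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must be in [0, 1)")
    age = cohort.samples["age"].to_numpy()
    burden = np.log10(cohort.samples["n_mutations"].to_numpy() + 1.0)
    eta = coefficients.age * age + coefficients.log10_burden * burden
    if latent_factors is not None and len(coefficients.factors) > 0:
        gamma = np.asarray(coefficients.factors, dtype=float)
        k = min(gamma.size, latent_factors.shape[1])
        eta = eta + latent_factors.to_numpy()[:, :k] @ gamma[:k]
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    eta_c = eta - eta.mean()

    rng = rng_for(seed, "survival")
    out = {"linear_predictor": eta}
    for label, base_rate in (("os", np.log(2) / 1000.0), ("pfi", 3 * np.log(2) / 1000.0)):
        t = rng.exponential(1.0 / (base_rate * np.exp(eta_c)))
        t = np.maximum(t, 1e-8)
        if censoring_rate == 0.0:
            event = np.ones_like(t, dtype=np.int8)
            time = t
        else:
            mu = _calibrated_censor_rate(t, censoring_rate)
            c = rng.exponential(1.0 / mu, size=t.shape)
            time = np.minimum(t, c)
            event = (t <= c).astype(np.int8)
        out[f"{label}_time"] = time
        out[f"{label}_event"] = event
    return pd.DataFrame(out, index=cohort.sample_ids)


def resolve_endpoint(
    survival: pd.DataFrame,
    cancer_types: pd.Series,
    pfi_types: frozenset[str] | set[str] = DEFAULT_PFI_TYPES,
) -> pd.DataFrame:
    """Pick each sample's endpoint: PFI for the configured cancer types
    (defaults to the nine types with few observed deaths), OS otherwise.

    Returns columns ``time, event, endpoint`` aligned to ``survival``'s index.
    """
    ct = cancer_types.reindex(survival.index)
    use_pfi = ct.isin(pfi_types).to_numpy()
    time = np.where(use_pfi, survival["pfi_time"], survival["os_time"])
    event = np.where(use_pfi, survival["pfi_event"], survival["os_event"])
    endpoint = np.where(use_pfi, "PFI", "OS")
    return pd.DataFrame(
        {"time": time, "event": event.astype(np.int8), "endpoint": endpoint},
        index=survival.index,
    )
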