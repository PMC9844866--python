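"""Synthetic LGG-like cohorts with planted molecular subtypes and survival.

The generator emulates the statistical structure a writer-gene prognostic
analysis assumes: two latent molecular subtypes separated by a small set of
informative genes, a large background of uninformative genes, exponentially
distributed overall-survival times whose hazard depends on the informative
signature, independent exponential censoring, and clinical covariates that
track the subtype imperfectly.

Expression is emitted on the log2 scale (genes x samples).  Non-negativity
for NMF is handled downstream by the consensus-clustering shift rule, not
here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CohortIOError

__all__ = [
    "CohortConfig",
    "ExpressionMatrix",
    "ClinicalTable",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: categorical clinical covariates generated alongside age
CATEGORICAL_COVARIATES = (
    "gender",
    "grade",
    "IDH_status",
    "1p19q_status",
    "MGMTp_status",
    "Chemo_status",
    "Radio_status",
)

#: baseline log2 expression of every gene before subtype shifts
BASELINE_LOG2_MEAN = 8.0


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic two-subtype survival cohort.

    effect_size is the mean shift of informative genes in subtype 2, in
    units of the within-group standard deviation ``noise_sd``.
    baseline_hazard and censoring_rate are exponential rates in events per
    year; log_hazard_ratio is the per-unit effect of the latent risk score
    (standardized mean informative-gene expression) on the log hazard.
    covariate_flip_prob is the probability that a categorical clinical
    covariate disagrees with the sample's true subtype.
    """

    n_samples: int = 300
    n_genes: int = 500
    n_informative: int = 20
    subtype_proportion: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_hazard: float = 0.12
    log_hazard_ratio: float = 1.0
    censoring_rate: float = 0.08
    covariate_flip_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_samples >= 1, "n_samples must be a positive integer"),
            (self.n_genes >= 1, "n_genes must be a positive integer"),
            (0 <= self.n_informative <= self.n_genes,
             "n_informative must satisfy 0 <= n_informative <= n_genes"),
            (0.0 < self.subtype_proportion < 1.0,
             "subtype_proportion must lie in (0, 1)"),
            (self.effect_size >= 0, "effect_size must be nonnegative"),
            (self.noise_sd > 0, "noise_sd must be positive"),
            (self.baseline_hazard > 0, "baseline_hazard must be positive"),
            (self.censoring_rate >= 0, "censoring_rate must be nonnegative"),
            (0 <= self.covariate_flip_prob < 0.5,
             "covariate_flip_prob must lie in [0, 0.5)"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigurationError(message)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale expression with identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        # C-contiguous layout so reductions are bit-reproducible regardless
        # of whether values came from the generator or a parsed TSV
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        """Row-subset by gene id, preserving the requested order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


@dataclass
class SyntheticCohort:
    """A generated cohort together with its ground truth."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame
    true_subtype: np.ndarray
    true_informative_genes: list[str]
    true_risk: np.ndarray
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        if list(self.clinical["sample_id"]) != list(self.expression.sample_ids):
            raise ValueError("expression and clinical sample ids differ")


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort from the planted two-subtype survival model.

    Background genes are i.i.d. Gaussian with mean ``BASELINE_LOG2_MEAN``
    and sd ``noise_sd`` in both subtypes; informative genes gain
    ``effect_size * noise_sd`` in subtype 2.  Survival is exponential with
    rate ``baseline_hazard * exp(log_hazard_ratio * true_risk)`` where
    true_risk is the standardized per-sample mean of informative-gene
    expression; censoring is independent exponential at ``censoring_rate``
    (0 means no censoring).  Identical config implies a bit-identical
    cohort.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    gene_ids = [f"G{i + 1:04d}" for i in range(g)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # subtype 2 is the planted high-expression (and, with log_hazard_ratio
    # > 0, high-risk) group
    subtype = np.where(rng.random(n) < config.subtype_proportion, 1, 2)
    informative = list(rng.choice(g, size=config.n_informative, replace=False))
    informative_ids = [gene_ids[i] for i in sorted(informative)]

    values = rng.normal(BASELINE_LOG2_MEAN, config.noise_sd, size=(g, n))
    shift = config.effect_size * config.noise_sd
    values[np.ix_(sorted(informative), np.flatnonzero(subtype == 2))] += shift

    if config.n_informative > 0:
        mean_inf = values[sorted(informative)].mean(axis=0)
        sd = mean_inf.std()
        true_risk = (mean_inf - mean_inf.mean()) / sd if sd > 0 else np.zeros(n)
    else:
        true_risk = np.zeros(n)

    rate = config.baseline_hazard * np.exp(config.log_hazard_ratio * true_risk)
    event_time = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_years = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    age = np.round(rng.normal(45.0, 10.0, size=n), 1)
    clinical = pd.DataFrame({"sample_id": sample_ids,
                             "os_years": os_years,
                             "os_event": os_event,
                             "age": age})
    # categorical covariates copy the subtype label and flip independently
    # with covariate_flip_prob, so clinical features differ by subtype
    for name in CATEGORICAL_COVARIATES:
        flip = rng.random(n) < config.covariate_flip_prob
        level = np.where(flip, 3 - subtype, subtype)
        clinical[name] = [f"{name}_L{v}" for v in level]

    expression = ExpressionMatrix(gene_ids, sample_ids, values)
    return SyntheticCohort(expression, clinical, subtype, informative_ids,
                           true_risk, config)


def _repr_float(v) -> str:
    """Shortest decimal representation that round-trips a float64."""
    return repr(float(v))


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with lossless (round-trip) float formatting."""
    frame.to_csv(path, sep="\t", index=index, float_format=_repr_float)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write expression/clinical TSVs and a ground-truth JSON.

    Round-trips losslessly: floats are printed with shortest round-trip
    repr.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.json",
    }
    frame = cohort.expression.to_frame()
    frame.index.name = "gene_id"
    write_tsv(frame, paths["expression"], index=True)
    write_tsv(cohort.clinical, paths["clinical"])
    truth = {
        "true_subtype": [int(v) for v in cohort.true_subtype],
        "true_informative_genes": list(cohort.true_informative_genes),
        "true_risk": [float(v) for v in cohort.true_risk],
        "config": asdict(cohort.config) if cohort.config is not None else None,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples expression TSV (first column gene ids)."""
    path = Path(path)
    if not path.exists():
        raise CohortIOError(f"expression file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)].tolist()
        raise CohortIOError(f"missing values in {path} for genes: {bad[:10]}")
    return ExpressionMatrix.from_frame(frame)


def read_clinical(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortIOError(f"clinical file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    clinical = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"sample_id", "os_years", "os_event"}
    missing = required - set(clinical.columns)
    if missing:
        raise CohortIOError(f"clinical file {path} lacks columns: {sorted(missing)}")
    return clinical


def align_cohort(expression: ExpressionMatrix, clinical: pd.DataFrame) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Check sample agreement and order clinical rows to match expression.

    Samples with incomplete clinical information (missing survival time or
    event) are rejected rather than silently dropped.
    """
    expr_ids = list(expression.sample_ids)
    clin_ids = list(clinical["sample_id"].astype(str))
    missing_in_clinical = sorted(set(expr_ids) - set(clin_ids))
    missing_in_expression = sorted(set(clin_ids) - set(expr_ids))
    if missing_in_clinical or missing_in_expression:
        raise CohortIOError(
            "sample mismatch between expression and clinical tables: "
            f"absent from clinical {missing_in_clinical[:10]}, "
            f"absent from expression {missing_in_expression[:10]}"
        )
    clinical = clinical.copy()
    clinical["sample_id"] = clinical["sample_id"].astype(str)
    clinical = clinical.set_index("sample_id").loc[expr_ids].reset_index()
    if clinical[["os_years", "os_event"]].isna().any().any():
        bad = clinical.loc[clinical[["os_years", "os_event"]].isna().any(axis=1),
                           "sample_id"].tolist()
        raise CohortIOError(f"incomplete survival information for samples: {bad[:10]}")
    return expression, clinical


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    expression = read_expression(directory / "expression.tsv")
    clinical = read_clinical(directory / "clinical.tsv")
    expression, clinical = align_cohort(expression, clinical)
    truth_path = directory / "truth.json"
    if not truth_path.exists():
        raise CohortIOError(f"truth file not found: {truth_path}")
    truth = json.loads(truth_path.read_text())
    config = CohortConfig(**truth["config"]) if truth.get("config") else None
    return SyntheticCohort(
        expression,
        clinical,
        np.asarray(truth["true_subtype"], dtype=int),
        list(truth["true_informative_genes"]),
        np.asarray(truth["true_risk"], dtype=float),
        config,
    )
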