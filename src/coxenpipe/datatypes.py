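"""Core domain containers shared across pipeline stages.

The containers are thin, validated wrappers around pandas objects: an
:class:`ExpressionPanel` is a genes x samples matrix of log-scale expression,
a :class:`DrugActivityProfile` is a per-cell-line sensitivity vector on the
"higher = more sensitive" scale (the role of -log10(GI50)), and a
:class:`PatientCohort` bundles tumour expression with pCR/RD response,
optional censored survival, and optional receptor-subtype flags.

Trained artifacts (:class:`DrugModel`, :class:`CombinationModel`) are plain
dataclasses that serialize losslessly to JSON so models are portable between
the training and evaluation halves of a study.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ConfigValidationError,
    DegenerateInputError,
)

DRUG_NAMES = ("T", "F", "A", "C")
#: Response label values understood by the evaluation stage.
RESPONSE_PCR = "pCR"
RESPONSE_RD = "RD"

DISCOVERY_METHODS = ("pearson", "spearman", "welch_t", "ancova", "rank_ancova")


def _check_unique(ids: Sequence[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ConfigValidationError(f"duplicate {what} IDs: {dups[:5]}")


class ExpressionPanel:
    """A genes x samples expression matrix with unique string identifiers.

    Parameters
    ----------
    data
        DataFrame indexed by gene ID with sample IDs as columns. Values must
        be numeric; NaN marks an explicitly missing measurement.
    name
        Free-text tag used in logs and provenance stamps.
    """

    def __init__(self, data: pd.DataFrame, name: str = "panel"):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("ExpressionPanel requires a pandas DataFrame")
        _check_unique(data.index, "gene")
        _check_unique(data.columns, "sample")
        values = data.to_numpy(dtype=float)  # raises on non-numeric
        if np.isinf(values).any():
            raise ConfigValidationError("expression values must be finite or NaN")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionPanel({self.name!r}, {self.n_genes} genes x {self.n_samples} samples)"

    # -- manipulation --------------------------------------------------------
    def subset_genes(self, genes: Sequence[str]) -> "ExpressionPanel":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise AlignmentError(
                f"genes absent from panel {self.name!r}: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return ExpressionPanel(self.data.loc[list(genes)], name=self.name)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionPanel":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise AlignmentError(
                f"samples absent from panel {self.name!r}: {missing[:5]}"
            )
        return ExpressionPanel(self.data[list(samples)], name=self.name)

    def zero_variance_genes(self) -> list[str]:
        sd = self.data.std(axis=1, ddof=1)
        return list(sd.index[(sd == 0) | sd.isna()])

    def equals(self, other: "ExpressionPanel") -> bool:
        return self.data.equals(other.data)


@dataclass
class DrugActivityProfile:
    """Per-cell-line drug sensitivity, higher = more sensitive.

    ``activity`` is indexed by cell-line sample ID; ``transform`` records the
    scale convention (the default plays the role of -log10(GI50)).
    """

    drug: str
    activity: pd.Series
    transform: str = "-log10(GI50)"

    def __post_init__(self) -> None:
        self.activity = pd.Series(self.activity, dtype=float)
        _check_unique(self.activity.index, "sample")
        if self.activity.isna().any():
            raise ConfigValidationError(
                f"activity for drug {self.drug!r} contains missing values"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activity.index.astype(str))

    def aligned_to(self, panel: ExpressionPanel) -> pd.Series:
        """Activity restricted to, and ordered by, the panel's samples."""
        shared = [s for s in panel.sample_ids if s in self.activity.index]
        if not shared:
            raise AlignmentError(
                f"no shared samples between panel {panel.name!r} and drug {self.drug!r}"
            )
        return self.activity.loc[shared]


@dataclass
class PatientCohort:
    """Tumour expression plus clinical channels for one patient cohort.

    ``response`` holds "pCR" / "RD" / NaN per patient. Survival time (months)
    and the event flag (1 = progression/relapse observed) are either both
    present or both absent. ``subtypes`` is a boolean frame of receptor flags
    (e.g. columns "ER-" and "TN"); where both are declared, TN must nest
    inside ER-.
    """

    panel: ExpressionPanel
    response: pd.Series | None = None
    survival_time: pd.Series | None = None
    event: pd.Series | None = None
    subtypes: pd.DataFrame | None = None
    tag: str = "cohort"

    def __post_init__(self) -> None:
        samples = pd.Index(self.panel.sample_ids)
        if (self.survival_time is None) != (self.event is None):
            raise ConfigValidationError(
                "survival_time and event flag must be provided together"
            )
        if self.response is not None:
            self.response = pd.Series(self.response).reindex(samples)
            bad = set(self.response.dropna().unique()) - {RESPONSE_PCR, RESPONSE_RD}
            if bad:
                raise ConfigValidationError(f"unknown response labels: {sorted(bad)}")
        if self.survival_time is not None:
            self.survival_time = pd.Series(self.survival_time, dtype=float).reindex(samples)
            self.event = pd.Series(self.event, dtype=float).reindex(samples)
            if (self.survival_time.dropna() < 0).any():
                raise ConfigValidationError("survival_time must be >= 0")
            ev = self.event.dropna()
            if not set(ev.unique()) <= {0.0, 1.0}:
                raise ConfigValidationError("event flag must be binary")
        if self.subtypes is not None:
            self.subtypes = self.subtypes.reindex(samples).fillna(False).astype(bool)
            if "TN" in self.subtypes.columns and "ER-" in self.subtypes.columns:
                if (self.subtypes["TN"] & ~self.subtypes["ER-"]).any():
                    raise ConfigValidationError(
                        "subtype nesting violated: TN patients must also be ER-"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return self.panel.sample_ids

    @property
    def has_survival(self) -> bool:
        return self.survival_time is not None

    def subtype_mask(self, subtype: str | None) -> pd.Series:
        """Boolean patient mask for a subtype label; all-True when None."""
        samples = pd.Index(self.panel.sample_ids)
        if subtype is None:
            return pd.Series(True, index=samples)
        if self.subtypes is None or subtype not in self.subtypes.columns:
            raise ConfigValidationError(f"cohort {self.tag!r} has no subtype {subtype!r}")
        return self.subtypes[subtype]


# ---------------------------------------------------------------------------
# Simulation configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the paired cell-line / patient simulator.

    Defaults describe a desk-scale analogue of a 60-line screen evaluated on
    an ER-negative neoadjuvant cohort of 200 patients: four drugs with 25
    planted signature genes each, a per-gene standardized slope of 0.6 on
    activity, half of each signature coexpression-concordant in tumours, and
    a logistic response link plus exponential survival driven by the true
    combined score.
    """

    n_cell_lines: int = 60
    n_patients: int = 200
    n_genes: int = 2000
    n_signature_genes_per_drug: int = 25
    n_drugs: int = 4
    signature_effect: float = 0.6
    concordant_fraction: float = 0.5
    n_tissues: int = 4
    tissue_shift: float = 0.5
    response_intercept: float = -1.2
    response_slope: float = 4.0
    baseline_hazard: float = 0.02
    hazard_log_ratio: float = 0.8
    censor_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_lines", "n_patients", "n_genes", "n_tissues", "n_drugs"):
            if getattr(self, name) < 1:
                raise ConfigValidationError(f"{name} must be >= 1")
        if self.n_signature_genes_per_drug < 0:
            raise ConfigValidationError("n_signature_genes_per_drug must be >= 0")
        if not 1 <= self.n_drugs <= 4:
            raise ConfigValidationError("n_drugs must be between 1 and 4")
        if self.n_signature_genes_per_drug * self.n_drugs > self.n_genes:
            raise ConfigValidationError(
                "n_signature_genes_per_drug x n_drugs exceeds n_genes"
            )
        if not 0.0 <= self.concordant_fraction <= 1.0:
            raise ConfigValidationError("concordant_fraction must lie in [0, 1]")
        if self.censor_rate < 0:
            raise ConfigValidationError("censor_rate must be >= 0")
        if self.baseline_hazard <= 0:
            raise ConfigValidationError("baseline_hazard must be > 0")

    @property
    def drugs(self) -> tuple[str, ...]:
        return DRUG_NAMES[: self.n_drugs]

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Manifest of planted signal: the oracle for parameter-recovery tests.

    ``signature_genes`` maps drug -> ordered gene IDs; ``concordant`` flags,
    per signature gene, whether its coexpression loadings are preserved in the
    patient panel. ``patient_truth`` accumulates one frame per generated
    cohort (columns ``true_score`` and ``response_prob``).
    """

    signature_genes: dict[str, list[str]]
    concordant: dict[str, bool]
    patient_truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def all_signature_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.signature_genes.values():
            out.extend(genes)
        return out

    def to_dict(self) -> dict:
        return {
            "signature_genes": self.signature_genes,
            "concordant": self.concordant,
            "patient_truth": {
                tag: df.reset_index().to_dict(orient="list")
                for tag, df in self.patient_truth.items()
            },
        }


# ---------------------------------------------------------------------------
# Statistical result records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAssociationResult:
    """One gene's association with drug activity under one method."""

    gene: str
    method: str
    statistic: float
    p_value: float
    direction: int
    n_used: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ConfigValidationError(
                f"p_value {self.p_value} outside [0, 1] for gene {self.gene}"
            )


@dataclass(frozen=True)
class CoxenScore:
    """Second-order (correlation-of-correlations) concordance of one gene."""

    gene: str
    score: float
    reference_tag: str
    n_reference: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.score <= 1.0 + 1e-12):
            raise ConfigValidationError(f"COXEN score {self.score} outside [-1, 1]")


@dataclass
class BiomarkerSet:
    """Concordantly expressed biomarker genes selected for one drug."""

    drug: str
    genes: list[str]
    scores: dict[str, float] = field(default_factory=dict)
    method: str = ""
    candidate_size: int = 0

    def __post_init__(self) -> None:
        _check_unique(self.genes, "biomarker gene")


# ---------------------------------------------------------------------------
# Trained model artifacts
# ---------------------------------------------------------------------------

@dataclass
class DrugModel:
    """A self-contained per-drug principal-component regression predictor.

    Stores everything needed to score a new cohort: the biomarker gene list,
    the training standardization (per-gene mean/sd on cell lines), orthonormal
    PC loadings of the standardized training submatrix, and the regression
    intercept/coefficients of activity on the leading components.
    """

    drug: str
    genes: list[str]
    train_mean: np.ndarray
    train_sd: np.ndarray
    loadings: np.ndarray  # genes x components, orthonormal columns
    intercept: float
    coefficients: np.ndarray  # per component
    training_tag: str = ""
    discovery_method: str = ""

    def __post_init__(self) -> None:
        self.train_mean = np.asarray(self.train_mean, dtype=float)
        self.train_sd = np.asarray(self.train_sd, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        g = len(self.genes)
        if self.train_mean.shape != (g,) or self.train_sd.shape != (g,):
            raise ConfigValidationError("standardization vectors must match gene list")
        if (self.train_sd <= 0).any():
            raise DegenerateInputError("training sd entries must be > 0")
        if self.loadings.shape[0] != g:
            raise ConfigValidationError("loadings rows must match gene list")
        if self.loadings.shape[1] != self.coefficients.shape[0]:
            raise ConfigValidationError("one coefficient per component required")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "genes": self.genes,
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "loadings": self.loadings.tolist(),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "training_tag": self.training_tag,
            "discovery_method": self.discovery_method,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "DrugModel":
        return cls(
            drug=payload["drug"],
            genes=list(payload["genes"]),
            train_mean=np.asarray(payload["train_mean"], dtype=float),
            train_sd=np.asarray(payload["train_sd"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            intercept=float(payload["intercept"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            training_tag=payload.get("training_tag", ""),
            discovery_method=payload.get("discovery_method", ""),
        )


@dataclass
class CombinationModel:
    """Fusion of per-drug percentile scores into one regimen-level predictor.

    ``logistic`` mode holds a fitted intercept and per-drug coefficients
    (main effects only; no drug-drug interaction terms). ``equal_weight``
    mode has no parameters: the combined score is the mean percentile.
    """

    drugs: list[str]
    mode: str
    intercept: float | None = None
    coefficients: dict[str, float] | None = None
    fitting_tag: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("logistic", "equal_weight"):
            raise ConfigValidationError(f"unknown combination mode {self.mode!r}")
        if not self.drugs or len(set(self.drugs)) != len(self.drugs):
            raise ConfigValidationError("drug list must be nonempty without duplicates")
        if self.mode == "logistic":
            if self.intercept is None or self.coefficients is None:
                raise ConfigValidationError("logistic mode requires coefficients")
            if set(self.coefficients) != set(self.drugs):
                raise ConfigValidationError("one coefficient per drug required")
        else:
            if self.intercept is not None or self.coefficients is not None:
                raise ConfigValidationError("equal_weight mode carries no coefficients")

    def to_dict(self) -> dict:
        return {
            "drugs": self.drugs,
            "mode": self.mode,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "fitting_tag": self.fitting_tag,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CombinationModel":
        return cls(
            drugs=list(payload["drugs"]),
            mode=payload["mode"],
            intercept=payload.get("intercept"),
            coefficients=dict(payload["coefficients"])
            if payload.get("coefficients") is not None
            else None,
            fitting_tag=payload.get("fitting_tag", ""),
        )


@dataclass
class KMCurve:
    """One group's product-limit curve plus median survival.

    ``median`` is None when the curve never reaches 0.5; ``max_followup``
    then bounds the median from below ("> max follow-up").
    """

    group: str
    times: np.ndarray
    survival: np.ndarray
    median: float | None
    max_followup: float
    n: int
    n_events: int

    def median_label(self) -> str:
        if self.median is None:
            return f">{self.max_followup:g}"
        return f"{self.median:g}"


@dataclass
class EvaluationReport:
    """Response and survival evaluation of one predictor on one cohort."""

    predictor_tag: str
    cohort_tag: str
    n_total: int
    n_pcr: int
    n_rd: int
    n_response_missing: int
    auc: float | None
    ranksum_p: float | None
    cutoff_fraction: float
    n_positive: int
    n_negative: int
    npv: float | None
    false_negative_risk: float | None
    km_curves: dict[str, KMCurve] | None = None
    logrank_statistic: float | None = None
    logrank_p: float | None = None

    def to_dict(self) -> dict:
        out = {
            "predictor_tag": self.predictor_tag,
            "cohort_tag": self.cohort_tag,
            "n_total": self.n_total,
            "n_pcr": self.n_pcr,
            "n_rd": self.n_rd,
            "n_response_missing": self.n_response_missing,
            "auc": self.auc,
            "ranksum_p": self.ranksum_p,
            "cutoff_fraction": self.cutoff_fraction,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "npv": self.npv,
            "false_negative_risk": self.false_negative_risk,
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
        }
        if self.km_curves is not None:
            out["median_survival"] = {
                g: c.median_label() for g, c in self.km_curves.items()
            }
        return out
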