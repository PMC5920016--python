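"""Per-drug principal-component regression models and score combination.

Training is strictly in vitro: :func:`fit_drug_model` sees only the
cell-line panel and its activity profile — by construction it cannot receive
patient data. The biomarker submatrix is standardized per gene on the
training samples, decomposed by SVD, and activity is regressed on the
leading components (the default rule keeps the smallest number of components
explaining >= 80% of the biomarker-set variance, capped at 10).

At application time a cohort is **re-standardized within itself** before
projection: cell lines and tumours are different systems with incomparable
location and scale, so the raw score is a fixed linear combination of
cohort-standardized expression. Raw scores are then converted to rank-based
percentiles in [0, 1] within the cohort, and per-drug percentiles are fused
into a regimen-level predictor — either by multivariate logistic regression
of pCR on the percentiles (main effects only; no drug-drug interaction
terms) or by an unfitted equal-weight mean.

Higher percentile = predicted more sensitive/responder, everywhere.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .datatypes import (
    BiomarkerSet,
    CombinationModel,
    DrugActivityProfile,
    DrugModel,
    ExpressionPanel,
)
from .exceptions import (
    ConfigValidationError,
    DegenerateInputError,
    FitError,
    PredictionError,
    ScoringError,
)

logger = logging.getLogger(__name__)

VARIANCE_TARGET = 0.8
MAX_COMPONENTS = 10
#: Fraction of model genes that may be absent from a cohort before scoring fails.
MAX_MISSING_GENE_FRACTION = 0.10


def choose_n_components(
    explained_ratio: np.ndarray,
    rule: int | str = "variance",
    variance_target: float = VARIANCE_TARGET,
    max_components: int = MAX_COMPONENTS,
) -> int:
    """Number of leading components to keep.

    ``rule`` is either an explicit integer or ``"variance"``: the smallest k
    whose cumulative explained variance reaches ``variance_target``, capped
    at ``max_components`` and at the available rank.
    """
    available = explained_ratio.shape[0]
    if isinstance(rule, (int, np.integer)):
        k = int(rule)
        if k < 1:
            raise ConfigValidationError("n_components must be >= 1")
        if k > available:
            logger.warning(
                "n_components=%d exceeds rank %d; reduced", k, available
            )
            k = available
        return k
    if rule != "variance":
        raise ConfigValidationError(f"unknown n_components rule {rule!r}")
    cum = np.cumsum(explained_ratio)
    k = int(np.searchsorted(cum, variance_target) + 1)
    return min(k, max_components, available)


def fit_drug_model(
    panel: ExpressionPanel,
    profile: DrugActivityProfile,
    biomarkers: BiomarkerSet,
    n_components_rule: int | str = "variance",
) -> DrugModel:
    """Train one drug's PC-regression chemosensitivity model on cell lines."""
    missing = [g for g in biomarkers.genes if g not in panel.data.index]
    if missing:
        raise FitError(f"biomarker genes missing from training panel: {missing[:10]}")
    activity = profile.aligned_to(panel)
    sub = panel.subset_genes(biomarkers.genes).subset_samples(list(activity.index))
    X = sub.values.T  # samples x genes
    if np.isnan(X).any():
        raise FitError("training expression contains missing values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(biomarkers.genes, sd) if s == 0]
        raise DegenerateInputError(f"zero-variance biomarker genes: {bad[:10]}")
    Z = (X - mean) / sd

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum()) if S.size else 0
    if rank == 0:
        raise FitError("standardized training matrix has rank 0")
    explained = (S[:rank] ** 2) / (S[:rank] ** 2).sum()
    k = choose_n_components(explained, n_components_rule)
    loadings = Vt[:k].T  # genes x k, orthonormal columns
    scores = Z @ loadings
    design = np.column_stack([np.ones(scores.shape[0]), scores])
    beta, *_ = np.linalg.lstsq(design, activity.to_numpy(), rcond=None)
    return DrugModel(
        drug=profile.drug,
        genes=list(biomarkers.genes),
        train_mean=mean,
        train_sd=sd,
        loadings=loadings,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        training_tag=panel.name,
        discovery_method=biomarkers.method,
    )


def score_cohort(
    model: DrugModel,
    cohort_panel: ExpressionPanel,
    standardization: str = "cohort",
) -> pd.Series:
    """Raw chemosensitivity scores for every sample of a cohort.

    ``standardization="cohort"`` (default) re-standardizes each model gene
    within the cohort before projecting on the training loadings;
    ``"training"`` applies the stored training mean/sd instead. Up to 10% of
    model genes may be absent from the cohort — they contribute zero after
    standardization (mean imputation) with a warning.
    """
    if standardization not in ("cohort", "training"):
        raise ConfigValidationError(f"unknown standardization {standardization!r}")
    present = [g for g in model.genes if g in cohort_panel.data.index]
    n_missing = len(model.genes) - len(present)
    if n_missing > MAX_MISSING_GENE_FRACTION * len(model.genes):
        raise ScoringError(
            f"{n_missing}/{len(model.genes)} model genes missing from cohort "
            f"{cohort_panel.name!r} (> {MAX_MISSING_GENE_FRACTION:.0%})"
        )
    if n_missing:
        logger.warning(
            "%d/%d model genes missing from cohort %s; mean-imputed",
            n_missing,
            len(model.genes),
            cohort_panel.name,
        )
    sub = cohort_panel.subset_genes(present)
    X = sub.values.T  # samples x genes(present)
    if np.isnan(X).any():
        raise ScoringError("cohort expression contains missing values")
    gene_idx = {g: i for i, g in enumerate(model.genes)}
    if standardization == "cohort":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.warning(
                "%d zero-variance model genes in cohort; treated as missing",
                int(zero.sum()),
            )
            sd[zero] = 1.0
        Z_present = (X - mean) / sd
        Z_present[:, zero] = 0.0
    else:
        cols = np.array([gene_idx[g] for g in present])
        Z_present = (X - model.train_mean[cols]) / model.train_sd[cols]
    Z = np.zeros((X.shape[0], len(model.genes)))
    for j, g in enumerate(present):
        Z[:, gene_idx[g]] = Z_present[:, j]
    raw = model.intercept + Z @ model.loadings @ model.coefficients
    return pd.Series(raw, index=sub.sample_ids, name=f"{model.drug}_raw")


def to_rank_percentile(raw_scores) -> pd.Series:
    """Rank-based percentile transform onto [0, 1].

    ``percentile = (rank - 1) / (n - 1)`` with midranks for ties: the
    minimum maps to 0, the maximum to 1, and the transform is invariant
    under any strictly monotone transform of the input. If every value is
    tied the output is flat 0.5 with a warning.
    """
    s = pd.Series(raw_scores, dtype=float)
    n = len(s)
    if n < 2:
        raise ConfigValidationError("need at least 2 scores for percentiles")
    vals = s.to_numpy()
    if np.all(vals == vals[0]):
        warnings.warn("all raw scores tied; percentiles set to 0.5", stacklevel=2)
        return pd.Series(0.5, index=s.index, name="percentile")
    ranks = stats.rankdata(vals, method="average")
    return pd.Series((ranks - 1) / (n - 1), index=s.index, name="percentile")


def _percentile_frame(per_drug: Mapping[str, pd.Series]) -> pd.DataFrame:
    frame = pd.DataFrame({d: pd.Series(v) for d, v in sorted(per_drug.items())})
    if frame.isna().any().any():
        raise ConfigValidationError("per-drug percentile vectors are misaligned")
    return frame


def fit_combination(
    per_drug_percentiles: Mapping[str, pd.Series],
    response,
    mode: str = "logistic",
    fitting_tag: str = "",
) -> CombinationModel:
    """Fuse per-drug percentile scores into one combination predictor.

    ``logistic`` fits maximum-likelihood logistic regression of pCR (1) vs
    RD (0) on the percentiles, main effects only. On complete separation the
    fit falls back to ``equal_weight`` with a warning. ``equal_weight``
    requires no response data at all.
    """
    frame = _percentile_frame(per_drug_percentiles)
    drugs = list(frame.columns)
    if mode == "equal_weight":
        return CombinationModel(drugs=drugs, mode="equal_weight", fitting_tag=fitting_tag)
    if mode != "logistic":
        raise ConfigValidationError(f"unknown combination mode {mode!r}")

    y = pd.Series(response).reindex(frame.index)
    if y.isna().any():
        frame = frame.loc[~y.isna()]
        y = y.dropna()
    y01 = y.map({"pCR": 1, "RD": 0}) if y.dtype == object else y.astype(int)
    if y01.nunique() < 2:
        raise FitError("logistic combination requires both response classes")
    design = sm.add_constant(frame.to_numpy())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            fit = sm.Logit(y01.to_numpy(), design).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.params)):
            raise FitError("non-finite coefficients")
        params = fit.params
    except Exception as exc:  # separation / non-convergence
        logger.warning(
            "logistic combination failed (%s); falling back to equal weights", exc
        )
        return CombinationModel(drugs=drugs, mode="equal_weight", fitting_tag=fitting_tag)
    return CombinationModel(
        drugs=drugs,
        mode="logistic",
        intercept=float(params[0]),
        coefficients={d: float(c) for d, c in zip(drugs, params[1:])},
        fitting_tag=fitting_tag,
    )


def predict_combination(
    model: CombinationModel, per_drug_percentiles: Mapping[str, pd.Series]
) -> pd.Series:
    """Combined score in [0, 1] for every patient.

    Logistic mode returns fitted response probabilities; equal-weight mode
    the mean percentile. Output is indexed like the inputs and invariant to
    the key order of the percentile map.
    """
    missing = [d for d in model.drugs if d not in per_drug_percentiles]
    if missing:
        raise PredictionError(f"percentiles missing for drugs: {missing}")
    frame = _percentile_frame(
        {d: per_drug_percentiles[d] for d in model.drugs}
    )[model.drugs]
    if model.mode == "equal_weight":
        out = frame.mean(axis=1)
    else:
        coef = np.array([model.coefficients[d] for d in model.drugs])
        out = pd.Series(
            expit(model.intercept + frame.to_numpy() @ coef), index=frame.index
        )
    return out.rename("combined_score")
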