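"""Gene-by-gene association screening between expression and drug activity.

Five alternative statistics are supported, because drug-sensitivity
biomarkers can show association patterns that different tests capture with
different power:

* ``pearson`` — product-moment correlation of expression with activity;
* ``spearman`` — rank correlation (midranks for ties);
* ``welch_t`` — unequal-variance t-test between "sensitive" (activity
  strictly above the panel median) and "resistant" (the rest) lines;
* ``ancova`` — t-test of the expression slope in a least-squares model that
  adjusts activity for histology (tissue-type) mean differences;
* ``rank_ancova`` — the same ANCOVA after replacing expression and activity
  each by their midranks.

Candidate ranking is by raw p-value (no multiplicity correction — selection
is by rank, not by a significance threshold), with |statistic| descending and
gene ID as deterministic tie-breakers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import (
    DISCOVERY_METHODS,
    DrugActivityProfile,
    ExpressionPanel,
    GeneAssociationResult,
)
from .exceptions import (
    AlignmentError,
    CollinearityError,
    ConfigValidationError,
    DegenerateInputError,
)

logger = logging.getLogger(__name__)

#: Minimum fraction of samples that must be observed for a gene to be tested.
MIN_COMPLETE_FRACTION = 0.8
DEFAULT_TOP_K = 500


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ConfigValidationError(f"{name} must be one-dimensional")
    return v


def _check_aligned(expression: np.ndarray, activity: np.ndarray, gene: str) -> None:
    if expression.shape[0] != activity.shape[0]:
        raise AlignmentError(
            f"gene {gene!r}: expression length {expression.shape[0]} != "
            f"activity length {activity.shape[0]}"
        )


def _result(gene, method, stat, p, n) -> GeneAssociationResult:
    return GeneAssociationResult(
        gene=gene,
        method=method,
        statistic=float(stat),
        p_value=float(p),
        direction=int(np.sign(stat)),
        n_used=int(n),
    )


# ---------------------------------------------------------------------------
# Per-gene statistics
# ---------------------------------------------------------------------------

def pearson_association(expression_row, activity, gene: str = "gene") -> GeneAssociationResult:
    """Pearson correlation of one gene's expression with drug activity.

    The two-sided p-value comes from the exact t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom.
    """
    x = _as_vector(expression_row, "expression")
    y = _as_vector(activity, "activity")
    _check_aligned(x, y, gene)
    if x.shape[0] < 3:
        raise DegenerateInputError(f"gene {gene!r}: need >= 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError(f"gene {gene!r}: zero variance input")
    r, p = stats.pearsonr(x, y)
    return _result(gene, "pearson", r, p, x.shape[0])


def spearman_association(expression_row, activity, gene: str = "gene") -> GeneAssociationResult:
    """Spearman rank correlation (midranks for ties), p as Pearson-on-ranks."""
    x = _as_vector(expression_row, "expression")
    y = _as_vector(activity, "activity")
    _check_aligned(x, y, gene)
    if x.shape[0] < 3:
        raise DegenerateInputError(f"gene {gene!r}: need >= 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError(f"gene {gene!r}: zero variance input")
    rho, p = stats.spearmanr(x, y)
    return _result(gene, "spearman", rho, p, x.shape[0])


def median_split(activity) -> np.ndarray:
    """Boolean "sensitive" mask: activity strictly above the median.

    Median-valued samples fall in the "resistant" group — the documented
    resolution of a median-cutoff split on the higher-is-sensitive scale.
    """
    y = _as_vector(activity, "activity")
    return y > np.median(y)


def welch_t_association(expression_row, activity, gene: str = "gene") -> GeneAssociationResult:
    """Welch two-sample t between sensitive and resistant lines.

    Sensitivity grouping uses the median activity as cutoff via
    :func:`median_split`. Degenerate case with identical expression in both
    groups reports t = 0, p = 1.
    """
    x = _as_vector(expression_row, "expression")
    y = _as_vector(activity, "activity")
    _check_aligned(x, y, gene)
    if x.shape[0] < 4:
        raise DegenerateInputError(f"gene {gene!r}: need >= 4 samples")
    sens = median_split(y)
    if sens.all() or (~sens).all():
        raise DegenerateInputError(
            f"gene {gene!r}: degenerate median split (all activities equal?)"
        )
    a, b = x[sens], x[~sens]
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return _result(gene, "welch_t", 0.0, 1.0, x.shape[0])
        raise DegenerateInputError(f"gene {gene!r}: zero within-group variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return _result(gene, "welch_t", t, p, x.shape[0])


def _ancova_design(expression: np.ndarray, tissue: np.ndarray) -> np.ndarray:
    """Intercept + tissue dummies (reference coding) + expression column."""
    levels = pd.unique(tissue)
    cols = [np.ones_like(expression)]
    for lev in levels[1:]:
        cols.append((tissue == lev).astype(float))
    cols.append(expression)
    return np.column_stack(cols)


def _check_tissue(tissue: np.ndarray, n: int) -> None:
    levels, counts = np.unique(tissue, return_counts=True)
    if len(levels) >= 2 and (counts < 2).any():
        raise DegenerateInputError("every tissue level needs >= 2 samples")
    if n <= len(levels) + 2:
        raise DegenerateInputError(
            f"need n > number of tissue levels + 2 (n={n}, levels={len(levels)})"
        )


def ancova_association(
    expression_row, activity, tissue_labels, gene: str = "gene"
) -> GeneAssociationResult:
    """Expression slope t-test adjusting activity for tissue mean offsets.

    Fits ``activity ~ intercept + tissue offsets + beta1 * expression`` by
    least squares; the statistic is the t of ``beta1``. With a single tissue
    level this reduces exactly to simple-regression inference (and hence to
    the Pearson test's p-value).
    """
    x = _as_vector(expression_row, "expression")
    y = _as_vector(activity, "activity")
    _check_aligned(x, y, gene)
    tissue = np.asarray(tissue_labels)
    if tissue.shape[0] != x.shape[0]:
        raise AlignmentError(f"gene {gene!r}: tissue labels misaligned")
    _check_tissue(tissue, x.shape[0])
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError(f"gene {gene!r}: zero variance input")
    design = _ancova_design(x, tissue)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            f"gene {gene!r}: expression collinear with tissue indicators"
        )
    fit = sm.OLS(y, design).fit()
    return _result(gene, "ancova", fit.tvalues[-1], fit.pvalues[-1], x.shape[0])


def rank_ancova_association(
    expression_row, activity, tissue_labels, gene: str = "gene"
) -> GeneAssociationResult:
    """ANCOVA applied after midrank-transforming expression and activity."""
    x = _as_vector(expression_row, "expression")
    y = _as_vector(activity, "activity")
    _check_aligned(x, y, gene)
    if np.all(y == y[0]):
        raise DegenerateInputError(f"gene {gene!r}: all activity values tied")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    res = ancova_association(rx, ry, tissue_labels, gene=gene)
    return _result(gene, "rank_ancova", res.statistic, res.p_value, res.n_used)


# ---------------------------------------------------------------------------
# Vectorized bulk paths (same formulas, all genes at once)
# ---------------------------------------------------------------------------

def _pearson_bulk(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = y.shape[0]
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    ynorm = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = Xc @ yc / (xnorm * ynorm)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |r| == 1 exactly
    return r, p


def _spearman_bulk(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    RX = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    return _pearson_bulk(RX, ry)


def _welch_bulk(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sens = median_split(y)
    t, p = stats.ttest_ind(X[:, sens], X[:, ~sens], axis=1, equal_var=False)
    # identical values in both groups: report no difference
    nan = np.isnan(t)
    if nan.any():
        same = nan & (X[:, sens].mean(axis=1) == X[:, ~sens].mean(axis=1))
        t[same], p[same] = 0.0, 1.0
    return t, p


def _ancova_bulk(
    X: np.ndarray, y: np.ndarray, tissue: np.ndarray, ranked: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-correlation form of the ANCOVA slope t-test, vectorized.

    Residualize expression and activity on the tissue design; the slope t
    equals ``r_p * sqrt(df / (1 - r_p^2))`` with ``df = n - levels - 1``.
    """
    if ranked:
        X = stats.rankdata(X, axis=1)
        y = stats.rankdata(y)
    n = y.shape[0]
    levels = pd.unique(tissue)
    D = np.column_stack(
        [np.ones(n)] + [(tissue == lev).astype(float) for lev in levels[1:]]
    )
    Q, _ = np.linalg.qr(D)
    resid = lambda v: v - Q @ (Q.T @ v)
    ry = resid(y)
    RX = X - (X @ Q) @ Q.T
    xnorm = np.sqrt((RX**2).sum(axis=1))
    ynorm = np.sqrt((ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = RX @ ry / (xnorm * ynorm)
    rp = np.clip(rp, -1.0, 1.0)
    df = n - len(levels) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rp * np.sqrt(df / (1 - rp**2))
    p = 2 * stats.t.sf(np.abs(t), df=df)
    p[np.isnan(t)] = 0.0
    return t, p


def _bulk_associate(
    X: np.ndarray, y: np.ndarray, method: str, tissue: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if method == "pearson":
        return _pearson_bulk(X, y)
    if method == "spearman":
        return _spearman_bulk(X, y)
    if method == "welch_t":
        return _welch_bulk(X, y)
    if method in ("ancova", "rank_ancova"):
        if tissue is None:
            tissue = np.zeros(y.shape[0], dtype=int)
        _check_tissue(np.asarray(tissue), y.shape[0])
        return _ancova_bulk(X, y, np.asarray(tissue), ranked=method == "rank_ancova")
    raise ConfigValidationError(f"unknown discovery method {method!r}")


_PER_GENE = {
    "pearson": pearson_association,
    "spearman": spearman_association,
    "welch_t": welch_t_association,
}


def associate_gene(
    expression_row, activity, method: str, tissue_labels=None, gene: str = "gene"
) -> GeneAssociationResult:
    """Dispatch one gene through the chosen statistic."""
    if method in _PER_GENE:
        return _PER_GENE[method](expression_row, activity, gene=gene)
    if method == "ancova":
        return ancova_association(expression_row, activity, tissue_labels, gene=gene)
    if method == "rank_ancova":
        return rank_ancova_association(expression_row, activity, tissue_labels, gene=gene)
    raise ConfigValidationError(f"unknown discovery method {method!r}")


# ---------------------------------------------------------------------------
# Ranking across the whole panel
# ---------------------------------------------------------------------------

def rank_candidates(
    panel: ExpressionPanel,
    profile: DrugActivityProfile,
    method: str = "pearson",
    tissue_labels: pd.Series | None = None,
    top_k: int = DEFAULT_TOP_K,
) -> list[GeneAssociationResult]:
    """Score every gene against one drug's activity and return the top_k.

    Ordering is ascending p-value, then descending |statistic|, then gene ID
    — a fully deterministic ranking. Genes with zero variance, too many
    missing values (< 80% observed), or other degenerate inputs are skipped
    with a logged warning. Genes with a tolerable number of missing values
    are tested on their complete cases.
    """
    if method not in DISCOVERY_METHODS:
        raise ConfigValidationError(f"unknown discovery method {method!r}")
    if top_k <= 0:
        raise ConfigValidationError("top_k must be positive")
    if top_k > panel.n_genes:
        raise ConfigValidationError(
            f"top_k={top_k} exceeds panel size {panel.n_genes}"
        )

    activity = profile.aligned_to(panel)
    sub = panel.subset_samples(list(activity.index))
    y = activity.to_numpy()
    X = sub.values
    genes = np.asarray(sub.gene_ids)
    tissue = None
    if tissue_labels is not None:
        tissue = tissue_labels.reindex(activity.index).to_numpy()
        if pd.isna(tissue).any():
            raise AlignmentError("tissue labels missing for some profiled samples")

    observed = ~np.isnan(X)
    frac = observed.mean(axis=1)
    complete = observed.all(axis=1)
    variable = np.nanstd(X, axis=1) > 0
    testable = frac >= MIN_COMPLETE_FRACTION
    n_skipped = int((~(testable & variable)).sum())
    if n_skipped:
        logger.warning(
            "%s/%s genes skipped (zero variance or >%d%% missing)",
            n_skipped,
            len(genes),
            round((1 - MIN_COMPLETE_FRACTION) * 100),
        )

    results: list[GeneAssociationResult] = []
    bulk_mask = complete & variable
    if bulk_mask.any():
        stat, p = _bulk_associate(X[bulk_mask], y, method, tissue)
        for g, s, pv, keep in zip(
            genes[bulk_mask], stat, p, np.isfinite(stat) & np.isfinite(p)
        ):
            if keep:
                results.append(_result(g, method, s, pv, y.shape[0]))
            else:
                logger.warning("gene %s skipped: degenerate statistic", g)

    # complete-case fallback for genes with tolerable missingness
    for i in np.nonzero(testable & variable & ~complete)[0]:
        mask = observed[i]
        try:
            res = associate_gene(
                X[i, mask],
                y[mask],
                method,
                tissue_labels=None if tissue is None else tissue[mask],
                gene=str(genes[i]),
            )
            results.append(res)
        except (DegenerateInputError, CollinearityError) as exc:
            logger.warning("gene %s skipped: %s", genes[i], exc)

    results.sort(key=lambda r: (r.p_value, -abs(r.statistic), r.gene))
    return results[:top_k]
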