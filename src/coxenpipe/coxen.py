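"""COXEN (COexpression ExtrapolatioN) concordance scoring and gene triage.

A candidate biomarker discovered on cell lines is only useful in patients if
its coexpression context — the vector of correlations with a reference gene
set — is preserved from the in vitro panel to tumours. The COXEN score of a
gene is the *second-order* correlation: the Pearson correlation, between the
two panels, of that gene's coexpression vectors. Genes scoring near 1 keep
their regulatory context across systems; genes near 0 do not.

By default the reference gene set for the coexpression vectors is the
candidate set itself (minus the gene being scored): genome-wide vectors are
dominated by near-zero noise correlations, while the candidate set carries
the structure that matters for the drug model. A whole-universe mode is
available via ``reference_genes``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BiomarkerSet,
    CoxenScore,
    ExpressionPanel,
    GeneAssociationResult,
)
from .exceptions import AlignmentError, ConfigValidationError, DegenerateInputError

logger = logging.getLogger(__name__)

MIN_REFERENCE_GENES = 10


def _usable_reference(
    panel: ExpressionPanel, reference_genes: Sequence[str], gene: str
) -> list[str]:
    refs = [g for g in reference_genes if g != gene]
    missing = [g for g in refs if g not in panel.data.index]
    if missing:
        raise AlignmentError(f"reference genes absent from panel: {missing[:5]}")
    zero_var = set(panel.subset_genes(refs).zero_variance_genes())
    if zero_var:
        logger.warning("excluding %d zero-variance reference genes", len(zero_var))
        refs = [g for g in refs if g not in zero_var]
    return refs


def coexpression_vector(
    gene: str, panel: ExpressionPanel, reference_genes: Sequence[str]
) -> pd.Series:
    """Pearson correlations of one gene with each reference gene.

    The gene itself is excluded from its own reference list; zero-variance
    reference genes are dropped with a warning. Output is ordered by the
    reference list.
    """
    if gene not in panel.data.index:
        raise AlignmentError(f"gene {gene!r} absent from panel {panel.name!r}")
    refs = _usable_reference(panel, reference_genes, gene)
    x = panel.data.loc[gene].to_numpy()
    if np.std(x) == 0:
        raise DegenerateInputError(f"gene {gene!r} has zero variance")
    R = panel.subset_genes(refs).values
    xc = x - x.mean()
    Rc = R - R.mean(axis=1, keepdims=True)
    corr = Rc @ xc / (np.sqrt((Rc**2).sum(axis=1)) * np.sqrt((xc**2).sum()))
    return pd.Series(corr, index=refs, name=gene)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        raise DegenerateInputError("zero-variance coexpression vector")
    return float(np.clip(ac @ bc / denom, -1.0, 1.0))


def coxen_score(
    gene: str,
    panel_a: ExpressionPanel,
    panel_b: ExpressionPanel,
    reference_genes: Sequence[str],
) -> CoxenScore:
    """Second-order correlation of one gene between two panels."""
    refs = [g for g in reference_genes if g != gene]
    shared = [
        g for g in refs if g in panel_a.data.index and g in panel_b.data.index
    ]
    if len(shared) < MIN_REFERENCE_GENES:
        raise ConfigValidationError(
            f"only {len(shared)} shared reference genes; need >= {MIN_REFERENCE_GENES}"
        )
    va = coexpression_vector(gene, panel_a, shared)
    vb = coexpression_vector(gene, panel_b, shared)
    common = [g for g in shared if g in va.index and g in vb.index]
    score = _pearson(va.loc[common].to_numpy(), vb.loc[common].to_numpy())
    return CoxenScore(
        gene=gene,
        score=score,
        reference_tag=f"{panel_a.name}|{panel_b.name}",
        n_reference=len(common),
    )


def coxen_scores(
    genes: Sequence[str],
    panel_a: ExpressionPanel,
    panel_b: ExpressionPanel,
) -> pd.Series:
    """COXEN scores for a candidate set, candidates as their own reference.

    Vectorized over the candidate submatrix: both gene-gene correlation
    matrices are computed once, and gene *i*'s score is the correlation of
    the two matrices' *i*-th rows with the diagonal (self) entry removed.
    """
    genes = list(genes)
    shared = [
        g for g in genes if g in panel_a.data.index and g in panel_b.data.index
    ]
    if len(shared) < MIN_REFERENCE_GENES:
        raise ConfigValidationError(
            f"only {len(shared)} candidates shared across panels; "
            f"need >= {MIN_REFERENCE_GENES}"
        )
    sub_a = panel_a.subset_genes(shared)
    sub_b = panel_b.subset_genes(shared)
    zero = set(sub_a.zero_variance_genes()) | set(sub_b.zero_variance_genes())
    if zero:
        logger.warning("excluding %d zero-variance candidates from COXEN", len(zero))
        shared = [g for g in shared if g not in zero]
        sub_a = panel_a.subset_genes(shared)
        sub_b = panel_b.subset_genes(shared)
    Ca = np.corrcoef(sub_a.values)
    Cb = np.corrcoef(sub_b.values)
    m = len(shared)
    out = np.empty(m)
    for i in range(m):
        mask = np.arange(m) != i
        out[i] = _pearson(Ca[i, mask], Cb[i, mask])
    return pd.Series(out, index=shared, name="coxen_score")


def select_coxen_genes(
    candidates: Sequence[GeneAssociationResult] | Sequence[str],
    panel_a: ExpressionPanel,
    panel_b: ExpressionPanel,
    n_select: int,
    drug: str = "",
    method: str = "",
) -> BiomarkerSet:
    """Keep the n_select candidates with the highest COXEN scores.

    ``candidates`` is an ordered association ranking (or a plain gene-ID
    list); the candidate rank breaks score ties, then gene ID. The reference
    set for each gene's coexpression vector is the candidate set itself,
    excluding the gene under evaluation.
    """
    if not candidates:
        raise ConfigValidationError("candidate list is empty")
    if isinstance(candidates[0], GeneAssociationResult):
        genes = [c.gene for c in candidates]
        if not method:
            method = candidates[0].method
    else:
        genes = [str(c) for c in candidates]
    rank = {g: i for i, g in enumerate(genes)}

    scores = coxen_scores(genes, panel_a, panel_b)
    if not 1 <= n_select <= len(scores):
        raise ConfigValidationError(
            f"n_select={n_select} out of range (1..{len(scores)} scored candidates)"
        )
    order = sorted(scores.index, key=lambda g: (-scores[g], rank[g], g))
    chosen = order[:n_select]
    return BiomarkerSet(
        drug=drug,
        genes=chosen,
        scores={g: float(scores[g]) for g in chosen},
        method=method,
        candidate_size=len(genes),
    )
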