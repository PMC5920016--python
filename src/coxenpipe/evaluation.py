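"""Response and survival evaluation of chemosensitivity predictors.

Response metrics: rank-sum (Mann-Whitney) AUC and two-sided p for pCR vs RD,
top-fraction dichotomization into predicted responders ("COXEN positive",
default top 30%) vs the rest, and NPV of the predicted-negative group.
Survival metrics: Kaplan-Meier product-limit curves per predicted group with
median survival (reported as "> max follow-up" when the curve never reaches
0.5) and the two-group log-rank test. KM/log-rank computations are delegated
to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .datatypes import (
    RESPONSE_PCR,
    RESPONSE_RD,
    EvaluationReport,
    KMCurve,
    PatientCohort,
)
from .exceptions import ConfigValidationError, EvaluationError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_FRACTION = 0.30
#: Below this combined sample size the rank-sum test enumerates exactly.
EXACT_RANKSUM_MAX_N = 20


def _binary_labels(labels) -> np.ndarray:
    y = pd.Series(labels)
    if y.dtype == object:
        mapped = y.map({RESPONSE_PCR: 1, RESPONSE_RD: 0})
        if mapped.isna().any():
            raise ConfigValidationError("labels must be pCR/RD or 0/1")
        return mapped.to_numpy(dtype=int)
    vals = y.to_numpy()
    if not set(np.unique(vals)) <= {0, 1}:
        raise ConfigValidationError("labels must be binary")
    return vals.astype(int)


def auc(scores, labels) -> float:
    """Rank-sum AUC: P(score_pos > score_neg) + half the tie probability.

    Equals the Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC undefined: only one class present")
    ranks = stats.rankdata(s)
    u_pos = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u_pos / (n_pos * n_neg))


def ranksum_test(scores, labels, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value for pCR vs RD scores.

    Uses exact permutation enumeration when the combined n is below 20 and
    there are no ties; otherwise the normal approximation with midrank ties
    and continuity correction.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("rank-sum test requires both classes")
    has_ties = len(np.unique(s)) < len(s)
    method = "exact" if (len(s) < EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        pos, neg, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def dichotomize_top_fraction(scores: pd.Series, fraction: float) -> pd.Series:
    """Boolean mask of predicted responders: the top ceil(fraction * n) scores.

    Ordering is by descending score with ascending sample ID as the
    deterministic tie-break, so boundary ties resolve reproducibly. An
    all-tied score vector degenerates to the first ceil(fraction * n)
    samples by ID, with a warning.
    """
    if not 0 < fraction < 1:
        raise ConfigValidationError("fraction must lie strictly between 0 and 1")
    s = pd.Series(scores, dtype=float)
    n = len(s)
    if n == 0:
        raise ConfigValidationError("empty score vector")
    k = int(np.ceil(fraction * n))
    if s.nunique() == 1:
        warnings.warn(
            "all scores tied; positive group taken by sample-ID order", stacklevel=2
        )
    order = sorted(s.index, key=lambda i: (-s[i], str(i)))
    positive = set(order[:k])
    return pd.Series([i in positive for i in s.index], index=s.index, name="positive")


def km_estimate(times, events, group_labels) -> dict[str, KMCurve]:
    """Product-limit survival curve and median per group.

    The median is the earliest time at which estimated survival drops to
    <= 0.5; if the curve never reaches 0.5 it is None and the curve's
    ``max_followup`` bounds it from below.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    g = np.asarray(group_labels)
    if (t < 0).any():
        raise ConfigValidationError("survival times must be >= 0")
    if not set(np.unique(e)) <= {0.0, 1.0}:
        raise ConfigValidationError("event flags must be binary")
    curves: dict[str, KMCurve] = {}
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() == 0:
            raise EvaluationError(f"group {label!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        med = kmf.median_survival_time_
        curves[str(label)] = KMCurve(
            group=str(label),
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            median=None if np.isinf(med) else float(med),
            max_followup=float(t[mask].max()),
            n=int(mask.sum()),
            n_events=int(e[mask].sum()),
        )
    return curves


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic and p (1 df)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    g = np.asarray(group_labels)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise EvaluationError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    m0, m1 = g == labels[0], g == labels[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise EvaluationError("log-rank test: one group is empty")
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    return float(res.test_statistic), float(res.p_value)


class NPVResult(NamedTuple):
    """Negative predictive value and its complement, the false-negative risk."""

    npv: float
    false_negative_risk: float


def npv(predicted_positive, response_labels) -> NPVResult:
    """NPV of the predicted-negative group: fraction that are truly RD.

    ``1 - NPV`` is the per-drug risk of falsely predicting a responsive
    patient negative.
    """
    pos = np.asarray(predicted_positive, dtype=bool)
    y = _binary_labels(response_labels)
    neg = ~pos
    if neg.sum() == 0:
        raise EvaluationError("NPV undefined: no predicted-negative patients")
    value = float((y[neg] == 0).mean())
    return NPVResult(npv=value, false_negative_risk=1.0 - value)


def joint_false_negative_risk(per_drug_risks: Sequence[float]) -> float:
    """Probability of falsely predicting negative for *all* listed drugs.

    Under the documented independence assumption across drug predictors the
    joint risk is the product of the per-drug false-negative probabilities —
    the arithmetic behind using several single-drug biomarkers side by side.
    """
    risks = [float(r) for r in per_drug_risks]
    for r in risks:
        if not 0.0 <= r <= 1.0:
            raise ConfigValidationError(f"risk {r} outside [0, 1]")
    return float(np.prod(risks)) if risks else 1.0


def evaluate_predictor(
    scores: pd.Series,
    cohort: PatientCohort,
    subtype: str | None = None,
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    predictor_tag: str = "predictor",
) -> EvaluationReport:
    """Full response + survival evaluation of one score vector on one cohort.

    Patients with missing response are excluded from AUC / rank-sum / NPV
    but retained for the survival comparison when survival is present.
    Deterministic: identical inputs give identical reports.
    """
    s = pd.Series(scores, dtype=float)
    mask = cohort.subtype_mask(subtype)
    ids = [i for i in cohort.sample_ids if mask[i]]
    if not ids:
        raise EvaluationError(f"subtype filter {subtype!r} selects no patients")
    missing_ids = [i for i in ids if i not in s.index]
    if missing_ids:
        raise EvaluationError(f"scores missing for patients: {missing_ids[:5]}")
    s = s.loc[ids]

    response = (
        cohort.response.loc[ids] if cohort.response is not None else pd.Series(index=ids, dtype=object)
    )
    known = response.dropna()
    n_pcr = int((known == RESPONSE_PCR).sum())
    n_rd = int((known == RESPONSE_RD).sum())
    n_missing = len(ids) - len(known)
    if n_missing:
        logger.info("%d patients without pCR/RD label excluded from response metrics", n_missing)

    auc_val = ranksum_p = None
    if n_pcr > 0 and n_rd > 0:
        auc_val = auc(s.loc[known.index], known)
        ranksum_p = ranksum_test(s.loc[known.index], known)

    positive = dichotomize_top_fraction(s, cutoff_fraction)
    npv_val = fnr_val = None
    if n_pcr + n_rd > 0 and (~positive.loc[known.index]).any():
        res = npv(positive.loc[known.index], known)
        npv_val, fnr_val = res.npv, res.false_negative_risk

    km = None
    lr_stat = lr_p = None
    if cohort.has_survival:
        t = cohort.survival_time.loc[ids]
        e = cohort.event.loc[ids]
        ok = t.notna() & e.notna()
        groups = np.where(positive.loc[ids][ok], "positive", "negative")
        if len(pd.unique(groups)) == 2:
            km = km_estimate(t[ok], e[ok], groups)
            lr_stat, lr_p = logrank_test(t[ok], e[ok], groups)
        else:
            logger.warning("survival comparison skipped: only one predicted group")

    return EvaluationReport(
        predictor_tag=predictor_tag,
        cohort_tag=cohort.tag + (f"[{subtype}]" if subtype else ""),
        n_total=len(ids),
        n_pcr=n_pcr,
        n_rd=n_rd,
        n_response_missing=n_missing,
        auc=auc_val,
        ranksum_p=ranksum_p,
        cutoff_fraction=cutoff_fraction,
        n_positive=int(positive.sum()),
        n_negative=int((~positive).sum()),
        npv=npv_val,
        false_negative_risk=fnr_val,
        km_curves=km,
        logrank_statistic=lr_stat,
        logrank_p=lr_p,
    )
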