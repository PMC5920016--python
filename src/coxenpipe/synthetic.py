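"""Paired cell-line / patient simulator with planted chemosensitivity signal.

The generator produces the two datasets every downstream stage assumes:

* a **cell-line training panel** — genes x cell-lines expression, a per-drug
  continuous activity phenotype on the -log10(GI50) convention (higher = more
  sensitive), and a histology (tissue) label that shifts mean activity;
* one or more **patient cohorts** sharing the gene universe — expression with
  partially concordant gene-gene coexpression, a binary pCR/RD response and a
  censored survival time, both driven by the planted signature genes.

Expression follows a latent-factor Gaussian model. Every gene is a mixture of
factor signal and independent noise, then standardized to mean 0 / sd 1:

* background genes load on ``k`` background factors with panel-specific
  loading directions (cell-line and tumour panels each get their own draw):
  background co-regulation exists in both systems but does not correspond
  across them, so it carries no cross-panel concordance signal;
* each drug's signature genes load on that drug's factor. In the patient
  panel a configured fraction of each signature keeps the cell-line loading
  structure ("concordant"); the rest get independently re-drawn background
  loadings, which destroys both their drug-factor attachment and their
  cross-panel coexpression correspondence while leaving their marginal
  distribution untouched.

Cross-panel coexpression concordance is therefore a property planted only in
the concordant signature genes — exactly the structure the COXEN second-order
correlation is designed to detect.

Drug activity on cell lines is a linear read-out of the standardized
signature expression plus a per-tissue mean offset and unit-variance noise.
The per-patient true combined score is the mean over drugs of the
standardized signature projection; pCR is Bernoulli with a logistic link on
that score and survival is exponential with hazard
``baseline_hazard * exp(-hazard_log_ratio * score)``.

All randomness derives from ``SimulationConfig.seed`` through named
``numpy.random.SeedSequence`` children, so identical configs give
bit-identical output and the study structure (gene roles, loadings) can be
rebuilt deterministically when generating additional cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import (
    DrugActivityProfile,
    ExpressionPanel,
    GroundTruth,
    PatientCohort,
    SimulationConfig,
)
from .exceptions import ConfigValidationError

# Latent-factor geometry: shared across both panels.
N_BACKGROUND_FACTORS = 5
#: Variance share a background gene draws from the shared factors.
BACKGROUND_VARIANCE_SHARE = 0.3
#: Variance share a signature gene draws from its drug factor.
SIGNATURE_VARIANCE_SHARE = 0.5

_STRUCTURE_STREAM = 0
_CELL_STREAM = 1
_PATIENT_STREAM_BASE = 2


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


@dataclass
class _StudyStructure:
    """Study-level randomness shared by both panels (rebuilt from the seed)."""

    gene_ids: list[str]
    signature_genes: dict[str, list[str]]
    concordant: dict[str, bool]
    background_loadings_cell: np.ndarray  # n_genes x k unit rows
    background_loadings_patient: np.ndarray  # independent draw, same shape
    tissue_offsets: np.ndarray  # n_drugs x n_tissues


def _build_structure(config: SimulationConfig) -> _StudyStructure:
    rng = _rng(config, _STRUCTURE_STREAM)
    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(config.n_genes)]

    n_sig_total = config.n_signature_genes_per_drug * config.n_drugs
    sig_idx = rng.choice(config.n_genes, size=n_sig_total, replace=False)
    signature_genes: dict[str, list[str]] = {}
    concordant: dict[str, bool] = {}
    for d, drug in enumerate(config.drugs):
        idx = sig_idx[
            d * config.n_signature_genes_per_drug : (d + 1) * config.n_signature_genes_per_drug
        ]
        genes = [gene_ids[i] for i in idx]
        signature_genes[drug] = genes
        n_conc = int(np.floor(config.concordant_fraction * len(genes) + 0.5))
        conc_positions = rng.choice(len(genes), size=n_conc, replace=False) if genes else []
        flags = np.zeros(len(genes), dtype=bool)
        flags[list(conc_positions)] = True
        for g, f in zip(genes, flags):
            concordant[g] = bool(f)

    def _unit_loadings() -> np.ndarray:
        m = rng.normal(size=(config.n_genes, N_BACKGROUND_FACTORS))
        return m / np.linalg.norm(m, axis=1, keepdims=True)

    loadings_cell = _unit_loadings()
    loadings_patient = _unit_loadings()
    tissue_offsets = config.tissue_shift * rng.normal(
        size=(config.n_drugs, config.n_tissues)
    )
    return _StudyStructure(
        gene_ids, signature_genes, concordant, loadings_cell, loadings_patient, tissue_offsets
    )


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def _draw_expression(
    structure: _StudyStructure,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_samples: int,
    patient_panel: bool,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw a standardized genes x samples matrix plus per-drug factor scores.

    Factor realizations are fresh per panel; loadings come from the shared
    structure except for discordant signature genes in the patient panel,
    which are re-attached to per-drug decoy factors.
    """
    n_genes = config.n_genes
    gene_pos = {g: i for i, g in enumerate(structure.gene_ids)}

    background = rng.normal(size=(N_BACKGROUND_FACTORS, n_samples))
    drug_factors = {drug: rng.normal(size=n_samples) for drug in config.drugs}
    noise = rng.normal(size=(n_genes, n_samples))

    b = BACKGROUND_VARIANCE_SHARE
    loadings = (
        structure.background_loadings_patient
        if patient_panel
        else structure.background_loadings_cell
    )
    x = np.sqrt(b) * loadings @ background + np.sqrt(1 - b) * noise

    w = SIGNATURE_VARIANCE_SHARE
    for drug in config.drugs:
        for g in structure.signature_genes[drug]:
            if patient_panel and not structure.concordant[g]:
                continue  # discordant: keep the re-drawn background loading
            i = gene_pos[g]
            x[i] = np.sqrt(w) * drug_factors[drug] + np.sqrt(1 - w) * noise[i]

    return _standardize_rows(x), drug_factors


def generate_cell_line_panel(
    config: SimulationConfig,
) -> tuple[ExpressionPanel, dict[str, DrugActivityProfile], pd.Series, GroundTruth]:
    """Generate the in vitro training panel with planted drug signatures.

    Returns
    -------
    panel, profiles, tissue_labels, truth
        Standardized expression panel, one activity profile per drug,
        per-cell-line histology labels, and the ground-truth manifest
        (signature gene lists and concordance flags; patient-level truth is
        filled in later by :func:`generate_patient_cohort`).
    """
    structure = _build_structure(config)
    rng = _rng(config, _CELL_STREAM)
    n = config.n_cell_lines
    sample_ids = [f"CL{i:03d}" for i in range(n)]

    # Balanced histology assignment, randomly permuted across lines.
    tissue_idx = np.tile(np.arange(config.n_tissues), n // config.n_tissues + 1)[:n]
    tissue_idx = rng.permutation(tissue_idx)
    tissue_labels = pd.Series(
        [f"tissue{t}" for t in tissue_idx], index=sample_ids, name="tissue"
    )

    x, _ = _draw_expression(structure, config, rng, n, patient_panel=False)
    panel = ExpressionPanel(
        pd.DataFrame(x, index=structure.gene_ids, columns=sample_ids),
        name="cell_lines",
    )

    gene_pos = {g: i for i, g in enumerate(structure.gene_ids)}
    profiles: dict[str, DrugActivityProfile] = {}
    for d, drug in enumerate(config.drugs):
        sig_rows = [gene_pos[g] for g in structure.signature_genes[drug]]
        signal = (
            config.signature_effect * x[sig_rows].sum(axis=0) if sig_rows else np.zeros(n)
        )
        activity = (
            signal + structure.tissue_offsets[d, tissue_idx] + rng.normal(size=n)
        )
        profiles[drug] = DrugActivityProfile(
            drug=drug, activity=pd.Series(activity, index=sample_ids)
        )

    truth = GroundTruth(
        signature_genes={d: list(v) for d, v in structure.signature_genes.items()},
        concordant=dict(structure.concordant),
    )
    return panel, profiles, tissue_labels, truth


def _true_scores(
    config: SimulationConfig,
    structure: _StudyStructure,
    x: np.ndarray,
) -> np.ndarray:
    """Mean over drugs of the standardized planted-signature projection."""
    gene_pos = {g: i for i, g in enumerate(structure.gene_ids)}
    projections = []
    for drug in config.drugs:
        rows = [gene_pos[g] for g in structure.signature_genes[drug]]
        if not rows:
            continue
        proj = x[rows].sum(axis=0)
        sd = proj.std(ddof=1)
        proj = (proj - proj.mean()) / (sd if sd > 0 else 1.0)
        projections.append(proj)
    if not projections:
        return np.zeros(x.shape[1])
    return np.mean(projections, axis=0)


def generate_patient_cohort(
    config: SimulationConfig,
    truth: GroundTruth,
    cohort_id: int = 0,
    tag: str | None = None,
    n_patients: int | None = None,
) -> PatientCohort:
    """Generate one patient cohort tied to a cell-line study's ground truth.

    ``cohort_id`` selects an independent random stream, so reference,
    combination-fit and validation cohorts can be drawn from the same study
    without sharing patients. Per-patient true scores and response
    probabilities are appended to ``truth.patient_truth[tag]``.
    """
    structure = _build_structure(config)
    if truth.signature_genes != structure.signature_genes:
        raise ConfigValidationError(
            "ground truth does not match this config's gene universe; "
            "it must come from generate_cell_line_panel with the same config"
        )
    rng = _rng(config, _PATIENT_STREAM_BASE + cohort_id)
    n = n_patients if n_patients is not None else config.n_patients
    tag = tag if tag is not None else f"cohort{cohort_id}"
    sample_ids = [f"{tag}_P{i:04d}" for i in range(n)]

    x, _ = _draw_expression(structure, config, rng, n, patient_panel=True)
    panel = ExpressionPanel(
        pd.DataFrame(x, index=structure.gene_ids, columns=sample_ids), name=tag
    )

    score = _true_scores(config, structure, x)
    prob = expit(config.response_intercept + config.response_slope * score)
    pcr = rng.random(n) < prob
    response = pd.Series(np.where(pcr, "pCR", "RD"), index=sample_ids)

    hazard = config.baseline_hazard * np.exp(-config.hazard_log_ratio * score)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(float)

    # Receptor flags mirror the ER- cohorts the generator emulates: every
    # patient is ER-negative; a subset is triple-negative.
    tn = rng.random(n) < 0.6
    subtypes = pd.DataFrame({"ER-": True, "TN": tn}, index=sample_ids)

    truth.patient_truth[tag] = pd.DataFrame(
        {"true_score": score, "response_prob": prob}, index=sample_ids
    )
    return PatientCohort(
        panel=panel,
        response=response,
        survival_time=pd.Series(observed, index=sample_ids),
        event=pd.Series(event, index=sample_ids),
        subtypes=subtypes,
        tag=tag,
    )
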