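"""End-to-end orchestration: discover -> COXEN -> train -> score -> combine -> evaluate.

Two entry points cover the two ways a study is run:

* :func:`run_pipeline` executes a file-based study described by a
  :class:`PipelineConfig` (typically loaded from YAML), writing every
  artifact — per-drug models, percentile tables, reports, KM tables — under
  the configured output directory, stamped with the config hash.
* :func:`run_synthetic_study` runs the same stages in memory on a simulated
  study (cell-line panel plus reference / combination-fit / validation
  cohorts), returning the artifacts and the ground truth for
  parameter-recovery checks.

The COXEN reference cohort is quarantined by construction: the config
validator refuses a study in which the reference cohort doubles as a
validation cohort, and the combination model is fitted once on the
designated fitting cohort and applied unchanged to validation cohorts
(refitting on a validation cohort requires the explicit ``allow_refit``
opt-in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .coxen import select_coxen_genes
from .datatypes import (
    CombinationModel,
    DrugModel,
    EvaluationReport,
    ExpressionPanel,
    GroundTruth,
    PatientCohort,
    SimulationConfig,
)
from .discovery import rank_candidates
from .evaluation import DEFAULT_CUTOFF_FRACTION, evaluate_predictor
from .exceptions import ConfigValidationError
from .modeling import (
    fit_combination,
    fit_drug_model,
    predict_combination,
    score_cohort,
    to_rank_percentile,
)
from .synthetic import generate_cell_line_panel, generate_patient_cohort

logger = logging.getLogger(__name__)

#: Per-drug defaults mirroring the discovery strategy and biomarker-set size
#: that proved optimal for each compound in the original study design.
DEFAULT_METHODS = {"T": "rank_ancova", "F": "welch_t", "A": "pearson", "C": "spearman"}
DEFAULT_N_SELECT = {"T": 33, "F": 56, "A": 27, "C": 68}
DEFAULT_TOP_K = 500


@dataclass
class DrugSettings:
    """Per-drug pipeline choices: discovery method, candidate and set sizes."""

    drug: str
    method: str = "pearson"
    top_k: int = DEFAULT_TOP_K
    n_select: int = 33
    n_components: int | str = "variance"

    @classmethod
    def with_defaults(cls, drug: str, **overrides) -> "DrugSettings":
        base = dict(
            method=DEFAULT_METHODS.get(drug, "pearson"),
            n_select=DEFAULT_N_SELECT.get(drug, 33),
        )
        base.update(overrides)
        return cls(drug=drug, **base)


@dataclass
class CohortPaths:
    """File locations of one patient cohort's tables."""

    expression: str
    response: str | None = None
    survival: str | None = None
    subtypes: str | None = None
    tag: str = "cohort"

    def load(self) -> PatientCohort:
        return pio.read_cohort_tables(
            self.expression, self.response, self.survival, self.subtypes, tag=self.tag
        )


@dataclass
class PipelineConfig:
    """Declarative description of a full file-based study."""

    expression_path: str
    activity_path: str
    coxen_reference: CohortPaths
    combination_fit: CohortPaths
    validation: list[CohortPaths]
    drugs: list[DrugSettings]
    tissue_path: str | None = None
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION
    combination_mode: str = "logistic"
    allow_refit: bool = False
    seed: int = 0
    output_dir: str = "coxenpipe_out"

    def validate(self) -> None:
        ref = Path(self.coxen_reference.expression).resolve()
        for cohort in self.validation:
            if Path(cohort.expression).resolve() == ref:
                raise ConfigValidationError(
                    "COXEN reference cohort cannot also be a validation cohort"
                )
        if not self.drugs:
            raise ConfigValidationError("at least one drug block is required")
        names = [d.drug for d in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigValidationError("duplicate drug blocks")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        def cohort(block: dict, default_tag: str) -> CohortPaths:
            return CohortPaths(
                expression=block["expression"],
                response=block.get("response"),
                survival=block.get("survival"),
                subtypes=block.get("subtypes"),
                tag=block.get("tag", default_tag),
            )

        drugs = [
            DrugSettings.with_defaults(b["drug"], **{k: v for k, v in b.items() if k != "drug"})
            for b in payload["drugs"]
        ]
        return cls(
            expression_path=payload["expression"],
            activity_path=payload["activity"],
            tissue_path=payload.get("tissue"),
            coxen_reference=cohort(payload["coxen_reference"], "coxen_reference"),
            combination_fit=cohort(payload["combination_fit"], "combination_fit"),
            validation=[
                cohort(b, f"validation{i}") for i, b in enumerate(payload["validation"])
            ],
            drugs=drugs,
            cutoff_fraction=payload.get("cutoff_fraction", DEFAULT_CUTOFF_FRACTION),
            combination_mode=payload.get("combination_mode", "logistic"),
            allow_refit=payload.get("allow_refit", False),
            seed=payload.get("seed", 0),
            output_dir=payload.get("output_dir", "coxenpipe_out"),
        )


@dataclass
class StudyResult:
    """Everything one orchestrated run produced, kept in memory."""

    models: dict[str, DrugModel]
    biomarkers: dict[str, list[str]]
    percentiles: dict[str, pd.DataFrame]  # cohort tag -> samples x drugs
    combination: CombinationModel
    combined_scores: dict[str, pd.Series]
    reports: dict[str, EvaluationReport]
    truth: GroundTruth | None = None
    cohorts: dict[str, PatientCohort] = field(default_factory=dict)


def _train_models(
    panel: ExpressionPanel,
    profiles,
    tissue_labels,
    reference_panel: ExpressionPanel,
    drug_settings: list[DrugSettings],
) -> tuple[dict[str, DrugModel], dict[str, list[str]]]:
    models: dict[str, DrugModel] = {}
    biomarkers: dict[str, list[str]] = {}
    for ds in drug_settings:
        if ds.drug not in profiles:
            raise ConfigValidationError(f"no activity profile for drug {ds.drug!r}")
        logger.info("drug %s: discovery (%s, top %d)", ds.drug, ds.method, ds.top_k)
        candidates = rank_candidates(
            panel, profiles[ds.drug], method=ds.method,
            tissue_labels=tissue_labels, top_k=ds.top_k,
        )
        logger.info("drug %s: COXEN selection (n_select=%d)", ds.drug, ds.n_select)
        bset = select_coxen_genes(
            candidates, panel, reference_panel, ds.n_select, drug=ds.drug, method=ds.method
        )
        biomarkers[ds.drug] = bset.genes
        models[ds.drug] = fit_drug_model(
            panel, profiles[ds.drug], bset, n_components_rule=ds.n_components
        )
    return models, biomarkers


def _score_cohorts(
    models: dict[str, DrugModel], cohorts: dict[str, PatientCohort]
) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    for tag, cohort in cohorts.items():
        cols = {}
        for drug, model in models.items():
            raw = score_cohort(model, cohort.panel)
            cols[drug] = to_rank_percentile(raw)
        out[tag] = pd.DataFrame(cols)
    return out


def run_study(
    panel: ExpressionPanel,
    profiles,
    tissue_labels,
    reference_cohort: PatientCohort,
    fit_cohort: PatientCohort,
    validation_cohorts: list[PatientCohort],
    drug_settings: list[DrugSettings],
    combination_mode: str = "logistic",
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    subtype: str | None = None,
) -> StudyResult:
    """Run every stage on in-memory containers and evaluate on each cohort."""
    models, biomarkers = _train_models(
        panel, profiles, tissue_labels, reference_cohort.panel, drug_settings
    )
    cohorts = {fit_cohort.tag: fit_cohort}
    for c in validation_cohorts:
        cohorts[c.tag] = c
    percentiles = _score_cohorts(models, cohorts)

    fit_pct = {d: percentiles[fit_cohort.tag][d] for d in models}
    combination = fit_combination(
        fit_pct, fit_cohort.response, mode=combination_mode, fitting_tag=fit_cohort.tag
    )

    combined_scores: dict[str, pd.Series] = {}
    reports: dict[str, EvaluationReport] = {}
    for tag, cohort in cohorts.items():
        pct = {d: percentiles[tag][d] for d in models}
        combined = predict_combination(combination, pct)
        combined_scores[tag] = combined
        reports[tag] = evaluate_predictor(
            combined,
            cohort,
            subtype=subtype,
            cutoff_fraction=cutoff_fraction,
            predictor_tag="combined[" + "+".join(models) + "]",
        )
    return StudyResult(
        models=models,
        biomarkers=biomarkers,
        percentiles=percentiles,
        combination=combination,
        combined_scores=combined_scores,
        reports=reports,
        cohorts=cohorts,
    )


def run_synthetic_study(
    config: SimulationConfig,
    drug_settings: list[DrugSettings] | None = None,
    combination_mode: str = "logistic",
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    reference_n_patients: int | None = None,
) -> StudyResult:
    """Simulate a paired study and push it through the whole pipeline.

    Three patient cohorts are drawn from independent streams of the same
    study: a COXEN reference cohort (concordance selection only), a
    combination-fit cohort, and a held-out validation cohort.
    """
    panel, profiles, tissue_labels, truth = generate_cell_line_panel(config)
    reference = generate_patient_cohort(
        config, truth, cohort_id=0, tag="reference", n_patients=reference_n_patients
    )
    fit_cohort = generate_patient_cohort(config, truth, cohort_id=1, tag="tuning")
    validation = generate_patient_cohort(config, truth, cohort_id=2, tag="validation")
    if drug_settings is None:
        drug_settings = [DrugSettings.with_defaults(d) for d in config.drugs]
    result = run_study(
        panel,
        profiles,
        tissue_labels,
        reference,
        fit_cohort,
        [validation],
        drug_settings,
        combination_mode=combination_mode,
        cutoff_fraction=cutoff_fraction,
    )
    result.truth = truth
    result.cohorts["reference"] = reference
    return result


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute a file-based study and write all artifacts to disk.

    Artifact layout under ``config.output_dir``::

        models/<drug>_model.json     biomarkers/<drug>_biomarkers.json
        scores/<cohort>_percentiles.tsv  scores/<cohort>_combined.tsv
        reports/<cohort>_report.json     reports/<cohort>_km.tsv
        combination_model.json           run_manifest.json
    """
    config.validate()
    panel = pio.read_expression_matrix(config.expression_path, name="training")
    profiles = pio.read_activity_table(config.activity_path)
    tissue = (
        pio.read_tissue_table(config.tissue_path) if config.tissue_path else None
    )
    reference = config.coxen_reference.load()
    fit_cohort = config.combination_fit.load()
    validation = [c.load() for c in config.validation]

    result = run_study(
        panel,
        profiles,
        tissue,
        reference,
        fit_cohort,
        validation,
        config.drugs,
        combination_mode=config.combination_mode,
        cutoff_fraction=config.cutoff_fraction,
    )

    out = Path(config.output_dir)
    for sub in ("models", "biomarkers", "scores", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for drug, model in result.models.items():
        pio.write_drug_model(model, out / "models" / f"{drug}_model.json")
        pio.write_json(
            {"drug": drug, "genes": result.biomarkers[drug]},
            out / "biomarkers" / f"{drug}_biomarkers.json",
        )
    for tag, pct in result.percentiles.items():
        pio.write_score_table(pct, out / "scores" / f"{tag}_percentiles.tsv")
        pio.write_score_table(
            result.combined_scores[tag].to_frame("combined"),
            out / "scores" / f"{tag}_combined.tsv",
        )
    pio.write_combination_model(result.combination, out / "combination_model.json")
    for tag, report in result.reports.items():
        pio.write_json(report.to_dict(), out / "reports" / f"{tag}_report.json")
        if report.km_curves is not None:
            pio.write_km_table(report.km_curves, out / "reports" / f"{tag}_km.tsv")

    import hashlib
    import json as _json

    cfg_payload = {
        "expression": config.expression_path,
        "activity": config.activity_path,
        "tissue": config.tissue_path,
        "drugs": [vars(d) for d in config.drugs],
        "cutoff_fraction": config.cutoff_fraction,
        "combination_mode": config.combination_mode,
        "seed": config.seed,
    }
    manifest = {
        "config": cfg_payload,
        "config_hash": hashlib.sha256(
            _json.dumps(cfg_payload, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "cohorts": list(result.reports),
    }
    pio.write_json(manifest, out / "run_manifest.json")
    return out
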