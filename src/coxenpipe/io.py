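"""Delimited-text readers/writers and JSON/YAML (de)serialization.

Expression matrices travel as gene x sample delimited text: first column
gene IDs, header row sample IDs, tab-delimited by default with comma
auto-detected. Clinical side tables (activity, tissue, response, survival,
subtype) are one row per sample. Models and ground-truth manifests are JSON;
configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    BiomarkerSet,
    CombinationModel,
    DrugActivityProfile,
    DrugModel,
    ExpressionPanel,
    GroundTruth,
    PatientCohort,
    SimulationConfig,
)
from .exceptions import AlignmentError, ParseError

NA_MARKERS = ["NA", "NaN", ""]


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(
            path,
            sep=_detect_sep(path),
            index_col=index_col,
            na_values=NA_MARKERS,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_expression_matrix(path: str | Path, name: str | None = None) -> ExpressionPanel:
    """Load a gene x sample expression matrix from delimited text."""
    path = Path(path)
    df = _read_table(path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated gene rows: {dup[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene = df.index[bad.any(axis=1)][0]
        # +2: header line plus 1-based numbering
        line = df.index.get_loc(gene) + 2
        raise ParseError(f"{path}:{line}: non-numeric cell in gene {gene!r}")
    return ExpressionPanel(numeric.astype(float), name=name or path.stem)


def write_expression_matrix(panel: ExpressionPanel, path: str | Path) -> None:
    df = panel.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_activity_table(path: str | Path) -> dict[str, DrugActivityProfile]:
    """One column per drug, rows = cell lines."""
    df = _read_table(path)
    return {
        str(drug): DrugActivityProfile(drug=str(drug), activity=df[drug].dropna())
        for drug in df.columns
    }


def write_activity_table(
    profiles: dict[str, DrugActivityProfile], path: str | Path
) -> None:
    df = pd.DataFrame({d: p.activity for d, p in profiles.items()})
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_tissue_table(path: str | Path) -> pd.Series:
    df = _read_table(path)
    return df.iloc[:, 0].astype(str)


def write_tissue_table(tissue: pd.Series, path: str | Path) -> None:
    df = tissue.rename("tissue").to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_cohort_tables(
    expression_path: str | Path,
    response_path: str | Path | None = None,
    survival_path: str | Path | None = None,
    subtype_path: str | Path | None = None,
    tag: str | None = None,
) -> PatientCohort:
    """Assemble a patient cohort from its expression matrix and side tables.

    Side-table sample IDs must be a subset of the expression samples;
    unmatched IDs raise an assembly error naming them.
    """
    panel = read_expression_matrix(expression_path, name=tag)
    samples = set(panel.sample_ids)

    def _check_subset(df: pd.DataFrame | pd.Series, what: str) -> None:
        extra = [s for s in df.index if s not in samples]
        if extra:
            raise AlignmentError(
                f"{what} table has samples absent from expression: {extra[:5]}"
            )

    response = None
    if response_path is not None:
        rdf = _read_table(response_path)
        _check_subset(rdf, "response")
        response = rdf.iloc[:, 0]
    time = event = None
    if survival_path is not None:
        sdf = _read_table(survival_path)
        _check_subset(sdf, "survival")
        time = sdf["time"].astype(float)
        event = sdf["event"].astype(float)
    subtypes = None
    if subtype_path is not None:
        tdf = _read_table(subtype_path)
        _check_subset(tdf, "subtype")
        subtypes = tdf.astype(bool)
    return PatientCohort(
        panel=panel,
        response=response,
        survival_time=time,
        event=event,
        subtypes=subtypes,
        tag=tag or Path(expression_path).stem,
    )


def write_cohort_tables(cohort: PatientCohort, prefix: str | Path) -> dict[str, Path]:
    """Write a cohort as <prefix>_expression/response/survival/subtypes.tsv."""
    prefix = Path(prefix)
    paths: dict[str, Path] = {}
    paths["expression"] = prefix.with_name(prefix.name + "_expression.tsv")
    write_expression_matrix(cohort.panel, paths["expression"])
    if cohort.response is not None:
        p = prefix.with_name(prefix.name + "_response.tsv")
        df = cohort.response.rename("response").to_frame()
        df.index.name = "sample"
        df.to_csv(p, sep="\t", na_rep="NA")
        paths["response"] = p
    if cohort.has_survival:
        p = prefix.with_name(prefix.name + "_survival.tsv")
        df = pd.DataFrame(
            {"time": cohort.survival_time, "event": cohort.event.astype(int)}
        )
        df.index.name = "sample"
        df.to_csv(p, sep="\t")
        paths["survival"] = p
    if cohort.subtypes is not None:
        p = prefix.with_name(prefix.name + "_subtypes.tsv")
        df = cohort.subtypes.astype(int).copy()
        df.index.name = "sample"
        df.to_csv(p, sep="\t")
        paths["subtypes"] = p
    return paths


# ---------------------------------------------------------------------------
# JSON / YAML artifacts
# ---------------------------------------------------------------------------

def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_drug_model(model: DrugModel, path: str | Path) -> None:
    write_json(model.to_dict(), path)


def read_drug_model(path: str | Path) -> DrugModel:
    return DrugModel.from_dict(read_json(path))


def write_combination_model(model: CombinationModel, path: str | Path) -> None:
    write_json(model.to_dict(), path)


def read_combination_model(path: str | Path) -> CombinationModel:
    return CombinationModel.from_dict(read_json(path))


def write_biomarker_set(bset: BiomarkerSet, path: str | Path) -> None:
    write_json(
        {
            "drug": bset.drug,
            "genes": bset.genes,
            "scores": bset.scores,
            "method": bset.method,
            "candidate_size": bset.candidate_size,
        },
        path,
    )


def read_biomarker_set(path: str | Path) -> BiomarkerSet:
    payload = read_json(path)
    return BiomarkerSet(
        drug=payload["drug"],
        genes=list(payload["genes"]),
        scores=dict(payload["scores"]),
        method=payload.get("method", ""),
        candidate_size=int(payload.get("candidate_size", 0)),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    write_json(truth.to_dict(), path)


def write_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return SimulationConfig(**payload)


def write_association_table(results, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "method": [r.method for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "rank": np.arange(1, len(results) + 1),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_association_table(path: str | Path) -> pd.DataFrame:
    return _read_table(path, index_col=None)


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    df = scores.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return _read_table(path)


def write_km_table(curves, path: str | Path) -> None:
    rows = []
    for name, curve in curves.items():
        for t, s in zip(curve.times, curve.survival):
            rows.append({"group": name, "time": t, "survival": s})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
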