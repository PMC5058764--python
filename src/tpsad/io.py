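"""Readers, writers and run configuration.

Cohort tables travel as CSV with one row per patient (booleans as 0/1,
missing values as empty fields); derived tables as TSV. Expression matrices
are TSV (genes in rows, first column the gene id) with a two-column labels
TSV; count matrices are additionally accepted as MatrixMarket triplets with
row/column name sidecars. Configuration is YAML layered over the packaged
defaults.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread

from .cohort import COHORT_COLUMNS, TpsadConstants
from .errors import ValidationError
from .expression import ExpressionStudy
from .simulate import CohortSimParams, ExpressionSimParams

_BOOL_COLUMNS = ["epe", "svi", "positive_margins", "recurrence"]
_OPTIONAL_COLUMNS = ["serum_psa", "gland_weight", "index_tumour_volume"]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a patient table; booleans become 0/1, missing become empty."""
    out = cohort[COHORT_COLUMNS].copy()
    for c in _BOOL_COLUMNS:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a patient table written by :func:`write_cohort_csv`.

    Raises a validation error naming the offending line for malformed rows;
    an empty file with a valid header yields an empty cohort.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed CSV ({exc})") from exc
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        for col in ("prostate_volume", "total_tumour_volume", "followup_time"):
            v = getattr(row, col)
            if not np.isfinite(v):
                raise ValidationError(f"{path}: line {i}: missing required field {col!r}")
    for c in _BOOL_COLUMNS:
        df[c] = df[c].astype(int).astype(bool)
    df["case_id"] = df["case_id"].astype(str)
    for c in ("gleason_primary", "gleason_secondary"):
        df[c] = df[c].astype(int)
    return df


def write_table(table: pd.DataFrame, path) -> None:
    """Write a derived results table as TSV."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_expression_tsv(matrix_path, labels_path, study_id: Optional[str] = None,
                        values_are_log: bool = True) -> ExpressionStudy:
    """Expression TSV (genes x samples, first column gene id) + labels TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index.name = None
    matrix.columns.name = None
    labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    labels.index.name = None
    return ExpressionStudy(
        study_id=study_id or Path(matrix_path).stem,
        matrix=matrix,
        labels=labels,
        values_are_log=values_are_log,
    )


def write_expression_tsv(study: ExpressionStudy, matrix_path, labels_path) -> None:
    study.matrix.rename_axis("gene").to_csv(matrix_path, sep="\t", float_format="%.10g")
    study.labels.rename("class").rename_axis("sample").to_csv(labels_path, sep="\t")


def read_counts(path, genes_path=None, samples_path=None) -> pd.DataFrame:
    """Count matrix from TSV, or MatrixMarket triplet + name sidecars."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if genes_path is None or samples_path is None:
            raise ValidationError("MTX input requires gene and sample sidecar files")
        raw = mmread(path)
        mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        return pd.DataFrame(mat, index=genes, columns=samples)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_geneset(path) -> list[str]:
    """Gene set file: one gene per line, blanks and #-comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if not genes:
        raise ValidationError(f"{path}: no genes")
    return genes


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    constants: TpsadConstants = field(default_factory=TpsadConstants)
    cohort_sim: CohortSimParams = field(default_factory=CohortSimParams)
    expression_sim: ExpressionSimParams = field(default_factory=ExpressionSimParams)
    volume_field: str = "total"
    volumetry_spacing_mm: float = 3.5
    volumetry_shrinkage_factor: float = 1.25
    n_perm: int = 2000
    alpha: float = 0.05
    ihc_low_od: float = 0.8
    ihc_high_od: float = 0.4
    ihc_images_per_group: int = 8
    ihc_region_size: int = 64
    seed: int = 0
    out_dir: str = "tpsad_report"

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "constants": asdict(self.constants),
                "cohort_sim": asdict(self.cohort_sim),
                "expression_sim": asdict(self.expression_sim),
                "volume_field": self.volume_field,
                "n_perm": self.n_perm,
                "alpha": self.alpha,
                "ihc": [self.ihc_low_od, self.ihc_high_od,
                        self.ihc_images_per_group, self.ihc_region_size],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_config_yaml() -> str:
    """The packaged, fully populated default configuration."""
    return (
        importlib.resources.files("tpsad").joinpath("default_config.yaml").read_text()
    )


def _build(cls, mapping: dict):
    known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(mapping) - known
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for k, v in mapping.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Layer a user YAML (and explicit overrides) over the packaged defaults."""
    data = yaml.safe_load(default_config_yaml()) or {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if isinstance(values, dict):
                data.setdefault(section, {}).update(values)
            else:
                data[section] = values
    for key, value in (overrides or {}).items():
        data[key] = value

    volumetry = data.pop("volumetry", {})
    if volumetry:
        data["volumetry_spacing_mm"] = volumetry.get(
            "spacing_mm", data.get("volumetry_spacing_mm", 3.5)
        )
        data["volumetry_shrinkage_factor"] = volumetry.get(
            "shrinkage_factor", data.get("volumetry_shrinkage_factor", 1.25)
        )
    constants = _build(TpsadConstants, data.pop("constants", {}))
    cohort_sim = _build(
        CohortSimParams,
        {**data.pop("cohort_sim", {}), "constants": constants},
    )
    expression_sim = _build(ExpressionSimParams, data.pop("expression_sim", {}))
    return RunConfig(
        constants=constants,
        cohort_sim=cohort_sim,
        expression_sim=expression_sim,
        **data,
    )
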