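"""Core data containers and plain-text readers/writers.

Three tables describe a cohort: a dense gene-by-subject expression matrix,
a subject-by-covariate table of continuous clinical/demographic measures
(with an explicit missing-value mask), and a set of categorical disease
indicators per subject.  A :class:`PipelineConfig` carries every tunable
of the multi-step analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CovariateTable",
    "IndicatorSet",
    "PipelineConfig",
    "ValidationError",
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_indicators",
    "write_indicators",
    "align_subjects",
    "reference_covariate_roster",
    "COVARIATE_CATEGORIES",
    "ALLERGY_CATEGORIES",
]

#: controlled vocabulary of covariate categories
COVARIATE_CATEGORIES = (
    "allergen_screen",
    "blood_chemistry",
    "CBC",
    "clinic",
    "hematology",
    "inflammatory",
    "lipids",
    "lung_function",
    "serum_allergen",
)

#: categories collapsed away when a continuous-only covariate set is needed
ALLERGY_CATEGORIES = frozenset({"allergen_screen", "serum_allergen"})

#: ordered scale tags; preprocessing may only move rightwards
_SCALE_TAGS = ("intensity", "sex_adjusted", "log2")

_ASTHMA_TOKENS = ("asthmatic", "non_asthmatic", "unknown")
_YESNO_TOKENS = ("yes", "no", "unknown")
_LEVEL_TOKENS = ("0", "1", "2", "3", "4", "unknown")

INDICATOR_VOCAB: Mapping[str, tuple[str, ...]] = {
    "confirmed_asthma": _ASTHMA_TOKENS,
    "current_asthma": _YESNO_TOKENS,
    "questionnaire_asthma": _YESNO_TOKENS,
    "phadiatop_level": _LEVEL_TOKENS,
    "foodscreen_level": _LEVEL_TOKENS,
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Dense genes x subjects expression values with named axes."""

    values: np.ndarray
    gene_ids: list[str]
    subject_ids: list[str]
    scale_tag: str = "intensity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.scale_tag not in _SCALE_TAGS:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.subject_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.subject_ids)} subjects"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.subject_ids, "subject")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite and complete")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = list(gene_ids)
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in keep if g not in idx]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(self.values[rows], keep, list(self.subject_ids), self.scale_tag)

    def subset_subjects(self, subject_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = list(subject_ids)
        idx = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise ValidationError(f"unknown subject ids: {missing[:5]}")
        cols = [idx[s] for s in keep]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), keep, self.scale_tag)

    def with_values(self, values: np.ndarray, scale_tag: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values, list(self.gene_ids), list(self.subject_ids), scale_tag or self.scale_tag
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.subject_ids)


@dataclass
class CovariateTable:
    """Subjects x continuous covariates with an explicit missing mask.

    ``values`` holds NaN at masked positions only as an in-memory detail;
    the mask is authoritative and always consistent with the NaN pattern.
    """

    values: np.ndarray
    subject_ids: list[str]
    covariate_ids: list[str]
    categories: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.covariate_ids = [str(c) for c in self.covariate_ids]
        if self.values.shape != (len(self.subject_ids), len(self.covariate_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.covariate_ids)} covariates"
            )
        _check_unique(self.subject_ids, "subject")
        _check_unique(self.covariate_ids, "covariate")
        if self.missing is None:
            self.missing = np.isnan(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValidationError("missing mask shape mismatch")
            if not np.array_equal(self.missing, np.isnan(self.values)):
                raise ValidationError("missing mask inconsistent with NaN pattern")
        for c in self.covariate_ids:
            cat = self.categories.get(c)
            if cat is None:
                raise ValidationError(f"covariate {c!r} has no category")
            if cat not in COVARIATE_CATEGORIES:
                raise ValidationError(
                    f"covariate {c!r} has unknown category {cat!r}; "
                    f"allowed: {', '.join(COVARIATE_CATEGORIES)}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_ids)

    def column(self, covariate_id: str) -> np.ndarray:
        try:
            j = self.covariate_ids.index(covariate_id)
        except ValueError:
            raise KeyError(covariate_id) from None
        return self.values[:, j]

    def subset_subjects(self, subject_ids: Iterable[str]) -> "CovariateTable":
        keep = list(subject_ids)
        idx = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [idx[s] for s in keep]
        return CovariateTable(
            self.values[rows],
            keep,
            list(self.covariate_ids),
            dict(self.categories),
            dict(self.units),
        )

    def subset_covariates(self, covariate_ids: Iterable[str]) -> "CovariateTable":
        keep = list(covariate_ids)
        idx = {c: j for j, c in enumerate(self.covariate_ids)}
        cols = [idx[c] for c in keep]
        return CovariateTable(
            self.values[:, cols],
            list(self.subject_ids),
            keep,
            {c: self.categories[c] for c in keep},
            {c: self.units[c] for c in keep if c in self.units},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.covariate_ids)


@dataclass
class IndicatorSet:
    """Per-subject categorical disease/allergy indicators.

    ``confirmed_asthma`` is the supervision label for the decision tree;
    subjects with unknown confirmed status are excluded from fitting and
    from accuracy computations.
    """

    subject_ids: list[str]
    confirmed_asthma: list[str]
    current_asthma: list[str]
    questionnaire_asthma: list[str]
    phadiatop_level: list[str]
    foodscreen_level: list[str]

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        _check_unique(self.subject_ids, "subject")
        n = len(self.subject_ids)
        for name in INDICATOR_VOCAB:
            col = [str(v) for v in getattr(self, name)]
            if len(col) != n:
                raise ValidationError(f"indicator {name!r} has wrong length")
            allowed = INDICATOR_VOCAB[name]
            for v in col:
                if v not in allowed:
                    raise ValidationError(
                        f"indicator {name!r} value {v!r} not in allowed set "
                        f"{{{', '.join(allowed)}}}"
                    )
            setattr(self, name, col)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def labeled_subjects(self) -> tuple[list[str], np.ndarray]:
        """Subjects with known confirmed asthma, and their binary label.

        Returns (subject_ids, labels) with label 1 = asthmatic, 0 = not.
        """
        ids, labels = [], []
        for s, v in zip(self.subject_ids, self.confirmed_asthma):
            if v != "unknown":
                ids.append(s)
                labels.append(1 if v == "asthmatic" else 0)
        return ids, np.asarray(labels, dtype=int)

    def subset_subjects(self, subject_ids: Iterable[str]) -> "IndicatorSet":
        keep = list(subject_ids)
        idx = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [idx[s] for s in keep]
        return IndicatorSet(
            keep,
            [self.confirmed_asthma[i] for i in rows],
            [self.current_asthma[i] for i in rows],
            [self.questionnaire_asthma[i] for i in rows],
            [self.phadiatop_level[i] for i in rows],
            [self.foodscreen_level[i] for i in rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: getattr(self, name) for name in INDICATOR_VOCAB},
            index=pd.Index(self.subject_ids, name="subject_id"),
        )


@dataclass
class PipelineConfig:
    """All tunables of the multi-step endotype pipeline."""

    family_alpha: float = 0.05
    n_covariate_tests: int | None = None
    iqr_threshold: float = 2000.0
    variance_fraction_min: float = 0.05
    n_gene_clusters: int = 11
    min_leaf_fraction: float = 0.10
    min_leaf_override: int | None = 14
    bootstrap_reps: int = 10000
    rng_seed: int = 0
    gene_ttest_alpha: float = 0.05
    gain_epsilon: float = 1e-6
    log2_floor: float = 1.0
    profile_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if not (0.0 < self.family_alpha < 1.0):
            raise ValidationError("family_alpha must lie in (0, 1)")
        if self.iqr_threshold < 0:
            raise ValidationError("iqr_threshold must be >= 0")
        if not (0.0 < self.variance_fraction_min < 1.0):
            raise ValidationError("variance_fraction_min must lie in (0, 1)")
        if self.min_leaf_override is not None and self.min_leaf_override < 2:
            raise ValidationError("min_leaf must be >= 2")
        if self.n_gene_clusters < 1:
            raise ValidationError("n_gene_clusters must be positive")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be positive")

    def effective_min_leaf(self, n_labeled_subjects: int) -> int:
        """min_leaf_override if set, else floor(min_leaf_fraction * n)."""
        if self.min_leaf_override is not None:
            return int(self.min_leaf_override)
        leaf = math.floor(self.min_leaf_fraction * n_labeled_subjects)
        return max(leaf, 2)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_column(
    df: pd.DataFrame, col: str, path: str | Path, allow_missing: bool
) -> np.ndarray:
    """Exact (round-trippable) float parsing with cell-level error reporting."""
    raw = df[col].to_numpy(dtype=object)
    out = np.empty(raw.shape[0], dtype=float)
    for i, v in enumerate(raw):
        if v is None:
            if allow_missing:
                out[i] = np.nan
                continue
            raise ValidationError(
                f"{path}: missing value at row {df.index[i]!r}, column {col!r}"
            )
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: malformed numeric cell at row {df.index[i]!r}, "
                f"column {col!r}: {v!r}"
            ) from None
    return out


def _parse_numeric_body(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        out[:, j] = _parse_column(df, col, path, allow_missing=False)
    return out


def read_expression(path: str | Path, dialect: str = "tsv_genes_by_subjects") -> ExpressionMatrix:
    """Read a genes-in-rows, subjects-in-columns tab-delimited matrix.

    Expression must be complete: any empty/NA cell is a parse error.
    """
    if dialect != "tsv_genes_by_subjects":
        raise ValidationError(f"unknown expression dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df = df.replace({"": None, "NA": None, "NaN": None, "nan": None})
    gene_ids = [str(g) for g in df.index]
    subject_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(subject_ids, "subject")
    values = _parse_numeric_body(df, path)
    return ExpressionMatrix(values, gene_ids, subject_ids, scale_tag="intensity")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_covariates(path: str | Path, meta_path: str | Path | None = None) -> CovariateTable:
    """Read a subjects-in-rows covariate CSV; empty cells / "NA" are missing.

    Categories and units come from ``meta_path`` (CSV with covariate_id,
    category, unit columns) or, if absent, from a ``<path>.meta.csv``
    sidecar; without either, every covariate defaults to category
    ``clinic`` with empty units.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df = df.replace({"": None, "NA": None, "NaN": None, "nan": None})
    subject_ids = [str(s) for s in df.index]
    covariate_ids = [str(c) for c in df.columns]
    _check_unique(subject_ids, "subject")
    _check_unique(covariate_ids, "covariate")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        values[:, j] = _parse_column(df, col, path, allow_missing=True)

    categories: dict[str, str] = {}
    units: dict[str, str] = {}
    if meta_path is None:
        sidecar = Path(str(path) + ".meta.csv")
        meta_path = sidecar if sidecar.exists() else None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
        for _, row in meta.iterrows():
            categories[str(row["covariate_id"])] = str(row["category"])
            units[str(row["covariate_id"])] = str(row.get("unit", ""))
    for c in covariate_ids:
        categories.setdefault(c, "clinic")
    return CovariateTable(values, subject_ids, covariate_ids, categories, units)


def write_covariates(cov: CovariateTable, path: str | Path, write_meta: bool = True) -> None:
    df = cov.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, na_rep="")
    if write_meta:
        meta = pd.DataFrame(
            {
                "covariate_id": cov.covariate_ids,
                "category": [cov.categories[c] for c in cov.covariate_ids],
                "unit": [cov.units.get(c, "") for c in cov.covariate_ids],
            }
        )
        meta.to_csv(str(path) + ".meta.csv", index=False)


def read_indicators(path: str | Path) -> IndicatorSet:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    missing_cols = [c for c in INDICATOR_VOCAB if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing indicator columns {missing_cols}")
    subject_ids = [str(s) for s in df.index]
    cols = {}
    for name in INDICATOR_VOCAB:
        cols[name] = ["unknown" if v in ("", "NA") else str(v) for v in df[name]]
    return IndicatorSet(subject_ids, **cols)


def write_indicators(ind: IndicatorSet, path: str | Path) -> None:
    ind.to_frame().to_csv(path)


def align_subjects(
    expr: ExpressionMatrix,
    cov: CovariateTable,
    ind: IndicatorSet,
) -> tuple[ExpressionMatrix, CovariateTable, IndicatorSet]:
    """Join the three tables on subject id, dropping non-shared subjects.

    Keeps the expression matrix's subject order restricted to the
    intersection; logs how many subjects each table loses.
    """
    shared = set(expr.subject_ids) & set(cov.subject_ids) & set(ind.subject_ids)
    keep = [s for s in expr.subject_ids if s in shared]
    for name, table in (("expression", expr.subject_ids),
                        ("covariates", cov.subject_ids),
                        ("indicators", ind.subject_ids)):
        dropped = len(table) - len(keep)
        if dropped:
            logger.warning("align_subjects: dropping %d subject(s) from %s", dropped, name)
    if not keep:
        raise ValidationError("no shared subjects between expression/covariates/indicators")
    return expr.subset_subjects(keep), cov.subset_subjects(keep), ind.subset_subjects(keep)


# ---------------------------------------------------------------------------
# Reference covariate roster
# ---------------------------------------------------------------------------

# 81-entry covariate roster used as a metadata fixture: (id, category, unit).
# Categories: 3 allergen_screen + 11 serum_allergen (the 14 allergy
# indicators) + 67 others.
_ROSTER: tuple[tuple[str, str, str], ...] = (
    ("foodscreen", "allergen_screen", "kUA/L"),
    ("phadiatop", "allergen_screen", "kUA/L"),
    ("total_serum_ige", "allergen_screen", "kU/L"),
    ("c_reactive_protein", "blood_chemistry", "mg/ml"),
    ("albumin", "blood_chemistry", "g/dL"),
    ("alkaline_phosphatase", "blood_chemistry", "IU/L"),
    ("sgpt", "blood_chemistry", "IU/L"),
    ("ast", "blood_chemistry", "IU/L"),
    ("sgot", "blood_chemistry", "IU/L"),
    ("albumin_globulin_ratio", "blood_chemistry", ""),
    ("total_bilirubin", "blood_chemistry", "mg/dL"),
    ("blood_urea_nitrogen", "blood_chemistry", "mg/dL"),
    ("bun_creatinine_ratio", "blood_chemistry", ""),
    ("serum_calcium", "blood_chemistry", "mg/dL"),
    ("serum_chloride", "blood_chemistry", "mmol/L"),
    ("serum_creatinine", "blood_chemistry", "mg/dL"),
    ("serum_ferritin", "blood_chemistry", "ng/ml"),
    ("serum_fibrinogen", "blood_chemistry", "mg/dL"),
    ("ggt", "blood_chemistry", "IU/L"),
    ("total_globulin", "blood_chemistry", "g/dL"),
    ("hematocrit", "blood_chemistry", "%"),
    ("hemoglobin", "blood_chemistry", "g/dL"),
    ("serum_iron", "blood_chemistry", "ug/dl"),
    ("lactate_dehydrogenase", "blood_chemistry", "IU/L"),
    ("plasma_leptin", "blood_chemistry", "ng/ml"),
    ("glycated_hemoglobin", "blood_chemistry", "%"),
    ("serum_glucose", "blood_chemistry", "mg/dL"),
    ("potassium", "blood_chemistry", "mmol/L"),
    ("urine_creatinine", "blood_chemistry", "mg/dl"),
    ("arachidonic_acid", "blood_chemistry", "ug/ml"),
    ("serum_osmolality", "blood_chemistry", "mOsmol/kg"),
    ("phospholipids", "blood_chemistry", "mg/dL"),
    ("serum_phosphorus", "blood_chemistry", "mg/dL"),
    ("total_protein", "blood_chemistry", "g/dL"),
    ("sodium", "blood_chemistry", "mmol/L"),
    ("oxygen_saturation", "blood_chemistry", "%"),
    ("wbc_count", "CBC", "K/uL"),
    ("basophil_pct", "CBC", "%"),
    ("eosinophil_pct", "CBC", "%"),
    ("lymphocyte_pct", "CBC", "%"),
    ("monocyte_pct", "CBC", "%"),
    ("neutrophil_pct", "CBC", "%"),
    ("age", "clinic", "years"),
    ("height", "clinic", "cm"),
    ("bmi", "clinic", "kg/m^2"),
    ("weight", "clinic", "kg"),
    ("diastolic_bp", "clinic", "mmHg"),
    ("systolic_bp", "clinic", "mmHg"),
    ("pulse", "clinic", "beats/min"),
    ("rbc_count", "hematology", "M/uL"),
    ("platelet_count", "hematology", "K/uL"),
    ("mch", "hematology", "pg"),
    ("mchc", "hematology", "g/dL"),
    ("mcv", "hematology", "fL"),
    ("rdw", "hematology", "%"),
    ("interleukin_4", "inflammatory", "pg/ml"),
    ("total_antioxidant_status", "inflammatory", "mmol/L"),
    ("unbound_iron_binding_capacity", "inflammatory", "ug/dl"),
    ("uric_acid", "inflammatory", "mg/dL"),
    ("reactive_oxygen_species", "inflammatory", "RLU"),
    ("hdl", "lipids", "mg/dL"),
    ("ldl", "lipids", "mg/dL"),
    ("cholesterol_hdl_ratio", "lipids", ""),
    ("total_cholesterol", "lipids", "mg/dL"),
    ("triglycerides", "lipids", "mg/dL"),
    ("vldl", "lipids", "mg/dL"),
    ("fef_25_75", "lung_function", ""),
    ("feno", "lung_function", "ppb"),
    ("fev1_fvc_ratio", "lung_function", "%"),
    ("peak_expiratory_flow", "lung_function", "L/min"),
    ("serum_alternaria_alternata", "serum_allergen", "kUA/L"),
    ("serum_aspergillus_fumigatus", "serum_allergen", "kUA/L"),
    ("serum_cat_dander", "serum_allergen", "kUA/L"),
    ("serum_cladosporium_herbarum", "serum_allergen", "kUA/L"),
    ("serum_derm_farinae", "serum_allergen", "kUA/L"),
    ("serum_derm_pteronyssinus", "serum_allergen", "kUA/L"),
    ("serum_dog_dander", "serum_allergen", "kUA/L"),
    ("serum_german_cockroach", "serum_allergen", "kUA/L"),
    ("serum_mouse_urine_protein", "serum_allergen", "kUA/L"),
    ("serum_penicillium_notatum", "serum_allergen", "kUA/L"),
    ("serum_rat_urine_protein", "serum_allergen", "kUA/L"),
)


def reference_covariate_roster() -> pd.DataFrame:
    """The 81-covariate reference roster as a metadata table.

    Columns: covariate_id, category, unit. 14 entries belong to the two
    allergy categories; 67 are continuous clinical/demographic covariates.
    """
    return pd.DataFrame(_ROSTER, columns=["covariate_id", "category", "unit"])
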