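"""Expression and covariate preprocessing.

Fixed expression pipeline order: linear sex adjustment (residual plus
per-gene grand mean), IQR variability filter, then log2 transform.
Covariate preparation: mean imputation, removal of the allergy-indicator
categories, and quantile categorization of the two allergy summaries.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .cohort_model import (
    ALLERGY_CATEGORIES,
    CovariateTable,
    ExpressionMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "adjust_for_sex",
    "iqr_filter",
    "log2_transform",
    "mean_impute",
    "allergy_levels",
    "split_covariates",
    "sex_effect_report",
]


def adjust_for_sex(expr: ExpressionMatrix, sex: np.ndarray) -> ExpressionMatrix:
    """Remove a per-gene linear sex effect, keeping each gene's grand mean.

    For every gene, fits value ~ intercept + sex by least squares and
    returns residual + grand mean.  With a binary regressor this equals
    centering each sex group at the gene's grand mean, which preserves
    positivity of intensity data for the later log step.
    """
    if expr.scale_tag != "intensity":
        raise ValidationError(
            f"adjust_for_sex expects scale_tag 'intensity', got {expr.scale_tag!r}"
        )
    sex = np.asarray(sex)
    if sex.shape != (expr.n_subjects,):
        raise ValidationError("sex vector length must equal number of subjects")
    groups = np.unique(sex)
    if groups.size < 2:
        raise ValidationError("sex adjustment undefined for a single-sex cohort")
    if groups.size > 2:
        raise ValidationError("sex must be binary")

    X = expr.values
    grand = X.mean(axis=1, keepdims=True)
    fitted = np.empty_like(X)
    for g in groups:
        cols = sex == g
        fitted[:, cols] = X[:, cols].mean(axis=1, keepdims=True)
    adjusted = X - fitted + grand
    return expr.with_values(adjusted, scale_tag="sex_adjusted")


def iqr_filter(
    expr: ExpressionMatrix, threshold: float
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep genes whose inter-quartile range strictly exceeds ``threshold``.

    Quartiles use linear interpolation between order statistics.
    Returns the filtered matrix and the kept gene ids.
    """
    if threshold < 0:
        raise ValidationError("iqr threshold must be >= 0")
    q1, q3 = np.quantile(expr.values, [0.25, 0.75], axis=1, method="linear")
    keep = (q3 - q1) > threshold
    kept_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    logger.info("iqr_filter: kept %d of %d genes at threshold %g",
                len(kept_ids), expr.n_genes, threshold)
    if not kept_ids:
        logger.warning("iqr_filter: no genes passed threshold %g", threshold)
        empty = ExpressionMatrix(
            np.empty((0, expr.n_subjects)), [], list(expr.subject_ids), expr.scale_tag
        )
        return empty, []
    return expr.subset_genes(kept_ids), kept_ids


def log2_transform(expr: ExpressionMatrix, floor_value: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2 after clamping values below ``floor_value``."""
    if expr.scale_tag != "sex_adjusted":
        raise ValidationError(
            f"log2_transform expects scale_tag 'sex_adjusted', got {expr.scale_tag!r}"
        )
    if floor_value <= 0:
        raise ValidationError("floor_value must be positive")
    n_clamped = int(np.sum(expr.values < floor_value))
    if n_clamped:
        logger.info("log2_transform: clamped %d value(s) to floor %g", n_clamped, floor_value)
    clamped = np.maximum(expr.values, floor_value)
    return expr.with_values(np.log2(clamped), scale_tag="log2")


def mean_impute(cov: CovariateTable) -> CovariateTable:
    """Replace each missing cell by its covariate's observed mean."""
    values = cov.values.copy()
    n_imputed_total = 0
    for j, cid in enumerate(cov.covariate_ids):
        col = values[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if miss.all():
            raise ValidationError(f"covariate {cid!r} is fully missing; cannot impute")
        col[miss] = col[~miss].mean()
        n_imputed_total += int(miss.sum())
        logger.info("mean_impute: %s <- %d value(s)", cid, int(miss.sum()))
    if n_imputed_total == 0:
        return cov
    logger.info("mean_impute: %d cell(s) imputed in total", n_imputed_total)
    return CovariateTable(
        values, list(cov.subject_ids), list(cov.covariate_ids),
        dict(cov.categories), dict(cov.units),
    )


def allergy_levels(values: np.ndarray, n_levels: int = 5) -> np.ndarray:
    """Ordinal allergy level per subject from equal-probability quantile bins.

    Level 0 is the lowest ("not allergic") and ``n_levels - 1`` the highest.
    A value equal to a cut point falls in the lower bin.  Cut points are
    the type-7 (linear interpolation) quantiles of the observed values;
    NaN inputs propagate to NaN levels.
    """
    if n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        raise ValidationError("allergy_levels: no observed values")
    if np.unique(obs).size < n_levels:
        warnings.warn(
            f"fewer distinct values ({np.unique(obs).size}) than bins ({n_levels}); "
            "some bins will be empty",
            stacklevel=2,
        )
    cuts = np.quantile(obs, [i / n_levels for i in range(1, n_levels)], method="linear")
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    # level = number of cut points strictly below the value (ties -> lower bin)
    out[ok] = (values[ok, None] > cuts[None, :]).sum(axis=1)
    return out


def split_covariates(
    cov: CovariateTable,
) -> tuple[CovariateTable, tuple[np.ndarray | None, np.ndarray | None]]:
    """Drop allergy-indicator covariates, returning the continuous rest.

    Removes every covariate categorised as allergen_screen or
    serum_allergen and returns, alongside the reduced table, the
    phadiatop and foodscreen summary vectors (matched by id substring)
    for quantile categorization; either is None when absent.
    """
    keep = [c for c in cov.covariate_ids if cov.categories[c] not in ALLERGY_CATEGORIES]
    dropped = cov.n_covariates - len(keep)
    if dropped:
        logger.info("split_covariates: removed %d allergy-category covariate(s)", dropped)

    def _find(token: str) -> np.ndarray | None:
        hits = [c for c in cov.covariate_ids if token in c.lower()]
        if not hits:
            logger.warning("split_covariates: no %s covariate found", token)
            return None
        return cov.column(hits[0]).copy()

    continuous = cov.subset_covariates(keep) if dropped else cov
    return continuous, (_find("phadiatop"), _find("foodscreen"))


def sex_effect_report(expr: ExpressionMatrix, sex: np.ndarray) -> dict:
    """Diagnostic: association of the top principal component with sex.

    Reports |Pearson r| between subject scores on the first PC of the
    gene-centered matrix and the binary sex vector, plus the PC's
    variance fraction.  Purely informational; never triggers adjustment.
    """
    sex = np.asarray(sex, dtype=float)
    X = expr.values - expr.values.mean(axis=1, keepdims=True)
    # subjects-space SVD; right singular vectors give subject scores
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = vt[0]
    if np.std(sex) == 0 or np.std(pc1) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pc1, sex)[0, 1])
    var_frac = float(s[0] ** 2 / np.sum(s**2)) if s.size else 0.0
    return {"pc1_sex_abs_r": abs(r), "pc1_variance_fraction": var_frac}
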