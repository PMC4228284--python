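"""Gene-covariate correlation screen and gene clustering.

Step 1: Pearson correlation of every covariate with every gene using
pairwise-complete subjects, with a Bonferroni-corrected per-test alpha.
Step 2: complete-linkage hierarchical clustering of the selected genes'
absolute-correlation profiles.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .cohort_model import CovariateTable, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "GeneClusterSet",
    "correlate",
    "per_test_alpha",
    "select_genes",
    "cluster_genes",
    "cluster_letter",
]

_PROFILE_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock",
                    "correlation": "correlation"}


@dataclass
class CorrelationResult:
    """Covariates x genes Pearson r / p matrices plus the gene selection."""

    r: np.ndarray
    p: np.ndarray
    covariate_ids: list[str]
    gene_ids: list[str]
    n_used: np.ndarray
    per_test_alpha: float | None = None
    selected_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.shape != self.p.shape:
            raise ValidationError("r and p must share shape")
        if self.r.shape != (len(self.covariate_ids), len(self.gene_ids)):
            raise ValidationError("correlation matrix shape mismatch")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValidationError("|r| must not exceed 1")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValidationError("p-values must lie in [0, 1]")

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.covariate_ids, columns=self.gene_ids)

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.covariate_ids, columns=self.gene_ids)

    def best_covariate_table(self) -> pd.DataFrame:
        """Per selected gene: best covariate, its r and p."""
        rows = []
        gidx = {g: j for j, g in enumerate(self.gene_ids)}
        for g in self.selected_gene_ids:
            j = gidx[g]
            i = int(np.argmin(self.p[:, j]))
            rows.append((g, self.covariate_ids[i], self.r[i, j], self.p[i, j]))
        return pd.DataFrame(rows, columns=["gene_id", "best_covariate", "r", "p"])


@dataclass
class GeneClusterSet:
    """Cut of the gene dendrogram into k named clusters ("A", "B", ...)."""

    labels: dict[str, str]
    k: int
    linkage_record: np.ndarray

    def __post_init__(self) -> None:
        ids = set(self.labels.values())
        if len(ids) != self.k:
            raise ValidationError(
                f"expected {self.k} clusters, found {len(ids)} distinct labels"
            )

    def members(self, cluster_id: str) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == cluster_id)

    def cluster_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.labels.values():
            if c not in seen:
                seen.append(c)
        return sorted(seen, key=lambda c: (len(c), c))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["gene_id", "cluster"]
        )


def cluster_letter(i: int) -> str:
    """0 -> "A", 25 -> "Z", 26 -> "AA", ... (spreadsheet-style)."""
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = letters[rem] + out
    return out


def correlate(expr: ExpressionMatrix, cov: CovariateTable) -> CorrelationResult:
    """Pearson r and two-sided p for every (covariate, gene) pair.

    Missing covariate values are handled by pairwise-complete deletion;
    two-sided p-values come from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2
    degrees of freedom.  Zero-variance pairs get r=0, p=1 with a warning.
    """
    if expr.subject_ids != cov.subject_ids:
        raise ValidationError("expression and covariates must share subject order")
    n_cov, n_gene = cov.n_covariates, expr.n_genes
    r = np.zeros((n_cov, n_gene))
    p = np.ones((n_cov, n_gene))
    n_used = np.zeros(n_cov, dtype=int)
    G = expr.values  # genes x subjects, complete by invariant

    for i, cid in enumerate(cov.covariate_ids):
        c = cov.values[:, i]
        ok = ~np.isnan(c)
        n = int(ok.sum())
        n_used[i] = n
        if n < 3:
            warnings.warn(f"covariate {cid!r}: fewer than 3 observed subjects", stacklevel=2)
            continue
        cv = c[ok]
        gv = G[:, ok]
        cc = cv - cv.mean()
        gc = gv - gv.mean(axis=1, keepdims=True)
        c_ss = float(cc @ cc)
        g_ss = np.einsum("ij,ij->i", gc, gc)
        if c_ss == 0.0:
            warnings.warn(f"covariate {cid!r} has zero variance; r set to 0", stacklevel=2)
            continue
        zero_genes = g_ss == 0.0
        if zero_genes.any():
            warnings.warn(
                f"{int(zero_genes.sum())} zero-variance gene(s) against covariate {cid!r}",
                stacklevel=2,
            )
        denom = np.sqrt(c_ss * np.where(zero_genes, 1.0, g_ss))
        ri = np.where(zero_genes, 0.0, (gc @ cc) / denom)
        ri = np.clip(ri, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = ri * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - ri**2, 0.0))
        pi = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pi = np.where(zero_genes, 1.0, np.minimum(pi, 1.0))
        pi = np.where(np.abs(ri) >= 1.0, 0.0, pi)
        pi = np.where(zero_genes, 1.0, pi)
        r[i], p[i] = ri, pi

    return CorrelationResult(
        r, p, list(cov.covariate_ids), list(expr.gene_ids), n_used
    )


def per_test_alpha(family_alpha: float, m: int) -> float:
    """Bonferroni per-test threshold: family_alpha / m."""
    if m < 1:
        raise ValidationError("number of tests m must be >= 1")
    if not (0 < family_alpha < 1):
        raise ValidationError("family_alpha must lie in (0, 1)")
    return family_alpha / m


def select_genes(corr: CorrelationResult, alpha: float | None = None) -> list[str]:
    """Genes whose minimum p across covariates is below the per-test alpha.

    Mutates ``corr`` in place (sets per_test_alpha and selected_gene_ids)
    and returns the selected ids in input gene order.
    """
    if alpha is None:
        alpha = corr.per_test_alpha
    if alpha is None:
        raise ValidationError("per-test alpha not set")
    corr.per_test_alpha = float(alpha)
    min_p = corr.p.min(axis=0)
    selected = [g for g, mp in zip(corr.gene_ids, min_p) if mp < alpha]
    corr.selected_gene_ids = selected
    if not selected:
        logger.warning("select_genes: no genes passed alpha %g", alpha)
    else:
        logger.info("select_genes: %d of %d genes selected at alpha %g",
                    len(selected), len(corr.gene_ids), alpha)
    return selected


def cluster_genes(
    corr: CorrelationResult, k: int, metric: str = "euclidean"
) -> GeneClusterSet:
    """Complete-linkage clustering of selected genes' |r| profiles.

    Genes are represented by their vector of absolute correlations across
    covariates; profile distances default to Euclidean.  The dendrogram is
    cut to exactly k clusters, named "A", "B", ... in dendrogram leaf
    order.  Genes are sorted lexicographically beforehand so ties break
    deterministically.
    """
    genes = sorted(corr.selected_gene_ids)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(genes):
        raise ValidationError(
            f"k={k} exceeds number of selected genes ({len(genes)})"
        )
    if metric not in _PROFILE_METRICS:
        raise ValidationError(
            f"unknown profile metric {metric!r}; allowed: {sorted(_PROFILE_METRICS)}"
        )
    gidx = {g: j for j, g in enumerate(corr.gene_ids)}
    profiles = np.abs(corr.r[:, [gidx[g] for g in genes]]).T  # genes x covariates
    if len(genes) == 1:
        return GeneClusterSet({genes[0]: "A"}, 1, np.empty((0, 4)))
    d = pdist(profiles, metric=_PROFILE_METRICS[metric])
    Z = linkage(d, method="complete")
    flat = fcluster(Z, t=k, criterion="maxclust")
    n_found = len(np.unique(flat))
    if n_found != k:
        # maxclust can undershoot only with tied heights; fall back to a
        # height-ordered cut that always yields exactly k groups
        raise ValidationError(
            f"dendrogram cut produced {n_found} clusters instead of {k}"
        )
    # name clusters by dendrogram leaf order for stable A, B, ... ids
    order = leaves_list(Z)
    name_of: dict[int, str] = {}
    for leaf in order:
        c = int(flat[leaf])
        if c not in name_of:
            name_of[c] = cluster_letter(len(name_of))
    labels = {g: name_of[int(flat[j])] for j, g in enumerate(genes)}
    return GeneClusterSet(labels, k, Z)


def silhouette_by_k(
    corr: CorrelationResult, k_values: range | list[int], metric: str = "euclidean"
) -> pd.DataFrame:
    """Mean silhouette of the |r|-profile clustering for each k (guidance only)."""
    from .baselines import silhouette_index

    genes = sorted(corr.selected_gene_ids)
    gidx = {g: j for j, g in enumerate(corr.gene_ids)}
    profiles = np.abs(corr.r[:, [gidx[g] for g in genes]]).T
    rows = []
    for k in k_values:
        if k < 2 or k >= len(genes):
            continue
        cs = cluster_genes(corr, k, metric=metric)
        lab = np.array([cs.labels[g] for g in genes])
        rows.append((k, silhouette_index(profiles, lab, distance=metric
                                         if metric != "manhattan" else "manhattan")))
    return pd.DataFrame(rows, columns=["k", "mean_silhouette"])
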