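"""Metagene construction: per-cluster PCA over subjects.

Each gene cluster's centered expression block is decomposed by SVD;
every principal component explaining at least a configurable fraction of
the cluster's variance becomes a "metagene" of subject-wise scores,
named "<cluster>-<component>" (e.g. "F-2").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import ExpressionMatrix, ValidationError
from .gene_covariate_map import GeneClusterSet

logger = logging.getLogger(__name__)

__all__ = ["MetageneSet", "build_metagenes", "project"]


@dataclass
class MetageneSet:
    """Subject-wise PC scores per gene cluster plus projection metadata."""

    scores: np.ndarray  # subjects x metagenes
    subject_ids: list[str]
    names: list[str]
    cluster_of: dict[str, str]
    loadings: dict[str, pd.Series]  # metagene -> unit-norm weights over member genes
    variance_fraction: dict[str, float]
    gene_means: dict[str, pd.Series] = field(default_factory=dict)  # cluster -> centering means

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.subject_ids), len(self.names)):
            raise ValidationError("metagene score matrix shape mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("metagene names must be unique")

    @property
    def n_metagenes(self) -> int:
        return len(self.names)

    def score_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.subject_ids, columns=self.names)

    def counts_per_cluster(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.names:
            out[self.cluster_of[m]] = out.get(self.cluster_of[m], 0) + 1
        return out


def build_metagenes(
    expr: ExpressionMatrix,
    clusters: GeneClusterSet,
    variance_fraction_min: float = 0.05,
) -> MetageneSet:
    """One PCA per gene cluster; retain components explaining enough variance.

    Genes are centered (no variance scaling); components come from the SVD
    of the centered genes x subjects block, variance fractions from squared
    singular values over their total.  The sign convention makes each
    loading vector's largest-magnitude element positive.  A single-gene
    cluster yields one metagene equal to the centered gene.
    """
    if expr.scale_tag != "log2":
        raise ValidationError(
            f"build_metagenes expects scale_tag 'log2', got {expr.scale_tag!r}"
        )
    if expr.n_subjects < 2:
        raise ValidationError("need at least 2 subjects for PCA")
    if not (0 < variance_fraction_min < 1):
        raise ValidationError("variance_fraction_min must lie in (0, 1)")

    names: list[str] = []
    cluster_of: dict[str, str] = {}
    loadings: dict[str, pd.Series] = {}
    var_frac: dict[str, float] = {}
    gene_means: dict[str, pd.Series] = {}
    score_cols: list[np.ndarray] = []

    for cid in clusters.cluster_ids():
        genes = clusters.members(cid)
        if not genes:
            raise ValidationError(f"cluster {cid!r} is empty")
        block = expr.subset_genes(genes)
        means = block.values.mean(axis=1)
        centered = block.values - means[:, None]
        gene_means[cid] = pd.Series(means, index=genes)

        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        total = float(np.sum(s**2))
        if total == 0.0:
            logger.warning("cluster %s has zero variance; emitting flat metagene", cid)
            fracs = np.zeros(s.shape)
            fracs[0] = 1.0
        else:
            fracs = s**2 / total
        n_kept = 0
        for comp in range(s.size):
            frac = float(fracs[comp])
            if frac < variance_fraction_min:
                break  # fractions are non-increasing
            load = u[:, comp].copy()
            score = s[comp] * vt[comp, :]
            pivot = int(np.argmax(np.abs(load)))
            if load[pivot] < 0:
                load = -load
                score = -score
            n_kept += 1
            name = f"{cid}-{n_kept}"
            names.append(name)
            cluster_of[name] = cid
            loadings[name] = pd.Series(load, index=genes)
            var_frac[name] = frac
            score_cols.append(score)
        if n_kept == 0:
            logger.warning(
                "cluster %s: no component reached variance fraction %g; "
                "cluster contributes no metagene", cid, variance_fraction_min,
            )
        else:
            logger.info("cluster %s: %d metagene(s) retained", cid, n_kept)

    if score_cols:
        scores = np.column_stack(score_cols)
    else:
        scores = np.empty((expr.n_subjects, 0))
    return MetageneSet(
        scores, list(expr.subject_ids), names, cluster_of, loadings, var_frac, gene_means
    )


def project(metagenes: MetageneSet, expr_new: ExpressionMatrix) -> pd.DataFrame:
    """Score new subjects on the stored loadings and centering means.

    Projecting the training matrix reproduces the training scores.
    """
    gidx = {g: i for i, g in enumerate(expr_new.gene_ids)}
    cols = {}
    for name in metagenes.names:
        cid = metagenes.cluster_of[name]
        load = metagenes.loadings[name]
        means = metagenes.gene_means[cid]
        missing = [g for g in load.index if g not in gidx]
        if missing:
            raise ValidationError(
                f"metagene {name!r}: expression lacks member gene(s) {missing[:5]}"
            )
        rows = [gidx[g] for g in load.index]
        centered = expr_new.values[rows, :] - means.to_numpy()[:, None]
        cols[name] = load.to_numpy() @ centered
    return pd.DataFrame(cols, index=expr_new.subject_ids)[metagenes.names]
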