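"""Comparison methods: gene-wise t-tests, internal-validity clustering
scans, and weighted multi-domain k-prototypes ("Modk") clustering.

The validity scan grids (distance x clustering method x k) are scored by
three internal indices: mean Silhouette (max is best), the Goodman-Kruskal
Gamma adaptation (max is best), and the C index (min is best).  Modk
alternates assignment/update over three weighted blocks: squared
Euclidean for the two numeric domains and simple matching for the
categorical indicator domain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .cohort_model import ValidationError
from .endotype_tree import LABEL_NAMES, SegregationReport

logger = logging.getLogger(__name__)

__all__ = [
    "ModkConfig",
    "ModkResult",
    "MODK_WEIGHT_PRESETS",
    "gene_ttests",
    "silhouette_index",
    "gamma_index",
    "c_index",
    "validity_scan",
    "modk_fit",
    "modk_biomarkers",
    "modk_accuracy",
]

#: preset domain weighting schemes (expression, clinical, indicators)
MODK_WEIGHT_PRESETS: dict[str, tuple[float, float, float]] = {
    "33/33/33": (1 / 3, 1 / 3, 1 / 3),
    "20/40/40": (0.20, 0.40, 0.40),
    "40/20/40": (0.40, 0.20, 0.40),
    "50/50/0": (0.50, 0.50, 0.00),
    "30/60/10": (0.30, 0.60, 0.10),
    "60/30/10": (0.60, 0.30, 0.10),
    "40/40/20": (0.40, 0.40, 0.20),
    "adaptive": None,
}

_DISTANCES = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "chebyshev": "chebyshev",
    "canberra": "canberra",
    "bray_curtis": "braycurtis",
    "squared_euclidean": "sqeuclidean",
}

_METHODS = ("kmeans", "pam", "hier_single", "hier_complete", "hier_average", "hier_ward")


# ---------------------------------------------------------------------------
# Gene-wise two-sample t-tests
# ---------------------------------------------------------------------------


def gene_ttests(
    expr_values: np.ndarray,
    gene_ids: list[str],
    labels: np.ndarray,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Pooled-variance two-sample t per gene, two-sided.

    Returns a frame with t, p, a flag at ``alpha`` and a
    Bonferroni-adjusted flag at ``alpha / n_genes``.  Degenerate
    (zero pooled variance) genes get p = 1 with a warning.
    """
    X = np.asarray(expr_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    g0 = X[:, labels == 0]
    g1 = X[:, labels == 1]
    n0, n1 = g0.shape[1], g1.shape[1]
    if n0 < 2 or n1 < 2:
        raise ValidationError("need at least 2 subjects per group")
    m0, m1 = g0.mean(axis=1), g1.mean(axis=1)
    v0 = g0.var(axis=1, ddof=1)
    v1 = g1.var(axis=1, ddof=1)
    if welch:
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v0 / n0 + v1 / n1
            t = (m0 - m1) / np.sqrt(se2)
            df = se2**2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
    else:
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m0 - m1) / np.sqrt(sp2 * (1 / n0 + 1 / n1))
        df = np.full(X.shape[0], n0 + n1 - 2, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero pooled variance; p set to 1",
            stacklevel=2,
        )
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), df=df))
    t = np.where(degenerate, 0.0, t)
    bonf = alpha / X.shape[0]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "t": t,
            "p": p,
            "significant": p < alpha,
            "significant_bonferroni": p < bonf,
        }
    )


# ---------------------------------------------------------------------------
# Internal validity indices (all from a point matrix + labels + distance)
# ---------------------------------------------------------------------------


def _as_points(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def silhouette_index(X: np.ndarray, labels: np.ndarray, distance: str = "euclidean") -> float:
    """Mean silhouette width; singleton clusters score 0, as do points
    with a = b = 0."""
    X = _as_points(X)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    D = squareform(pdist(X, metric=_DISTANCES[distance]))
    n = X.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = int(own.sum())
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def _pair_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    within = labels[iu] == labels[ju]
    return within, ~within


def gamma_index(X: np.ndarray, labels: np.ndarray, distance: str = "euclidean") -> float:
    """Goodman-Kruskal Gamma over (within, between) distance comparisons.

    s+ counts comparisons where the within-cluster distance is smaller,
    s- where it is larger; ties count for neither.  Gamma =
    (s+ - s-)/(s+ + s-), with 0/0 -> 0.
    """
    X = _as_points(X)
    d = pdist(X, metric=_DISTANCES[distance])
    within, between = _pair_masks(labels)
    if not within.any() or not between.any():
        raise ValidationError("need at least one within- and one between-cluster pair")
    dw = np.sort(d[within])
    db = np.sort(d[between])
    # for each within distance: number of between distances greater / smaller
    greater = db.size - np.searchsorted(db, dw, side="right")
    smaller = np.searchsorted(db, dw, side="left")
    s_plus = int(greater.sum())
    s_minus = int(smaller.sum())
    if s_plus + s_minus == 0:
        return 0.0
    return float((s_plus - s_minus) / (s_plus + s_minus))


def c_index(X: np.ndarray, labels: np.ndarray, distance: str = "euclidean") -> float:
    """Hubert-Levine C: (S - S_min)/(S_max - S_min) over within-pair sums."""
    X = _as_points(X)
    d = pdist(X, metric=_DISTANCES[distance])
    within, _ = _pair_masks(labels)
    n_w = int(within.sum())
    if n_w == 0:
        raise ValidationError("need at least one within-cluster pair")
    S = float(d[within].sum())
    d_sorted = np.sort(d)
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum())
    if s_max == s_min:
        return 0.0
    return float((S - s_min) / (s_max - s_min))


# ---------------------------------------------------------------------------
# Clustering drivers for the validity scan
# ---------------------------------------------------------------------------


def _kmedoids(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Simple deterministic PAM-style k-medoids on a distance matrix.

    Init: first medoid minimizes total distance; the rest are chosen
    farthest-first.  Alternates assignment and medoid refreshment.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_near = D[:, medoids].min(axis=1)
        dist_to_near[medoids] = -1
        medoids.append(int(np.argmax(dist_to_near)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            sub = D[np.ix_(members, members)]
            new_medoids[c] = members[int(np.argmin(sub.sum(axis=1)))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def _cluster_once(
    X: np.ndarray, D: np.ndarray, d_cond: np.ndarray, method: str, k: int, seed: int
) -> np.ndarray | None:
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(X)
    if method == "pam":
        return _kmedoids(D, k)
    if method.startswith("hier_"):
        link = method.removeprefix("hier_")
        Z = linkage(d_cond, method=link)
        return fcluster(Z, t=k, criterion="maxclust")
    raise ValidationError(f"unknown clustering method {method!r}")


def validity_scan(
    X: np.ndarray,
    domain_tag: str,
    distances: list[str] | None = None,
    methods: list[str] | None = None,
    k_range: range | list[int] = range(2, 11),
    seed: int = 0,
) -> pd.DataFrame:
    """Score every (distance, method, k) combination with all three indices.

    Returns the grid as a frame with a ``best`` marker column identifying
    the argmax-silhouette, argmax-gamma and argmin-C rows.  Combinations
    that are infeasible (Ward or k-means with a non-Euclidean distance)
    are skipped with a log entry.
    """
    X = _as_points(X)
    n = X.shape[0]
    distances = distances or list(_DISTANCES)
    methods = methods or list(_METHODS)
    rows = []
    for dist in distances:
        if dist not in _DISTANCES:
            raise ValidationError(f"unknown distance {dist!r}")
        d_cond = pdist(X, metric=_DISTANCES[dist])
        D = squareform(d_cond)
        for method in methods:
            if method not in _METHODS:
                raise ValidationError(f"unknown method {method!r}")
            if method in ("kmeans", "hier_ward") and dist not in (
                "euclidean",
                "squared_euclidean",
            ):
                logger.info("validity_scan: skipping %s with %s distance", method, dist)
                continue
            for k in k_range:
                if not (2 <= k <= n - 1):
                    raise ValidationError(f"k={k} outside [2, n-1]")
                labels = _cluster_once(X, D, d_cond, method, k, seed)
                if len(np.unique(labels)) < 2:
                    logger.info(
                        "validity_scan: %s/%s/k=%d collapsed to one cluster; skipped",
                        dist, method, k,
                    )
                    continue
                rows.append(
                    (
                        domain_tag,
                        dist,
                        method,
                        k,
                        silhouette_index(X, labels, dist),
                        gamma_index(X, labels, dist),
                        c_index(X, labels, dist),
                    )
                )
    scan = pd.DataFrame(
        rows,
        columns=["domain", "distance", "method", "k", "silhouette", "gamma", "c_index"],
    )
    scan["best"] = ""
    if len(scan):
        scan.loc[scan["silhouette"].idxmax(), "best"] += "silhouette;"
        scan.loc[scan["gamma"].idxmax(), "best"] += "gamma;"
        scan.loc[scan["c_index"].idxmin(), "best"] += "c_index;"
    return scan


# ---------------------------------------------------------------------------
# Modk-prototypes
# ---------------------------------------------------------------------------


@dataclass
class ModkConfig:
    k: int = 8
    weights: tuple[float, float, float] | None = (1 / 3, 1 / 3, 1 / 3)
    adaptive: bool = False
    max_iter: int = 100
    n_starts: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if not self.adaptive:
            if self.weights is None:
                raise ValidationError("fixed-weight mode requires weights")
            w = np.asarray(self.weights, dtype=float)
            if w.size != 3 or np.any(w < 0):
                raise ValidationError("weights must be 3 non-negative numbers")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError("weights must sum to 1")

    @classmethod
    def from_preset(cls, name: str, k: int = 8, **kw) -> "ModkConfig":
        if name not in MODK_WEIGHT_PRESETS:
            raise ValidationError(f"unknown weighting preset {name!r}")
        w = MODK_WEIGHT_PRESETS[name]
        if w is None:
            return cls(k=k, weights=None, adaptive=True, **kw)
        return cls(k=k, weights=w, **kw)


@dataclass
class ModkResult:
    assignment: np.ndarray
    subject_ids: list[str]
    expr_prototypes: np.ndarray  # k x n_genes (z-score space)
    clin_prototypes: np.ndarray  # k x n_covariates (z-score space)
    ind_prototypes: np.ndarray  # k x n_indicators (modes, encoded)
    objective_trace: list[float]
    weight_trace: list[tuple[float, float, float]] = field(default_factory=list)
    final_weights: tuple[float, float, float] | None = None
    objective: float = np.nan


def _zscore_block(X: np.ndarray, tag: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance variable(s) in {tag} block", stacklevel=3
        )
        sd = np.where(zero, 1.0, sd)
    return (X - mu) / sd


def _encode_categorical(block) -> np.ndarray:
    """Map a subjects x indicators table of tokens to integer codes."""
    df = pd.DataFrame(block)
    return np.column_stack([pd.factorize(df[c])[0] for c in df.columns])


def _domain_costs(
    E: np.ndarray, C: np.ndarray, M: np.ndarray,
    pe: np.ndarray, pc: np.ndarray, pm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (subject, cluster) unweighted cost matrices for the 3 domains."""
    de = ((E[:, None, :] - pe[None, :, :]) ** 2).sum(axis=2)
    dc = ((C[:, None, :] - pc[None, :, :]) ** 2).sum(axis=2)
    dm = (M[:, None, :] != pm[None, :, :]).mean(axis=2)
    return de, dc, dm


def _mode_rows(M: np.ndarray, members: np.ndarray) -> np.ndarray:
    out = np.empty(M.shape[1], dtype=M.dtype)
    for j in range(M.shape[1]):
        vals, counts = np.unique(M[members, j], return_counts=True)
        out[j] = vals[int(np.argmax(counts))]
    return out


def modk_fit(
    expr_block: np.ndarray,
    clinical_block: np.ndarray,
    indicator_block,
    config: ModkConfig,
    subject_ids: list[str] | None = None,
) -> ModkResult:
    """Weighted k-prototypes over expression/clinical/indicator blocks.

    Numeric blocks are z-scored per variable, then the alternation
    minimizes ``w_e * d2_expr + w_c * d2_clin + w_i * d_match`` per
    subject.  Prototypes are cluster means (numeric) and modes
    (categorical).  Best of ``n_starts`` restarts by final objective;
    in adaptive mode weights are recomputed each iteration as
    ``w_d ~ 1/(1 + within_cost_d)``, renormalized.
    """
    E = _zscore_block(expr_block, "expression")
    C = _zscore_block(clinical_block, "clinical")
    M = _encode_categorical(indicator_block)
    n = E.shape[0]
    if C.shape[0] != n or M.shape[0] != n:
        raise ValidationError("blocks must share subjects")
    if config.k > n:
        raise ValidationError(f"k={config.k} exceeds number of subjects ({n})")
    rng = np.random.default_rng(config.rng_seed)

    best: ModkResult | None = None
    for _start in range(config.n_starts):
        init_idx = rng.choice(n, size=config.k, replace=False)
        result = _modk_single(E, C, M, config, init_idx)
        if best is None or result.objective < best.objective:
            best = result
    best.subject_ids = subject_ids or [f"s{i}" for i in range(n)]
    return best


def _modk_single(
    E: np.ndarray, C: np.ndarray, M: np.ndarray, config: ModkConfig, init_idx: np.ndarray
) -> ModkResult:
    k = config.k
    n = E.shape[0]
    pe, pc, pm = E[init_idx].copy(), C[init_idx].copy(), M[init_idx].copy()
    if config.adaptive:
        w = np.array([1 / 3, 1 / 3, 1 / 3])
    else:
        w = np.asarray(config.weights, dtype=float)
    assign = np.full(n, -1)
    trace: list[float] = []
    weight_trace: list[tuple[float, float, float]] = []

    for _it in range(config.max_iter):
        de, dc, dm = _domain_costs(E, C, M, pe, pc, pm)
        cost = w[0] * de + w[1] * dc + w[2] * dm
        new_assign = np.argmin(cost, axis=1)

        # re-seed empty clusters with the point farthest from its prototype
        for c in range(k):
            if not np.any(new_assign == c):
                taken = cost[np.arange(n), new_assign]
                far = int(np.argmax(taken))
                new_assign[far] = c
                logger.info("modk: re-seeded empty cluster %d with subject %d", c, far)

        objective = float(
            (w[0] * de + w[1] * dc + w[2] * dm)[np.arange(n), new_assign].sum()
        )
        trace.append(objective)
        converged = np.array_equal(new_assign, assign)
        assign = new_assign
        for c in range(k):
            members = np.flatnonzero(assign == c)
            pe[c] = E[members].mean(axis=0)
            pc[c] = C[members].mean(axis=0)
            pm[c] = _mode_rows(M, members)
        if config.adaptive:
            de, dc, dm = _domain_costs(E, C, M, pe, pc, pm)
            idx = np.arange(n)
            costs = np.array(
                [de[idx, assign].sum(), dc[idx, assign].sum(), dm[idx, assign].sum()]
            )
            w = 1.0 / (1.0 + costs)
            w = w / w.sum()
            weight_trace.append(tuple(float(x) for x in w))
        if converged:
            break

    return ModkResult(
        assignment=assign,
        subject_ids=[],
        expr_prototypes=pe,
        clin_prototypes=pc,
        ind_prototypes=pm,
        objective_trace=trace,
        weight_trace=weight_trace,
        final_weights=tuple(float(x) for x in w),
        objective=trace[-1],
    )


def modk_biomarkers(
    result: ModkResult,
    expr_ids: list[str],
    clinical_ids: list[str],
    expr_block: np.ndarray,
    clinical_block: np.ndarray,
    clinical_sd_threshold: float = 1.0,
    gene_alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag prototype variables deviating from the overall mean.

    Prototypes are standardized to z-scores against each variable's
    overall mean/sd; a clinical covariate is flagged for a cluster when
    |z| exceeds ``clinical_sd_threshold`` (default 1 sd) and a gene when
    |z| exceeds the two-sided normal quantile for ``gene_alpha``
    (1.96 at 0.05).  Zero-variance variables are excluded with a warning.
    """
    gene_z_cut = float(stats.norm.ppf(1 - gene_alpha / 2))
    rows = []
    for block, ids, protos, cut, domain in (
        (clinical_block, clinical_ids, result.clin_prototypes, clinical_sd_threshold, "clinical"),
        (expr_block, expr_ids, result.expr_prototypes, gene_z_cut, "expression"),
    ):
        block = np.asarray(block, dtype=float)
        zero = block.std(axis=0, ddof=0) == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance {domain} variable(s) excluded from flagging",
                stacklevel=2,
            )
        # prototypes already live in per-variable z-score space, so the
        # prototype value IS its z against the overall mean/sd
        for c in range(protos.shape[0]):
            for j, vid in enumerate(ids):
                if zero[j]:
                    continue
                z = float(protos[c, j])
                if abs(z) > cut:
                    rows.append((c, domain, vid, z))
    return pd.DataFrame(rows, columns=["cluster", "domain", "variable", "z"])


def modk_accuracy(result: ModkResult, labels: np.ndarray) -> SegregationReport:
    """Majority-vote accuracy of a Modk clustering against binary labels."""
    labels = np.asarray(labels, dtype=int)
    if labels.size != result.assignment.size:
        raise ValidationError("labels must cover all clustered subjects")
    rows = []
    n_correct = 0
    asthmatic_groups = non_groups = 0
    for c in sorted(set(result.assignment.tolist())):
        y = labels[result.assignment == c]
        n0, n1 = int((y == 0).sum()), int((y == 1).sum())
        if n1 > n0:
            majority, correct = 1, n1
            asthmatic_groups += 1
        else:
            majority, correct = 0, n0
            non_groups += 1
        n_correct += correct
        rows.append((c, LABEL_NAMES[majority], 100.0 * correct / (n0 + n1), n0 + n1))
    per_cluster = pd.DataFrame(rows, columns=["leaf_id", "majority_label", "pct_correct", "n"])
    overall = 100.0 * n_correct / labels.size
    return SegregationReport(overall, (asthmatic_groups, non_groups), per_cluster)
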