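import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from endotree.baselines import (
    ModkConfig,
    MODK_WEIGHT_PRESETS,
    c_index,
    gamma_index,
    gene_ttests,
    modk_accuracy,
    modk_biomarkers,
    modk_fit,
    silhouette_index,
    validity_scan,
)
from endotree.cohort_model import ValidationError


class TestGeneTtests:
    def test_identical_groups_t_zero(self):
        X = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        out = gene_ttests(X, ["g0"], labels)
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_pooled_t(self):
        # (1,2,3) vs (4,5,6): pooled s^2 = 1, t = -3.6742, p = 0.02131
        X = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        out = gene_ttests(X, ["g0"], labels)
        assert out["t"].iloc[0] == pytest.approx(-3.6742346141747673, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(0.021311641128756713, abs=1e-10)

    def test_hand_rolled_oracle_random_fixtures(self):
        import math

        from scipy import stats

        rng = np.random.default_rng(17)
        X = rng.standard_normal((15, 12))
        labels = np.array([0] * 6 + [1] * 6)
        out = gene_ttests(X, [f"g{i}" for i in range(15)], labels)
        for g in range(15):
            a, b = X[g, :6], X[g, 6:]
            sp2 = (sum((v - a.mean()) ** 2 for v in a) + sum((v - b.mean()) ** 2 for v in b)) / 10
            t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 6 + 1 / 6))
            p = 2 * stats.t.sf(abs(t), 10)
            assert out["t"].iloc[g] == pytest.approx(t, abs=1e-10)
            assert out["p"].iloc[g] == pytest.approx(p, abs=1e-10)

    def test_two_label_vectors_little_overlap_on_noise(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((800, 60))
        la = rng.integers(2, size=60)
        lb = rng.integers(2, size=60)
        fa = gene_ttests(X, list(map(str, range(800))), la)["significant"]
        fb = gene_ttests(X, list(map(str, range(800))), lb)["significant"]
        overlap = int((fa & fb).sum())
        # ~5% flagged per list; independent lists should share ~0.25%
        assert overlap < 0.01 * 800

    def test_degenerate_gene_warns(self):
        X = np.array([[1.0, 1.0, 1.0, 1.0]])
        with pytest.warns(UserWarning, match="zero pooled variance"):
            out = gene_ttests(X, ["g0"], np.array([0, 0, 1, 1]))
        assert out["p"].iloc[0] == 1.0


class TestSilhouette:
    def test_hand_computed_example(self):
        X = np.array([0.0, 1.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        s = silhouette_index(X, labels)
        assert s == pytest.approx(0.899749373433584, abs=1e-12)

    def test_tight_separated_clusters_near_one(self):
        X = np.r_[np.zeros(5), np.full(5, 1e6)]
        s = silhouette_index(X, np.r_[np.zeros(5), np.ones(5)])
        assert s > 0.999

    def test_all_identical_zero(self):
        X = np.zeros(6)
        s = silhouette_index(X, np.array([0, 0, 0, 1, 1, 1]))
        assert s == 0.0

    def test_one_cluster_rejected(self):
        with pytest.raises(ValidationError):
            silhouette_index(np.arange(4.0), np.zeros(4))

    def test_matches_sklearn_on_euclidean(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 3))
        labels = rng.integers(3, size=30)
        ours = silhouette_index(X, labels)
        ref = silhouette_score(X, labels, metric="euclidean")
        assert ours == pytest.approx(ref, abs=1e-10)


def gamma_brute(X, labels, distance="euclidean"):
    d = squareform(pdist(np.atleast_2d(X.T).T if X.ndim == 1 else X))
    n = len(labels)
    within, between = [], []
    for i, j in itertools.combinations(range(n), 2):
        (within if labels[i] == labels[j] else between).append(d[i, j])
    s_plus = sum(1 for w in within for b in between if w < b)
    s_minus = sum(1 for w in within for b in between if w > b)
    if s_plus + s_minus == 0:
        return 0.0
    return (s_plus - s_minus) / (s_plus + s_minus)


class TestGamma:
    def test_perfectly_separated(self):
        X = np.r_[np.zeros(3), np.full(3, 100.0)]
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert gamma_index(X, labels) == 1.0

    def test_all_equal_distances_zero(self):
        # equilateral simplex in 3-D: all pairwise distances equal
        X = np.eye(4)
        labels = np.array([0, 0, 1, 1])
        assert gamma_index(X, labels) == 0.0

    def test_brute_force_oracle_planted(self):
        X = np.array([0.0, 0.5, 0.9, 5.0, 5.2])
        labels = np.array([0, 0, 1, 1, 1])
        assert gamma_index(X, labels) == pytest.approx(gamma_brute(X[:, None], labels))

    def test_brute_force_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            X = rng.standard_normal((8, 2))
            labels = rng.integers(3, size=8)
            if len(np.unique(labels)) < 2:
                continue
            assert gamma_index(X, labels) == pytest.approx(gamma_brute(X, labels), abs=1e-12)


def c_brute(X, labels):
    d = squareform(pdist(X))
    n = len(labels)
    within = [d[i, j] for i, j in itertools.combinations(range(n), 2) if labels[i] == labels[j]]
    alldist = sorted(d[i, j] for i, j in itertools.combinations(range(n), 2))
    l = len(within)
    S = sum(within)
    s_min = sum(alldist[:l])
    s_max = sum(alldist[-l:])
    if s_max == s_min:
        return 0.0
    return (S - s_min) / (s_max - s_min)


class TestCIndex:
    def test_optimal_zero(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        assert c_index(X, labels) == pytest.approx(0.0)

    def test_pathological_one(self):
        # thin rectangle: the two diagonals are the two largest distances
        # and are exactly the within-cluster pairs
        X = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 1.0], [10.0, 1.0]])
        labels = np.array([0, 1, 1, 0])
        assert c_index(X, labels) == pytest.approx(1.0)

    def test_brute_force_random_labeling(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((6, 2))
        labels = np.array([0, 1, 0, 2, 1, 0])
        assert c_index(X, labels) == pytest.approx(c_brute(X, labels), abs=1e-12)


class TestValidityScan:
    def test_two_blobs_all_indices_select_k2(self):
        rng = np.random.default_rng(3)
        X = np.vstack([
            rng.standard_normal((30, 2)) * 0.3,
            rng.standard_normal((30, 2)) * 0.3 + 8.0,
        ])
        scan = validity_scan(
            X, "test", distances=["euclidean"], methods=["hier_complete", "kmeans"],
            k_range=range(2, 7),
        )
        assert scan.loc[scan["silhouette"].idxmax(), "k"] == 2
        assert scan.loc[scan["gamma"].idxmax(), "k"] == 2
        assert scan.loc[scan["c_index"].idxmin(), "k"] == 2
        # per-k brute check: silhouette at k=2 beats every other k
        best_row = scan.loc[scan["silhouette"].idxmax()]
        for _, row in scan.iterrows():
            assert best_row["silhouette"] >= row["silhouette"]

    def test_single_blob_low_silhouette(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((120, 3))
        scan = validity_scan(
            X, "test", distances=["euclidean"], methods=["kmeans"],
            k_range=range(2, 6),
        )
        assert (scan["silhouette"] < 0.3).all()

    def test_grid_cardinality(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 3))
        scan = validity_scan(
            X, "test", distances=["manhattan", "chebyshev"],
            methods=["hier_single", "pam"], k_range=[2, 3, 4],
        )
        assert len(scan) == 12

    def test_infeasible_combo_skipped(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 2))
        scan = validity_scan(
            X, "test", distances=["manhattan"], methods=["hier_ward", "kmeans"],
            k_range=[2, 3],
        )
        assert len(scan) == 0

    def test_index_ranges(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 2))
        scan = validity_scan(
            X, "test", distances=["euclidean", "bray_curtis", "canberra"],
            methods=["hier_complete"], k_range=[2, 4],
        )
        assert scan["silhouette"].between(-1, 1).all()
        assert scan["gamma"].between(-1, 1).all()
        assert scan["c_index"].between(0, 1).all()


def lloyd_oracle(X, k, init_idx, max_iter=100):
    """Reference k-means (Lloyd) with the same init and tie rules."""
    protos = X[init_idx].copy()
    assign = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d = ((X[:, None, :] - protos[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d, axis=1)
        for c in range(k):
            if not np.any(new_assign == c):
                taken = d[np.arange(X.shape[0]), new_assign]
                new_assign[int(np.argmax(taken))] = c
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            protos[c] = X[assign == c].mean(axis=0)
    return assign


def _blocks(rng, n=40):
    E = rng.standard_normal((n, 6))
    C = rng.standard_normal((n, 4))
    M = pd.DataFrame({
        "i1": rng.choice(["a", "b"], size=n),
        "i2": rng.choice(["x", "y", "z"], size=n),
    })
    return E, C, M


class TestModk:
    def test_expression_only_matches_lloyd_10_fixtures(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            E, C, M = _blocks(rng)
            config = ModkConfig(k=3, weights=(1.0, 0.0, 0.0), n_starts=1,
                                rng_seed=seed)
            result = modk_fit(E, C, M, config)
            # replicate the z-scoring and the single-start init draw
            Ez = (E - E.mean(axis=0)) / E.std(axis=0)
            init = np.random.default_rng(seed).choice(40, size=3, replace=False)
            expected = lloyd_oracle(Ez, 3, init)
            np.testing.assert_array_equal(result.assignment, expected)

    def test_objective_non_increasing(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            E, C, M = _blocks(rng)
            config = ModkConfig(k=3, n_starts=2, rng_seed=seed)
            result = modk_fit(E, C, M, config)
            trace = np.array(result.objective_trace)
            assert (np.diff(trace) <= 1e-9).all()

    def test_indicator_only_separates_patterns(self):
        rng = np.random.default_rng(0)
        E = rng.standard_normal((4, 2))
        C = rng.standard_normal((4, 2))
        M = pd.DataFrame({"i1": ["a", "a", "b", "b"], "i2": ["x", "x", "y", "y"]})
        config = ModkConfig(k=2, weights=(0.0, 0.0, 1.0), n_starts=10, rng_seed=0)
        result = modk_fit(E, C, M, config)
        assert result.objective == pytest.approx(0.0)
        assert result.assignment[0] == result.assignment[1]
        assert result.assignment[2] == result.assignment[3]
        assert result.assignment[0] != result.assignment[2]

    def test_k_equals_distinct_subjects_zero_objective(self):
        rng = np.random.default_rng(0)
        E = rng.standard_normal((5, 3))
        C = rng.standard_normal((5, 2))
        M = pd.DataFrame({"i": list("abcde")})
        config = ModkConfig(k=5, n_starts=5, rng_seed=1)
        result = modk_fit(E, C, M, config)
        assert result.objective == pytest.approx(0.0, abs=1e-18)

    def test_adaptive_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        E, C, M = _blocks(rng)
        config = ModkConfig(k=3, weights=None, adaptive=True, n_starts=1, rng_seed=2)
        result = modk_fit(E, C, M, config)
        assert result.final_weights is not None
        assert sum(result.final_weights) == pytest.approx(1.0)
        assert len(result.weight_trace) >= 1

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(3)
        E, C, M = _blocks(rng, n=4)
        with pytest.raises(ValidationError):
            modk_fit(E, C, M, ModkConfig(k=5))

    def test_weight_presets_table(self):
        assert len(MODK_WEIGHT_PRESETS) == 8
        for name, w in MODK_WEIGHT_PRESETS.items():
            if w is not None:
                assert sum(w) == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            ModkConfig(weights=(0.5, 0.6, 0.2))


class TestModkBiomarkers:
    def _fit(self, seed=0):
        rng = np.random.default_rng(seed)
        E = rng.standard_normal((30, 4))
        C = rng.standard_normal((30, 3))
        M = pd.DataFrame({"i": rng.choice(["a", "b"], size=30)})
        config = ModkConfig(k=2, n_starts=3, rng_seed=seed)
        return modk_fit(E, C, M, config), E, C

    def test_thresholds_differ_by_domain(self):
        result, E, C = self._fit()
        # synthetic prototypes: clinical z=1.5 flagged, gene z=1.5 not
        result.clin_prototypes = np.array([[1.5, 0.0, 0.0], [0.0, 0.0, 0.0]])
        result.expr_prototypes = np.array([[1.5, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
        flags = modk_biomarkers(result, [f"g{i}" for i in range(4)],
                                [f"c{i}" for i in range(3)], E, C)
        clinical = flags[flags["domain"] == "clinical"]
        expression = flags[flags["domain"] == "expression"]
        assert len(clinical) == 1 and clinical["z"].iloc[0] == pytest.approx(1.5)
        assert len(expression) == 0

    def test_flat_prototypes_nothing_flagged(self):
        result, E, C = self._fit(1)
        result.clin_prototypes = np.zeros_like(result.clin_prototypes)
        result.expr_prototypes = np.zeros_like(result.expr_prototypes)
        flags = modk_biomarkers(result, [f"g{i}" for i in range(4)],
                                [f"c{i}" for i in range(3)], E, C)
        assert len(flags) == 0

    def test_gene_z_above_196_flagged(self):
        result, E, C = self._fit(2)
        result.expr_prototypes = np.array([[2.5, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
        result.clin_prototypes = np.zeros_like(result.clin_prototypes)
        flags = modk_biomarkers(result, [f"g{i}" for i in range(4)],
                                [f"c{i}" for i in range(3)], E, C)
        assert set(flags["variable"]) == {"g0"}


class TestModkAccuracy:
    def test_pure_clusters(self):
        result, _, _ = TestModkBiomarkers()._fit()
        result.assignment = np.array([0] * 15 + [1] * 15)
        labels = np.array([1] * 15 + [0] * 15)
        rep = modk_accuracy(result, labels)
        assert rep.overall_accuracy == 100.0

    def test_mixed_cluster_60pct(self):
        result, _, _ = TestModkBiomarkers()._fit()
        result.assignment = np.zeros(10, dtype=int)
        labels = np.array([1] * 6 + [0] * 4)
        rep = modk_accuracy(result, labels)
        assert rep.per_leaf["pct_correct"].iloc[0] == pytest.approx(60.0)
        assert rep.group_counts == (1, 0)
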