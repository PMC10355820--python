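"""Biweight midcorrelation, adjacency, TOM, consensus, clustering, eigengenes."""

import numpy as np
import pytest

from methdrift.io import BetaMatrix
from methdrift.network import (SimilarityMatrix, adjacency, bicor_matrix,
                               cluster_modules, consensus_tom, kme,
                               module_eigengenes, tom, top_kme)


def _beta(values, prefix="cg"):
    values = np.asarray(values, dtype=float)
    return BetaMatrix([f"{prefix}{i}" for i in range(values.shape[0])],
                      [f"s{i}" for i in range(values.shape[1])], values)


def bicor_reference(x, y):
    """Straight-from-formula biweight midcorrelation of two vectors."""
    def weighted_dev(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - v.mean()
        u = (v - med) / (9 * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    a, b = weighted_dev(x), weighted_dev(y)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def tom_reference(A):
    """Triple-loop topological overlap."""
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    W = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(A[i, u] for u in range(n) if u != i)
            k_j = sum(A[j, u] for u in range(n) if u != j)
            denom = min(k_i, k_j) + 1 - A[i, j]
            W[i, j] = (l_ij + A[i, j]) / denom if denom != 0 else 0.0
    return W


class TestBicor:
    def test_affine_relation_gives_unit_correlation(self):
        x = np.array([0.12, 0.3, 0.45, 0.2, 0.33, 0.28, 0.41, 0.09, 0.38])
        m = _beta(np.vstack([x, x / 2]))  # scale by 1/2: exact in floats
        C = bicor_matrix(m).values
        assert C[0, 1] == 1.0

    def test_negation_gives_minus_one(self):
        # x >= 0.5 makes 1 - x exact (Sterbenz) and odd n keeps the median
        # an exact data point, so the mirrored CpG has exactly negated
        # weighted deviations
        x = np.array([0.52, 0.8, 0.65, 0.7, 0.58, 0.85, 0.6, 0.75, 0.9])
        m = _beta(np.vstack([x, 1.0 - x]))
        assert bicor_matrix(m).values[0, 1] == -1.0

    def test_matches_pairwise_formula_oracle(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(5, 8))
        m = _beta(vals)
        C = bicor_matrix(m).values
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else bicor_reference(vals[i], vals[j])
                assert C[i, j] == pytest.approx(expected, abs=1e-10)

    def test_outlier_downweighted_vs_pearson(self, rng):
        x = rng.uniform(0.3, 0.7, 20)
        y = x.copy()
        y[0] = 0.0  # single corrupted sample
        m = _beta(np.vstack([x, y]))
        b = bicor_matrix(m).values[0, 1]
        p = np.corrcoef(x, y)[0, 1]
        assert b > p

    def test_zero_mad_falls_back_to_pearson(self, rng):
        # heavy ties -> MAD 0; fallback must still give finite correlation
        x = np.array([0.5] * 6 + [0.6, 0.7])
        y = rng.uniform(0.2, 0.8, 8)
        m = _beta(np.vstack([x, y]))
        C = bicor_matrix(m).values
        assert np.isfinite(C).all()
        ref = np.corrcoef(x - x.mean(), y)[0, 1]  # x side is plain centered
        assert abs(C[0, 1]) <= 1

    def test_requires_four_samples(self):
        with pytest.raises(ValueError):
            bicor_matrix(_beta(np.random.default_rng(0).uniform(size=(3, 3))))


class TestAdjacency:
    def test_extremes(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(4, 10))
        corr = bicor_matrix(_beta(vals))
        corr.values[0, 1] = corr.values[1, 0] = 1.0
        corr.values[2, 3] = corr.values[3, 2] = 0.0
        a = adjacency(corr, power=6).values
        assert a[0, 1] == 1.0 and a[2, 3] == 0.0

    def test_unsigned_power_oracle(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(4, 12))
        corr = bicor_matrix(_beta(vals))
        a = adjacency(corr, power=6).values
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(a[off], np.abs(corr.values[off]) ** 6,
                                   atol=1e-12)

    def test_signed_mode(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(4, 12))
        corr = bicor_matrix(_beta(vals))
        a = adjacency(corr, power=2, mode="signed").values
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(a[off], ((1 + corr.values[off]) / 2) ** 2)

    def test_invalid_power_errors(self, rng):
        corr = bicor_matrix(_beta(rng.uniform(0.1, 0.9, size=(4, 8))))
        with pytest.raises(ValueError):
            adjacency(corr, power=0)


class TestTom:
    def _adj(self, values):
        n = values.shape[0]
        return SimilarityMatrix([f"cg{i}" for i in range(n)], values, "adjacency")

    def test_empty_graph(self):
        W = tom(self._adj(np.eye(4))).values
        assert np.array_equal(W, np.eye(4))

    def test_two_isolated_connected_nodes_closed_form(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 1.0
        W = tom(self._adj(A)).values
        assert W[0, 1] == pytest.approx(1.0)  # (0 + 1) / (1 + 1 - 1)

    def test_brute_force_oracle_random_20_nodes(self, rng):
        A = rng.uniform(0, 1, size=(20, 20))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        W = tom(self._adj(A)).values
        np.testing.assert_allclose(W, tom_reference(A), atol=1e-12)

    def test_identical_neighborhood_unit_overlap(self):
        # clique of 3 with full adjacency: identical neighborhoods, a_ij = 1
        A = np.ones((3, 3))
        W = tom(self._adj(A)).values
        np.testing.assert_allclose(W, 1.0)

    def test_output_in_unit_interval(self, rng):
        A = rng.uniform(0, 1, size=(15, 15))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        W = tom(self._adj(A)).values
        assert W.min() >= 0 and W.max() <= 1 + 1e-12

    def test_rejects_out_of_range_adjacency(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1.5
        with pytest.raises(ValueError):
            tom(self._adj(A))


class TestConsensus:
    def _tom(self, values):
        n = values.shape[0]
        return SimilarityMatrix([f"cg{i}" for i in range(n)], values, "tom")

    def _random_tom(self, rng, n=10):
        A = rng.uniform(0, 1, size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        return tom(SimilarityMatrix([f"cg{i}" for i in range(n)], A, "adjacency"))

    def test_idempotence_on_identical_inputs(self, rng):
        T = self._random_tom(rng)
        cons = consensus_tom(T, T)
        np.testing.assert_allclose(cons.values, T.values, atol=1e-12)

    def test_elementwise_min_without_scaling(self, rng):
        Ta, Tb = self._random_tom(rng), self._random_tom(rng)
        cons = consensus_tom(Ta, Tb, scale=False)
        n = len(Ta.cpg_ids)
        for i in range(n):
            for j in range(n):
                if i != j:
                    assert cons.values[i, j] == min(Ta.values[i, j], Tb.values[i, j])

    def test_consensus_below_first_input(self, rng):
        Ta, Tb = self._random_tom(rng), self._random_tom(rng)
        cons = consensus_tom(Ta, Tb)
        off = ~np.eye(len(Ta.cpg_ids), dtype=bool)
        assert np.all(cons.values[off] <= Ta.values[off] + 1e-12)

    def test_quantile_scaling_matches_target_quantile(self, rng):
        # power transform commutes with quantiles up to the interpolation
        # between order statistics, hence the loose relative tolerance
        Ta, Tb = self._random_tom(rng, 30), self._random_tom(rng, 30)
        q = 0.95
        off = ~np.eye(30, dtype=bool)
        qa = np.quantile(Ta.values[off], q)
        qb = np.quantile(Tb.values[off], q)
        scaled = Tb.values[off] ** (np.log(qa) / np.log(qb))
        assert np.quantile(scaled, q) == pytest.approx(qa, rel=0.05)

    def test_cpg_mismatch_errors(self, rng):
        Ta = self._random_tom(rng)
        Tb = self._random_tom(rng)
        Tb.cpg_ids = [f"other{i}" for i in range(len(Tb.cpg_ids))]
        with pytest.raises(ValueError):
            consensus_tom(Ta, Tb)


def _planted_tom(rng, sizes=(8, 8), n_noise=4, high=0.6, low=0.02):
    n = sum(sizes) + n_noise
    T = np.full((n, n), low)
    start = 0
    for sz in sizes:
        T[start:start + sz, start:start + sz] = high
        start += sz
    T += rng.uniform(0, 0.005, size=(n, n))
    T = (T + T.T) / 2
    np.fill_diagonal(T, 1.0)
    return SimilarityMatrix([f"cg{i}" for i in range(n)], T, "tom")


class TestClusterModules:
    def test_planted_blocks_recovered_block_pure(self, rng):
        cons = _planted_tom(rng)
        part, _ = cluster_modules(cons, cut_height=0.95, min_cluster_size=5)
        assert len(part.module_ids) == 2
        labels = part.labels
        assert len(set(labels[:8])) == 1 and labels[0] != 0
        assert len(set(labels[8:16])) == 1 and labels[8] != 0
        assert labels[0] != labels[8]
        assert all(l == 0 for l in labels[16:])

    def test_all_identical_cpgs_single_module(self):
        n = 6
        T = np.ones((n, n))
        cons = SimilarityMatrix([f"cg{i}" for i in range(n)], T, "tom")
        part, _ = cluster_modules(cons, min_cluster_size=2)
        assert part.module_ids == [1]
        assert all(l == 1 for l in part.labels)

    def test_min_cluster_size_above_n_unassigns_everything(self, rng):
        cons = _planted_tom(rng)
        part, _ = cluster_modules(cons, min_cluster_size=100)
        assert all(l == 0 for l in part.labels)

    def test_labels_ordered_by_decreasing_size(self, rng):
        cons = _planted_tom(rng, sizes=(10, 6))
        part, _ = cluster_modules(cons, min_cluster_size=3)
        sizes = part.module_sizes()
        assert sizes[1] >= sizes[2]

    def test_input_order_invariance(self, rng):
        cons = _planted_tom(rng)
        perm = rng.permutation(len(cons.cpg_ids))
        shuffled = SimilarityMatrix(
            [cons.cpg_ids[i] for i in perm],
            cons.values[np.ix_(perm, perm)], "tom")
        p1, _ = cluster_modules(cons, min_cluster_size=5)
        p2, _ = cluster_modules(shuffled, min_cluster_size=5)
        d1, d2 = p1.as_dict(), p2.as_dict()
        # same co-membership structure regardless of row order
        from itertools import combinations
        for a, b in combinations(cons.cpg_ids, 2):
            assert (d1[a] == d1[b]) == (d2[a] == d2[b])

    def test_invalid_cut_height_errors(self, rng):
        with pytest.raises(ValueError):
            cluster_modules(_planted_tom(rng), cut_height=1.5)


class TestEigengenes:
    def _module_matrix(self, rng, n_per=5, n_samples=12):
        profile = rng.uniform(0.3, 0.7, n_samples)
        rows = [np.clip(profile + rng.normal(0, 0.01, n_samples), 0, 1)
                for _ in range(n_per)]
        noise = rng.uniform(0.2, 0.8, size=(n_per, n_samples))
        vals = np.vstack(rows + [noise])
        m = _beta(vals)
        from methdrift.network import ModulePartition
        labels = np.array([1] * n_per + [2] * n_per)
        part = ModulePartition(m.cpg_ids, labels, 2)
        return m, part, profile

    def test_identical_profiles_give_that_profile(self, rng):
        n_samples = 10
        profile = np.linspace(0.2, 0.8, n_samples)
        vals = np.vstack([profile, profile, profile, profile])
        m = _beta(vals)
        from methdrift.network import ModulePartition
        part = ModulePartition(m.cpg_ids, np.array([1, 1, 1, 1]), 2)
        eig = module_eigengenes(m, part)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig.eigengene(1), z, atol=1e-8)
        assert eig.explained_variance[1] == pytest.approx(1.0)

    def test_sample_shuffle_equivariance(self, rng):
        m, part, _ = self._module_matrix(rng)
        eig = module_eigengenes(m, part)
        perm = rng.permutation(m.n_samples)
        m2 = BetaMatrix(m.cpg_ids, [m.sample_ids[i] for i in perm],
                        m.values[:, perm])
        eig2 = module_eigengenes(m2, part)
        np.testing.assert_allclose(eig2.eigengene(1), eig.eigengene(1)[perm],
                                   atol=1e-8)

    def test_unit_variance_and_positive_mean_kme(self, rng):
        m, part, _ = self._module_matrix(rng)
        eig = module_eigengenes(m, part)
        for mod in eig.module_ids:
            assert np.std(eig.eigengene(mod)) == pytest.approx(1.0)
        K = kme(m, eig)
        members = np.array(part.labels) == 1
        assert K[members, 0].mean() >= 0

    def test_planted_latent_recovery(self, study):
        """Module eigengene tracks the planted drift factor closely."""
        beta, sheet, truth = study["passaging_train"]
        from methdrift.network import ModulePartition
        part = ModulePartition(truth.cpg_ids, truth.module_labels(), 2)
        eig = module_eigengenes(beta, part)
        cpd = sheet["cpd"].to_numpy()
        for mod in truth.physio_modules:
            r = np.corrcoef(eig.eigengene(mod), cpd)[0, 1]
            assert abs(r) >= 0.95


class TestKme:
    def test_cpg_equal_to_eigengene_has_unit_kme(self, rng):
        n_samples = 10
        profile = np.linspace(0.2, 0.8, n_samples)
        vals = np.vstack([profile, profile, 1 - profile])
        m = _beta(vals)
        from methdrift.network import ModulePartition
        part = ModulePartition(m.cpg_ids, np.array([1, 1, 1]), 2)
        eig = module_eigengenes(m, part)
        K = kme(m, eig)
        assert abs(K[0, 0]) == pytest.approx(1.0)

    def test_matches_per_pair_correlation_loop(self, rng):
        m, part, _ = TestEigengenes()._module_matrix(rng)
        eig = module_eigengenes(m, part)
        K = kme(m, eig)
        for i in range(m.n_cpgs):
            for j, mod in enumerate(eig.module_ids):
                expected = np.corrcoef(m.values[i], eig.eigengene(mod))[0, 1]
                assert K[i, j] == pytest.approx(expected, abs=1e-12)

    def test_top_kme_exhaustive_returns_ranked_members(self, rng):
        m, part, _ = TestEigengenes()._module_matrix(rng)
        eig = module_eigengenes(m, part)
        members = part.members(1)
        got = top_kme(m, eig, part, 1, len(members))
        assert set(got) == set(members)
        K = kme(m, eig)
        idx = {c: i for i, c in enumerate(m.cpg_ids)}
        vals = [K[idx[c], 0] for c in got]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
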