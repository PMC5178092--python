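import numpy as np
import pytest

import bnm
from bnm.io import GeneticMap
from bnm.networks import (
    mi_to_dissimilarity,
    snf_fuse,
    weighted_mutual_information,
)


def _gmap(cm, chrom="1"):
    cm = np.asarray(cm, dtype=float)
    return GeneticMap(
        marker_id=np.array([f"m{i}" for i in range(len(cm))]),
        chromosome=chrom,
        cm=cm,
        mb=cm / 2,
    )


class TestGeneticDistance:
    def test_forced_values(self):
        d = bnm.genetic_distance_matrix(_gmap([0.0, 1.5, 3.0]))
        np.testing.assert_allclose(
            d, [[0, 1.5, 3.0], [1.5, 0, 1.5], [3.0, 1.5, 0]]
        )

    def test_coincident_markers_zero_matrix(self):
        d = bnm.genetic_distance_matrix(_gmap([2.0, 2.0, 2.0]))
        np.testing.assert_array_equal(d, np.zeros((3, 3)))

    def test_matches_brute_force(self, rng):
        cm = np.sort(rng.uniform(0, 100, size=15))
        d = bnm.genetic_distance_matrix(_gmap(cm))
        for i in range(15):
            for j in range(15):
                assert d[i, j] == abs(cm[i] - cm[j])

    def test_collinearity_along_the_map(self, rng):
        cm = np.sort(rng.uniform(0, 50, size=8))
        d = bnm.genetic_distance_matrix(_gmap(cm))
        for i in range(6):
            assert d[i, i + 2] == pytest.approx(d[i, i + 1] + d[i + 1, i + 2])


class TestWeightedMutualInformation:
    def test_identical_binary_markers_give_log2(self):
        # two identical markers, states split 50/50 between 0 and 2,
        # uniform weights: joint is diagonal with mass 1/2 + 1/2
        row = np.array([0] * 10 + [2] * 10, dtype=np.int8)
        states = np.vstack([row, row])
        rho = np.full(20, 1 / 20)
        mi = weighted_mutual_information(states, rho)
        # direct summation over the 2x2 joint table
        expected = 0.5 * np.log(0.5 / 0.25) + 0.5 * np.log(0.5 / 0.25)
        assert mi[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(np.log(2))

    def test_independent_markers_vanish_at_large_n(self, rng):
        n = 50_000
        states = rng.integers(0, 3, size=(2, n)).astype(np.int8)
        rho = np.full(n, 1 / n)
        mi = weighted_mutual_information(states, rho)
        assert mi[0, 1] < 5e-4

    def test_diagonal_is_weighted_entropy(self, rng):
        n = 60
        states = rng.integers(0, 3, size=(3, n)).astype(np.int8)
        y = rng.normal(size=n)
        rho = bnm.normalize_phenotype(y).rho
        mi = weighted_mutual_information(states, rho)
        for s in range(3):
            p = np.array([rho[states[s] == a].sum() for a in range(3)])
            entropy = -sum(pa * np.log(pa) for pa in p if pa > 0)
            assert mi[s, s] == pytest.approx(entropy, abs=1e-12)

    def test_invariant_under_subject_relabeling(self, rng):
        n = 40
        states = rng.integers(0, 3, size=(4, n)).astype(np.int8)
        rho = bnm.normalize_phenotype(rng.normal(size=n)).rho
        perm = rng.permutation(n)
        a = weighted_mutual_information(states, rho)
        b = weighted_mutual_information(states[:, perm], rho[perm])
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_entirely_missing_marker_rejected(self):
        states = np.array([[3, 3, 3, 3], [0, 1, 2, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="missing"):
            weighted_mutual_information(states, np.full(4, 0.25))


class TestPermutationMutualInformation:
    def test_uniform_weights_no_missing_equal_single_call(self, rng):
        n = 30
        states = rng.integers(0, 3, size=(5, n)).astype(np.int8)
        rho = np.full(n, 1 / n)
        single = weighted_mutual_information(states, rho)
        averaged = bnm.permutation_mutual_information(states, rho, n_perm=7, seed=1)
        np.testing.assert_allclose(averaged, single, atol=1e-12)

    def test_split_half_convergence_on_skewed_weights(self, rng):
        n = 50
        states = rng.integers(0, 3, size=(4, n)).astype(np.int8)
        rho = bnm.normalize_phenotype(rng.normal(scale=2.0, size=n)).rho
        a = bnm.permutation_mutual_information(states, rho, n_perm=150, seed=2)
        b = bnm.permutation_mutual_information(states, rho, n_perm=150, seed=3)
        assert np.max(np.abs(a - b)) < 0.02

    def test_symmetric_output(self, rng):
        n = 30
        states = rng.integers(0, 4, size=(6, n)).astype(np.int8)
        states[:, 0] = 0  # keep every marker partly observed
        rho = bnm.normalize_phenotype(rng.normal(size=n)).rho
        mi = bnm.permutation_mutual_information(states, rho, n_perm=5, seed=4)
        np.testing.assert_allclose(mi, mi.T, atol=1e-15)


def _snf_oracle(diss_views, kappa, eta, iterations):
    """Straight-line re-implementation of the fusion recurrence."""
    def affinity(diss):
        s = diss.shape[0]
        w = np.zeros((s, s))
        mu = np.empty(s)
        for i in range(s):
            mu[i] = np.mean(sorted(diss[i])[1 : kappa + 1])
        for i in range(s):
            for j in range(s):
                eps = max(eta * (mu[i] + mu[j] + diss[i, j]) / 3.0, 1e-12)
                w[i, j] = np.exp(-(diss[i, j] ** 2) / eps)
        return (w + w.T) / 2.0

    def full(w):
        s = w.shape[0]
        p = np.zeros((s, s))
        for i in range(s):
            tot = sum(w[i, j] for j in range(s) if j != i)
            for j in range(s):
                if i == j:
                    p[i, j] = 0.5
                elif tot > 0:
                    p[i, j] = w[i, j] / (2 * tot)
        return p

    def sparse(w):
        s = w.shape[0]
        p = np.zeros((s, s))
        for i in range(s):
            nbr = np.argsort(-w[i])[:kappa]
            tot = w[i, nbr].sum()
            if tot == 0:
                tot = 1.0
            p[i, nbr] = w[i, nbr] / tot
        return p

    kernels = [full(affinity(v)) for v in diss_views]
    sparses = [sparse(affinity(v)) for v in diss_views]
    for _ in range(iterations):
        new = []
        for v in range(2):
            p = sparses[v] @ kernels[1 - v] @ sparses[v].T
            p = full((p + p.T) / 2.0)
            new.append((p + p.T) / 2.0)
        kernels = new
    m = (kernels[0] + kernels[1]) / 2.0
    return (m + m.T) / 2.0


def _random_views(rng, s=5):
    cm = np.sort(rng.uniform(0, 30, size=s))
    d = np.abs(cm[:, None] - cm[None, :])
    a = rng.uniform(0, 1, size=(s, s))
    mi = (a + a.T) / 2.0
    np.fill_diagonal(mi, 1.5)
    return d, mi


class TestSnfFuse:
    def test_matches_literal_recurrence_oracle(self, rng):
        d, mi = _random_views(rng, s=5)
        fused = snf_fuse(d, mi, kappa=3, eta=0.5, iterations=4)
        oracle = _snf_oracle([d, mi_to_dissimilarity(mi)], 3, 0.5, 4)
        np.testing.assert_allclose(fused, oracle, atol=1e-10)

    def test_identical_views_reach_single_view_recurrence(self, rng):
        d, _ = _random_views(rng, s=8)
        # an MI view of max(d) - d inverts back to the distance view, so
        # both views coincide; the fused result must equal the same
        # recurrence applied to the single common view
        fused = snf_fuse(d, d.max() - d, kappa=4, eta=0.6, iterations=5)
        oracle = _snf_oracle([d, d], 4, 0.6, 5)
        np.testing.assert_allclose(fused, oracle, atol=1e-10)

    def test_symmetric_nonnegative_finite(self, rng):
        for _ in range(5):
            d, mi = _random_views(rng, s=10)
            m = snf_fuse(d, mi, kappa=4, eta=0.4, iterations=20)
            assert np.allclose(m, m.T)
            assert (m >= 0).all()
            assert np.isfinite(m).all()

    def test_zero_iterations_returns_average_of_initial_kernels(self, rng):
        d, mi = _random_views(rng, s=6)
        base = snf_fuse(d, mi, kappa=3, eta=0.5, iterations=0)
        from bnm.networks import _full_kernel, _local_affinity

        k1 = _full_kernel(_local_affinity(d, 3, 0.5))
        k2 = _full_kernel(_local_affinity(mi_to_dissimilarity(mi), 3, 0.5))
        avg = (k1 + k2) / 2.0
        np.testing.assert_allclose(base, (avg + avg.T) / 2.0, atol=1e-14)

    def test_kappa_too_large_rejected(self, rng):
        d, mi = _random_views(rng, s=5)
        with pytest.raises(ValueError, match="kappa"):
            snf_fuse(d, mi, kappa=5, eta=0.5)

    def test_asymmetric_input_rejected(self, rng):
        d, mi = _random_views(rng, s=5)
        d[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            snf_fuse(d, mi, kappa=3, eta=0.5)

    def test_far_apart_groups_stay_more_similar_within(self):
        # two tight marker groups separated by a huge cM gap
        cm = np.array([0.0, 1.0, 2.0, 100.0, 101.0, 102.0])
        d = np.abs(cm[:, None] - cm[None, :])
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 0.1, size=(6, 6))
        mi = (a + a.T) / 2
        mi[:3, :3] += 1.0
        mi[3:, 3:] += 1.0
        m = snf_fuse(d, mi, kappa=2, eta=0.5, iterations=10)
        within = np.concatenate(
            [m[:3, :3][np.triu_indices(3, 1)], m[3:, 3:][np.triu_indices(3, 1)]]
        )
        between = m[:3, 3:].ravel()
        assert within.min() > between.max()
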