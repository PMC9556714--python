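"""ICASSO stability machinery: bootstrap runs, similarity, clustering,
Iq, R-index, centrotypes, reliability screen."""

import itertools

import numpy as np
import pytest

from wmgating import icasso as ic
from wmgating.groupica import infomax, pca_compress


def planted_block_similarity(k, per_block, rng, within=0.95, between=0.05, jitter=0.02):
    n = k * per_block
    s = between + jitter * rng.random((n, n))
    for b in range(k):
        sl = slice(b * per_block, (b + 1) * per_block)
        s[sl, sl] = within + jitter * rng.random((per_block, per_block))
    s = 0.5 * (s + s.T)
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return s


@pytest.fixture(scope="module")
def small_aggregate():
    rng = np.random.default_rng(4)
    sources = rng.laplace(size=(4, 4000))
    mixed = rng.normal(size=(4, 4)) @ sources
    _, red = pca_compress(mixed, n_pc=4, var_threshold=0.0)
    return red


class TestBootstrapRuns:
    def test_single_run_without_bootstrap_reproduces_base(self, small_aggregate):
        base = infomax(small_aggregate, seed=3)
        est = ic.run_bootstrap_ica(
            small_aggregate, r_runs=1, seed=3, bootstrap=False, fixed_init=True
        )
        np.testing.assert_array_equal(est.weights[0], base)

    def test_fixed_init_runs_identical_with_unit_similarity(self, small_aggregate):
        est = ic.run_bootstrap_ica(
            small_aggregate, r_runs=3, seed=1, bootstrap=False, fixed_init=True
        )
        np.testing.assert_array_equal(est.weights[0], est.weights[1])
        s = ic.similarity_matrix(est)
        n_pc = est.n_pc
        for r in range(1, est.n_runs):
            block = s[0:n_pc, r * n_pc : (r + 1) * n_pc]
            np.testing.assert_allclose(np.diag(block), 1.0, atol=1e-9)

    def test_fixed_seed_reproducible(self, small_aggregate):
        a = ic.run_bootstrap_ica(small_aggregate, r_runs=2, seed=5)
        b = ic.run_bootstrap_ica(small_aggregate, r_runs=2, seed=5)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestSimilarity:
    def test_self_and_negation_are_fully_similar(self, rng):
        tc = rng.normal(size=(1, 500))
        courses = np.vstack([tc, -tc, tc])
        s = ic.similarity_matrix(courses)
        assert s[0, 1] == pytest.approx(1.0)
        assert s[0, 2] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(s), 1.0)

    def test_independent_noise_courses_nearly_orthogonal(self, rng):
        # null |r| is approximately half-normal with sd 1/sqrt(n)
        s = ic.similarity_matrix(rng.normal(size=(2, 10000)))
        assert s[0, 1] < 0.05

    def test_zero_variance_course_warned_and_zeroed(self, rng):
        courses = np.vstack([rng.normal(size=500), np.zeros(500)])
        with pytest.warns(UserWarning):
            s = ic.similarity_matrix(courses)
        assert s[0, 1] == 0.0 and s[1, 1] == 1.0

    def test_estimates_path_matches_explicit_time_courses(self, small_aggregate):
        est = ic.run_bootstrap_ica(small_aggregate, r_runs=2, seed=0)
        np.testing.assert_allclose(
            ic.similarity_matrix(est),
            ic.similarity_matrix(est.time_courses()),
            atol=1e-9,
        )


class TestClustering:
    def test_perfect_blocks_recovered(self, rng):
        s = planted_block_similarity(5, 4, rng, jitter=0.0)
        part = ic.cluster_estimates(s, 5)
        for b in range(5):
            ids = part[b * 4 : (b + 1) * 4]
            assert len(set(ids)) == 1

    def test_all_singletons_at_maximal_cluster_count(self, rng):
        s = planted_block_similarity(3, 2, rng)
        part = ic.cluster_estimates(s, 6)
        assert len(np.unique(part)) == 6

    def test_partition_invariant_to_estimate_order(self, rng):
        s = planted_block_similarity(4, 3, rng)
        part = ic.cluster_estimates(s, 4)
        perm = rng.permutation(12)
        part_perm = ic.cluster_estimates(s[np.ix_(perm, perm)], 4)
        # same co-membership structure up to relabeling
        for i in range(12):
            for j in range(12):
                same = part[perm[i]] == part[perm[j]]
                assert same == (part_perm[i] == part_perm[j])


class TestIq:
    def test_perfect_block_scores_one(self):
        s = np.eye(6)
        s[:3, :3] = 1.0
        part = np.array([0, 0, 0, 1, 2, 3])
        q = ic.iq(part, s)
        assert q[0] == pytest.approx(1.0)

    def test_equal_within_and_between_scores_zero(self):
        s = np.full((4, 4), 0.5)
        np.fill_diagonal(s, 1.0)
        q = ic.iq(np.array([0, 0, 1, 1]), s)
        np.testing.assert_allclose(q, 0.0, atol=1e-12)

    def test_matches_bruteforce_double_sum(self, rng):
        s = planted_block_similarity(2, 4, rng)
        part = np.array([0] * 4 + [1] * 4)
        q = ic.iq(part, s)
        for c in (0, 1):
            members = np.flatnonzero(part == c)
            others = np.flatnonzero(part != c)
            intra = np.mean(
                [s[i, j] for i, j in itertools.combinations(members, 2)]
            )
            inter = np.mean([s[i, j] for i in members for j in others])
            assert q[c] == pytest.approx(intra - inter, rel=1e-12)

    def test_invariant_to_sign_flips_of_estimates(self, rng):
        # similarity uses |r|, so flipping a course's sign changes nothing
        courses = rng.normal(size=(6, 300))
        part = np.array([0, 0, 1, 1, 2, 2])
        q1 = ic.iq(part, ic.similarity_matrix(courses))
        flipped = courses * np.array([1, -1, 1, -1, 1, -1])[:, None]
        q2 = ic.iq(part, ic.similarity_matrix(flipped))
        np.testing.assert_allclose(q1, q2, atol=1e-12)


class TestRIndex:
    def test_recovers_planted_block_count(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(3, 7))
            s = planted_block_similarity(k, 5, rng)
            _, best = ic.r_index(s, range(2, 10))
            hits += best == k
        assert hits >= 18  # >= 90% of seeds

    def test_matches_bruteforce_formula(self, rng):
        s = planted_block_similarity(3, 3, rng)
        curve, _ = ic.r_index(s, [3])
        part = ic.cluster_estimates(s, 3)
        d = 1.0 - s
        terms = []
        for c in np.unique(part):
            members = np.flatnonzero(part == c)
            pairs = list(itertools.combinations(members, 2))
            within = np.mean([d[i, j] for i, j in pairs]) if pairs else 0.0
            between = min(
                np.mean([d[i, j] for i in members for j in np.flatnonzero(part == m)])
                for m in np.unique(part)
                if m != c
            )
            terms.append(within / between)
        assert curve[3] == pytest.approx(np.mean(terms), rel=1e-12)

    def test_identical_estimates_guarded_as_infinite(self):
        s = np.ones((6, 6))
        with pytest.warns(UserWarning):
            curve, _ = ic.r_index(s, [2, 3])
        assert np.isinf(curve[2]) and np.isinf(curve[3])

    def test_out_of_range_cluster_count_rejected(self, rng):
        s = planted_block_similarity(2, 3, rng)
        with pytest.raises(ValueError):
            ic.r_index(s, [1])


class TestCentrotype:
    def test_singleton_is_its_own_representative(self):
        s = np.eye(3)
        part = np.array([0, 1, 2])
        np.testing.assert_array_equal(ic.centrotype(part, s), [0, 1, 2])

    def test_forced_by_similarity_sums(self):
        s = np.eye(3)
        s[0, 1] = s[1, 0] = 0.9
        s[0, 2] = s[2, 0] = 0.9
        s[1, 2] = s[2, 1] = 0.5
        assert ic.centrotype(np.zeros(3, dtype=int), s)[0] == 0

    def test_matches_bruteforce_argmax(self, rng):
        s = planted_block_similarity(2, 5, rng)
        part = np.array([0] * 5 + [1] * 5)
        cents = ic.centrotype(part, s)
        for c in (0, 1):
            members = np.flatnonzero(part == c)
            sums = [s[i, members].sum() for i in members]
            assert cents[c] == members[int(np.argmax(sums))]


class TestReliabilityScreen:
    def test_screen_excludes_only_the_unstable_cluster(self):
        # one unstable cluster at 0.65, the rest at or above 0.88
        iq_values = np.array([0.65, 0.88, 0.92])
        keep = ic.select_reliable(iq_values, threshold=0.85)
        np.testing.assert_array_equal(keep, [1, 2])

    def test_all_perfect_retained(self):
        np.testing.assert_array_equal(
            ic.select_reliable(np.ones(5)), np.arange(5)
        )

    def test_unreachable_threshold_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            keep = ic.select_reliable(np.array([0.9, 0.95]), threshold=1.01)
        assert keep.size == 0


def test_component_iq_attached_to_base_components(small_aggregate):
    base = infomax(small_aggregate, seed=0)
    res = ic.run_icasso(
        small_aggregate, base_w=base, r_runs=8, n_clusters=4, seed=0
    )
    assert res.component_iq.shape == (4,)
    # clean separable sources: the base components sit in tight clusters
    assert (res.component_iq > 0.85).all()
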