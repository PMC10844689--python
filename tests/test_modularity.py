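"""Covariance ratio, modularity null, two-block PLS, integration null."""

import itertools
import math

import numpy as np
import pytest

import morphokit as mk
from morphokit.modularity import _first_singular_pair, cr_from_covariance
from tests.conftest import make_aligned


IDX1 = np.arange(6)
IDX2 = np.arange(6, 12)


def compound_symmetric(p, c, var=1.0):
    s = np.full((p, p), c * var)
    np.fill_diagonal(s, var)
    return s


class TestCovarianceRatio:
    def test_block_diagonal_population_matrix_gives_zero(self):
        s = np.zeros((12, 12))
        s[:6, :6] = compound_symmetric(6, 0.5)
        s[6:, 6:] = compound_symmetric(6, 0.5)
        assert cr_from_covariance(s, IDX1, IDX2) == 0.0

    def test_compound_symmetry_closed_form(self):
        """Equal covariance c everywhere, 6|6 coordinates: CR = sqrt(6/5),
        i.e. sqrt(p1 p2 / sqrt(p1 (p1-1) p2 (p2-1)))."""
        s = compound_symmetric(12, 0.37)
        assert cr_from_covariance(s, IDX1, IDX2) == pytest.approx(
            math.sqrt(6 / 5), abs=1e-12
        )

    def test_matches_elementwise_summation_oracle(self, aligned_study):
        aligned, _ = aligned_study
        s = np.cov(aligned.flatten(), rowvar=False)
        i1, i2 = mk.HEAD_BODY.coordinate_columns(aligned.landmark_labels)
        num = sum(s[i, j] ** 2 for i in i1 for j in i2)
        d1 = sum(s[i, j] ** 2 for i in i1 for j in i1 if i != j)
        d2 = sum(s[i, j] ** 2 for i in i2 for j in i2 if i != j)
        oracle = math.sqrt(num / math.sqrt(d1 * d2))
        assert mk.covariance_ratio(aligned, mk.HEAD_BODY) == pytest.approx(oracle, abs=1e-12)

    def test_block_label_swap_invariance(self, aligned_study):
        aligned, _ = aligned_study
        swapped = mk.ModulePartition(
            (mk.HEAD_BODY.blocks[1], mk.HEAD_BODY.blocks[0])
        )
        assert mk.covariance_ratio(aligned, swapped) == pytest.approx(
            mk.covariance_ratio(aligned, mk.HEAD_BODY), abs=1e-12
        )

    def test_zero_within_covariance_is_an_error(self):
        rng = np.random.default_rng(0)
        coords = np.tile(mk.BASE_SHAPE.coords, (10, 1, 1))
        coords[:, 0, 0] = rng.normal(size=10)  # single varying coordinate
        ds = make_aligned(coords)
        with pytest.raises(mk.MorphokitError, match="within-block"):
            mk.covariance_ratio(ds, mk.HEAD_BODY)

    def test_partition_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            mk.ModulePartition((("eye", "neck"), ("neck", "rostrum")))
        with pytest.raises(ValueError, match="two landmarks"):
            mk.ModulePartition((("eye",), ("neck", "rostrum")))


class TestModularityTest:
    def test_exhaustive_null_matches_manual_enumeration(self, aligned_study):
        """3|3 split of 6 landmarks has exactly C(6,3) = 20 assignments;
        the test's null and p equal a from-scratch enumeration."""
        aligned, _ = aligned_study
        with pytest.warns(RuntimeWarning, match="exhaustive"):
            res = mk.modularity_test(aligned, mk.HEAD_BODY, n_permutations=999, seed=0)
        assert res.exhaustive and len(res.null_distribution) == 20

        s = np.cov(aligned.flatten(), rowvar=False)
        labels = mk.HEAD_BODY.blocks[0] + mk.HEAD_BODY.blocks[1]
        null = []
        for combo in itertools.combinations(labels, 3):
            rest = tuple(l for l in labels if l not in combo)
            i1 = np.array([j for l in combo for j in
                           (2 * aligned.landmark_labels.index(l), 2 * aligned.landmark_labels.index(l) + 1)])
            i2 = np.array([j for l in rest for j in
                           (2 * aligned.landmark_labels.index(l), 2 * aligned.landmark_labels.index(l) + 1)])
            null.append(cr_from_covariance(s, i1, i2))
        np.testing.assert_allclose(np.sort(res.null_distribution), np.sort(null), atol=1e-12)
        p_oracle = np.mean(np.asarray(null) <= res.cr_observed + 1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_six_landmark_null_granularity(self, aligned_study):
        """The complement split always reproduces the observed CR, so with
        six landmarks the attainable p floor is 2/20."""
        aligned, _ = aligned_study
        with pytest.warns(RuntimeWarning):
            res = mk.modularity_test(aligned, mk.HEAD_BODY)
        assert res.p >= 2 / 20 - 1e-12

    def test_detects_modularity_with_resolving_landmark_count(self):
        """12 landmarks (6|6): strong within-module, zero between-module
        correlation is declared modular."""
        ds = _twelve_landmark_dataset(n=150, rho_w=0.7, rho_b=0.0, seed=1)
        part = _twelve_partition()
        res = mk.modularity_test(ds, part, n_permutations=999, seed=2)
        assert res.cr_observed < 0.4
        assert res.p <= 0.05
        assert res.effect_size < 0

    def test_specimen_reordering_invariance(self, aligned_study):
        aligned, _ = aligned_study
        rng = np.random.default_rng(3)
        perm = rng.permutation(aligned.n)
        shuffled = make_aligned(aligned.coords[perm])
        assert mk.covariance_ratio(shuffled, mk.HEAD_BODY) == pytest.approx(
            mk.covariance_ratio(make_aligned(aligned.coords), mk.HEAD_BODY), abs=1e-12
        )


class TestPLS:
    def test_deterministic_block_dependence(self):
        """Block B a noise-free linear image of block A: a similarity
        transform (rotation x scale + offset) gives r-PLS exactly 1; a
        general linear map still gives near-perfect integration."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 6))
        part = mk.ModulePartition(
            (("eye", "neck", "mid-dorsal"), ("spine-base", "mid-ventral", "rostrum"))
        )

        def dataset(m):
            coords = np.empty((40, 6, 2))
            coords[:, :3, :] = x.reshape(40, 3, 2)
            coords[:, 3:, :] = (x @ m + 1.0).reshape(40, 3, 2)
            return make_aligned(coords)

        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        assert mk.pls_two_block(dataset(2.0 * q), part).r_pls == pytest.approx(1.0, abs=1e-9)
        assert mk.pls_two_block(dataset(rng.normal(size=(6, 6))), part).r_pls > 0.9

    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(5)
        ds = make_aligned(rng.normal(size=(10_000, 6, 2)))
        part = mk.ModulePartition((("eye", "neck", "mid-dorsal"), ("spine-base", "mid-ventral", "rostrum")))
        assert mk.pls_two_block(ds, part).r_pls < 0.05

    def test_first_singular_pair_of_diagonal_cross_covariance(self):
        u1, v1, s1 = _first_singular_pair(np.array([[0.3, 0.0], [0.0, 0.1]]))
        np.testing.assert_allclose(u1, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(v1, [1.0, 0.0], atol=1e-12)
        assert s1 == pytest.approx(0.3)

    def test_unit_loadings_and_score_shapes(self, aligned_study):
        aligned, _ = aligned_study
        res = mk.pls_two_block(aligned, mk.DORSAL_VENTRAL)
        u1, v1 = res.singular_vectors
        assert np.linalg.norm(u1) == pytest.approx(1.0)
        assert np.linalg.norm(v1) == pytest.approx(1.0)
        assert u1[np.argmax(np.abs(u1))] > 0  # reproducible sign
        assert res.scores.shape == (aligned.n, 2)
        assert 0.0 <= res.r_pls <= 1.0

    def test_within_block_rotation_invariance(self, aligned_study):
        """r-PLS only sees the cross-block covariance structure: an
        orthogonal rotation of one block's coordinates leaves it fixed."""
        aligned, _ = aligned_study
        i1, i2 = mk.HEAD_BODY.coordinate_columns(aligned.landmark_labels)
        y = aligned.flatten().copy()
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        y[:, i1] = y[:, i1] @ q
        rotated = make_aligned(y.reshape(aligned.n, 6, 2))
        base = make_aligned(aligned.coords)
        assert mk.pls_two_block(rotated, mk.HEAD_BODY).r_pls == pytest.approx(
            mk.pls_two_block(base, mk.HEAD_BODY).r_pls, abs=1e-9
        )

    def test_block_order_invariance(self, aligned_study):
        aligned, _ = aligned_study
        swapped = mk.ModulePartition((mk.HEAD_BODY.blocks[1], mk.HEAD_BODY.blocks[0]))
        assert mk.pls_two_block(aligned, swapped).r_pls == pytest.approx(
            mk.pls_two_block(aligned, mk.HEAD_BODY).r_pls, abs=1e-12
        )


class TestIntegrationTest:
    def test_exhaustive_small_n_matches_manual_enumeration(self):
        rng = np.random.default_rng(7)
        ds = make_aligned(mk.BASE_SHAPE.coords + rng.normal(0, 0.05, (6, 6, 2)))
        res = mk.integration_test(ds, mk.HEAD_BODY, n_permutations=999)
        assert res.exhaustive and len(res.null_distribution) == math.factorial(6)

        i1, i2 = mk.HEAD_BODY.coordinate_columns(ds.landmark_labels)
        y = ds.flatten()
        x1 = y[:, i1] - y[:, i1].mean(0)
        x2 = y[:, i2] - y[:, i2].mean(0)
        null = []
        for p in itertools.permutations(range(6)):
            x2p = x2[list(p)]
            u, sv, vt = np.linalg.svd(x1.T @ x2p / 5)
            null.append(abs(np.corrcoef(x1 @ u[:, 0], x2p @ vt[0])[0, 1]))
        np.testing.assert_allclose(np.sort(res.null_distribution), np.sort(null), atol=1e-10)
        assert res.p == pytest.approx(np.mean(np.asarray(null) >= res.r_pls - 1e-12), abs=1e-12)

    def test_detects_integration(self, aligned_study):
        aligned, _ = aligned_study
        res = mk.integration_test(aligned, mk.HEAD_BODY, n_permutations=499, seed=8)
        # default generator covariance couples the modules (rho_b > 0)
        assert res.p <= 0.01

    def test_seed_reproducibility(self, aligned_study):
        aligned, _ = aligned_study
        r1 = mk.integration_test(aligned, mk.DORSAL_VENTRAL, n_permutations=99, seed=9)
        r2 = mk.integration_test(aligned, mk.DORSAL_VENTRAL, n_permutations=99, seed=9)
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)
        assert r1.p == r2.p


def test_population_r_pls_perfect_and_null():
    s = np.eye(12)
    assert mk.population_r_pls(s, IDX1, IDX2) == 0.0
    # one shared latent factor loading the first coordinate of each block
    s = np.eye(12) * 0.01
    s[0, 0] = s[6, 6] = 1.0
    s[0, 6] = s[6, 0] = 0.95
    assert mk.population_r_pls(s, IDX1, IDX2) == pytest.approx(0.95, abs=1e-6)


def _twelve_landmark_dataset(n, rho_w, rho_b, seed, sigma=0.02):
    rng = np.random.default_rng(seed)
    base = np.random.default_rng(99).normal(size=(12, 2))
    member = np.repeat([0, 1], 12)
    corr = np.where(member[:, None] == member[None, :], rho_w, rho_b)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(sigma**2 * corr + 1e-12 * np.eye(24))
    y = base.reshape(-1) + (chol @ rng.standard_normal((24, n))).T
    labels = tuple(f"lm{i + 1}" for i in range(12))
    return make_aligned(y.reshape(n, 12, 2), landmark_labels=labels)


def _twelve_partition():
    labels = tuple(f"lm{i + 1}" for i in range(12))
    return mk.ModulePartition((labels[:6], labels[6:]))
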