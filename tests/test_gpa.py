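"""Centroid size, OPA, GPA invariances, and repeatability."""

import math

import numpy as np
import pandas as pd
import pytest

import morphokit as mk
from morphokit.core import DegenerateConfigurationError, FactorTable, ShapeDataset
from morphokit.gpa import _center_scale


def rigid(coords, theta=0.0, shift=(0.0, 0.0), scale=1.0):
    c, s = math.cos(theta), math.sin(theta)
    return scale * coords @ np.array([[c, s], [-s, c]]) + np.asarray(shift)


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert mk.centroid_size(sq) == pytest.approx(math.sqrt(2), abs=1e-12)
        assert mk.squared_centroid_size(sq) == pytest.approx(2.0, abs=1e-12)

    def test_homogeneous_in_scale(self, triangle):
        for c in (0.2, 3.7):
            assert mk.centroid_size(c * triangle) == pytest.approx(
                c * mk.centroid_size(triangle), rel=1e-12
            )

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 2))
        mean = x.mean(axis=0)
        brute = math.sqrt(sum((xi - mean) @ (xi - mean) for xi in x))
        assert mk.centroid_size(x) == pytest.approx(brute, abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            mk.centroid_size(np.ones((4, 2)))

    def test_variants(self, triangle):
        cs = mk.centroid_size(triangle)
        assert mk.size_measure(triangle, "cs-squared") == pytest.approx(cs**2)
        assert mk.size_measure(triangle, "log-cs") == pytest.approx(math.log(cs))


class TestOPA:
    def test_similarity_transform_is_invisible(self, triangle):
        target = rigid(triangle, theta=math.radians(37), shift=(5, -3), scale=2.4)
        _, d = mk.opa_align(target, triangle)
        assert d < 1e-10

    def test_reflection_branch(self, triangle):
        mirrored = triangle * np.array([-1.0, 1.0])
        assert mk.opa_align(mirrored, triangle, allow_reflection=False)[1] > 0.1
        assert mk.opa_align(mirrored, triangle, allow_reflection=True)[1] < 1e-10

    def test_aligned_postconditions(self, triangle):
        rng = np.random.default_rng(1)
        target = rigid(rng.normal(size=(6, 2)), theta=1.0, shift=(2, 2), scale=0.5)
        aligned, _ = mk.opa_align(target, rng.normal(size=(6, 2)))
        assert np.abs(aligned.mean(axis=0)).max() < 1e-12
        assert mk.centroid_size(aligned) == pytest.approx(1.0, abs=1e-12)

    def test_distance_matches_rotation_grid_search(self):
        """OPA's SVD rotation matches a brute-force search over angles."""
        rng = np.random.default_rng(2)
        for _ in range(3):
            a = _center_scale(rng.normal(size=(6, 2)))
            b = _center_scale(rng.normal(size=(6, 2)))
            _, d = mk.opa_align(a, b)
            thetas = np.radians(np.arange(0.0, 360.0, 0.001))
            cos, sin = np.cos(thetas), np.sin(thetas)
            rots = np.stack([np.stack([cos, sin], -1), np.stack([-sin, cos], -1)], -2)
            dists = np.linalg.norm(a @ rots - b, axis=(1, 2))
            assert d == pytest.approx(dists.min(), abs=1e-6)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b, c = (rng.normal(size=(6, 2)) for _ in range(3))
            dab = mk.procrustes_distance(a, b)
            dba = mk.procrustes_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-9)
            assert dab <= mk.procrustes_distance(a, c) + mk.procrustes_distance(c, b) + 1e-9


class TestGPA:
    def test_nuisance_invariance_single_shape(self, triangle):
        rng = np.random.default_rng(4)
        coords = np.stack(
            [
                rigid(
                    triangle,
                    theta=rng.uniform(0, 2 * math.pi),
                    shift=rng.uniform(-5, 5, 2),
                    scale=rng.uniform(0.5, 2.0),
                )
                for _ in range(20)
            ]
        )
        ds = ShapeDataset(coords, tuple(f"s{i}" for i in range(20)))
        res = mk.gpa(ds)
        flat = res.aligned.flatten()
        dmax = np.abs(flat[None] - flat[:, None]).max()
        assert dmax < 1e-8
        assert mk.procrustes_distance(res.consensus.coords, triangle) < 1e-8

    def test_consensus_properties(self, aligned_study):
        aligned, _ = aligned_study
        res = mk.gpa(
            ShapeDataset(aligned.coords, aligned.specimen_ids, aligned.landmark_labels)
        )
        cons = res.consensus.coords
        assert np.abs(cons.mean(axis=0)).max() < 1e-9
        assert mk.centroid_size(cons) == pytest.approx(1.0, abs=1e-9)
        # aligned sample mean equals the consensus at convergence
        np.testing.assert_allclose(
            res.aligned.coords.mean(axis=0), cons, atol=1e-6
        )

    def test_two_shape_symmetry(self, triangle):
        other = np.array([[0.0, 0.0], [2.0, 0.5], [0.5, 2.0]])
        r1 = mk.gpa(ShapeDataset(np.stack([triangle, other]), ("a", "b")))
        r2 = mk.gpa(ShapeDataset(np.stack([other, triangle]), ("b", "a")))
        assert (
            mk.procrustes_distance(r1.consensus.coords, r2.consensus.coords) < 1e-10
        )
        # consensus is the OPA-aligned average of the two unit shapes
        a = _center_scale(triangle)
        b, _ = mk.opa_align(other, a)
        avg = _center_scale((a + b) / 2)
        assert mk.procrustes_distance(r1.consensus.coords, avg) < 1e-8

    def test_permutation_invariance(self, small_study):
        data, _ = small_study
        res = mk.gpa(data)
        rng = np.random.default_rng(5)
        perm = rng.permutation(data.n)
        shuffled = ShapeDataset(
            data.coords[perm],
            tuple(np.array(data.specimen_ids)[perm]),
            data.landmark_labels,
        )
        res2 = mk.gpa(shuffled)
        lookup = dict(zip(res2.aligned.specimen_ids, res2.aligned.coords))
        for sid, xy in zip(res.aligned.specimen_ids, res.aligned.coords):
            np.testing.assert_allclose(xy, lookup[sid], atol=1e-8)

    def test_per_specimen_nuisance_invariance(self, small_study):
        data, _ = small_study
        rng = np.random.default_rng(6)
        bent = data.coords.copy()
        for i in range(data.n):
            bent[i] = rigid(
                bent[i],
                theta=rng.uniform(0, 2 * math.pi),
                shift=rng.uniform(-3, 3, 2),
                scale=rng.uniform(0.5, 2.0),
            )
        res0 = mk.gpa(data)
        res1 = mk.gpa(ShapeDataset(bent, data.specimen_ids, data.landmark_labels))
        np.testing.assert_allclose(res0.aligned.coords, res1.aligned.coords, atol=1e-8)

    def test_centroid_sizes_are_preserved_from_raw(self, small_study):
        data, _ = small_study
        res = mk.gpa(data)
        expect = [mk.centroid_size(data.coords[i]) for i in range(data.n)]
        np.testing.assert_allclose(res.centroid_sizes, expect, rtol=1e-12)

    def test_nonconvergence_warns_not_raises(self, small_study):
        data, _ = small_study
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = mk.gpa(data, max_iter=1, tolerance=1e-30)
        assert res.converged is False


class TestRepeatability:
    @staticmethod
    def _sessions(rng, n, among_sd, within_sd, m=2):
        base = mk.BASE_SHAPE.coords
        coords, rows, ids = [], [], []
        for i in range(n):
            indiv = base + rng.normal(0, among_sd, (6, 2))
            for s in range(1, m + 1):
                coords.append(indiv + rng.normal(0, within_sd, (6, 2)))
                sid = f"i{i}-s{s}"
                ids.append(sid)
                rows.append({"specimen": sid, "individual": f"i{i}", "session": s})
        ds = ShapeDataset(
            np.stack(coords), tuple(ids), factors=FactorTable(pd.DataFrame(rows))
        )
        return mk.gpa(ds).aligned

    def test_identical_sessions_give_one(self):
        rng = np.random.default_rng(7)
        aligned = self._sessions(rng, 40, among_sd=0.02, within_sd=0.0)
        assert mk.repeatability(aligned).repeatability == pytest.approx(1.0, abs=1e-9)

    def test_independent_sessions_give_zero(self):
        # "sessions" share nothing: within-noise dominates a tiny among signal
        rng = np.random.default_rng(8)
        aligned = self._sessions(rng, 200, among_sd=1e-7, within_sd=0.02)
        assert abs(mk.repeatability(aligned).repeatability) < 0.05

    def test_variance_component_recovery(self):
        # among-individual variance 9 s^2, session error s^2, m = 2 -> R = 0.9
        rng = np.random.default_rng(9)
        aligned = self._sessions(rng, 500, among_sd=0.03, within_sd=0.01)
        assert mk.repeatability(aligned).repeatability == pytest.approx(0.9, abs=0.02)

    def test_single_session_rejected(self):
        rng = np.random.default_rng(10)
        aligned = self._sessions(rng, 10, 0.02, 0.01)
        keep = [i for i, s in enumerate(aligned.specimen_ids) if s != "i0-s2"]
        broken = ShapeDataset(
            aligned.coords[keep],
            tuple(np.array(aligned.specimen_ids)[keep]),
            aligned.landmark_labels,
            factors=aligned.factors,
            aligned=True,
        )
        with pytest.raises(ValueError, match="single session"):
            mk.repeatability(broken)
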