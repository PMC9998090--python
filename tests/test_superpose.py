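import math
from functools import lru_cache

import numpy as np
import pytest

from tmic7.structure_io import ChainStructure, ResidueRecord
from tmic7.superpose import (GAP_OPEN, AlignmentPath, d0_for_length, dp_align,
                             kabsch, tm_align, tm_score)
from tmic7.synthetic_data import BundleSpec, make_bundle, perturb


def _chain(xyz, ident="c"):
    rr = [ResidueRecord("A", i + 1, "A", tuple(p)) for i, p in enumerate(xyz)]
    return ChainStructure(ident, rr)


def _rigid(xyz, seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    return xyz @ R.T + rng.normal(0, 10, 3)


class TestKabsch:
    def test_identity(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch(X, X)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform(self):
        X = np.random.default_rng(1).normal(size=(8, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        B = X @ Rz.T + np.array([1.0, 2.0, 3.0])
        sup = kabsch(X, B)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation @ Rz, np.eye(3), atol=1e-9)

    def test_proper_rotation_even_for_reflected_input(self):
        X = np.random.default_rng(2).normal(size=(6, 3))
        B = X * np.array([1.0, 1.0, -1.0])  # reflection
        sup = kabsch(X, B)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_errors(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError):
            kabsch(X, np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_beats_random_rotations(self):
        """Kabsch rmsd must not exceed the best of many random rotations."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            sup = kabsch(A, B)
            Ac = A - A.mean(axis=0)
            Bc = B - B.mean(axis=0)
            best = np.inf
            for _ in range(2000):
                q = rng.normal(size=4)
                q /= np.linalg.norm(q)
                w, x, y, z = q
                R = np.array([
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
                r = np.sqrt(((Bc @ R.T - Ac) ** 2).sum() / len(A))
                best = min(best, r)
            assert sup.rmsd <= best + 1e-9


class TestTMScore:
    def test_d0_formula(self):
        assert d0_for_length(120) == pytest.approx(1.24 * 105 ** (1 / 3) - 1.8)
        assert d0_for_length(21) == 0.5
        assert d0_for_length(10) == 0.5

    def test_self_alignment_is_one(self, bundle):
        chain, _ = bundle
        path = AlignmentPath([(i, i) for i in range(len(chain))])
        assert tm_score(path, chain, chain, "A") == pytest.approx(1.0)

    def test_rigid_invariance(self, bundle):
        chain, _ = bundle
        moved = chain.with_coords(_rigid(chain.coords, 7))
        path = AlignmentPath([(i, i) for i in range(len(chain))])
        assert tm_score(path, chain, moved, "A") == pytest.approx(1.0, abs=1e-6)

    def test_empty_path_errors(self, bundle):
        chain, _ = bundle
        with pytest.raises(ValueError):
            tm_score(AlignmentPath([]), chain, chain)


def _dp_oracle(S, gap_open):
    """Exhaustive memoized recursion over monotone paths; each maximal gap
    run costs gap_open once.  Independent of the production DP."""
    n, m = S.shape

    @lru_cache(maxsize=None)
    def f(i, j, prev):
        if i == n and j == m:
            return 0.0
        best = -math.inf
        if i < n and j < m:
            best = max(best, S[i, j] + f(i + 1, j + 1, 0))
        if i < n:
            best = max(best, (gap_open if prev != 1 else 0.0) + f(i + 1, j, 1))
        if j < m:
            best = max(best, (gap_open if prev != 2 else 0.0) + f(i, j + 1, 2))
        return best

    return f(0, 0, 0)


class TestDP:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 12, size=2)
        S = rng.uniform(0, 1, size=(n, m))
        path, score = dp_align(S, GAP_OPEN)
        assert score == pytest.approx(_dp_oracle(S, GAP_OPEN), abs=1e-9)

    def test_path_is_strictly_monotone(self):
        S = np.random.default_rng(9).uniform(0, 1, (20, 15))
        path, _ = dp_align(S, GAP_OPEN)
        a, b = path.a_indices, path.b_indices
        assert (np.diff(a) > 0).all() and (np.diff(b) > 0).all()


class TestTMAlign:
    def test_self_alignment(self, bundle):
        chain, _ = bundle
        res = tm_align(chain, chain)
        assert res.tm_score_by_A == pytest.approx(1.0, abs=1e-6)
        assert res.tm_score_by_B == pytest.approx(1.0, abs=1e-6)
        assert res.aligned_identity_pct == pytest.approx(100.0)
        assert res.aligned_length == len(chain)

    def test_short_chain_errors(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            tm_align(_chain(X), _chain(X))

    def test_heuristic_symmetry(self, bundle):
        chain, _ = bundle
        other = perturb(chain, 2.0, seed=5)
        ab = tm_align(chain, other)
        ba = tm_align(other, chain)
        assert ab.tm_score_by_A == pytest.approx(ba.tm_score_by_B, abs=0.02)

    def test_rigid_invariance_of_score(self, bundle):
        chain, _ = bundle
        other = perturb(chain, 3.0, seed=8)
        moved = other.with_coords(_rigid(other.coords, 11))
        t1 = tm_align(chain, other).tm_score_by_A
        t2 = tm_align(chain, moved).tm_score_by_A
        assert t1 == pytest.approx(t2, abs=0.02)

    def test_perturbation_ordering_single_pair(self):
        chain, _ = make_bundle(BundleSpec(seed=3))
        t_small = tm_align(chain, perturb(chain, 1.0, 4)).tm_score_by_A
        t_big = tm_align(chain, perturb(chain, 5.0, 4)).tm_score_by_A
        assert t_small > t_big
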