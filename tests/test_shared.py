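"""Shared-synergy counting, the relative-share formula and cross-task refits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgsyn.factorization import SynergyDecomposition, nmf, tvaf
from emgsyn.shared import (all_task_shared, count_shared,
                           cross_task_reconstruction, pct_shared, shared_ind,
                           shared_oa)
from emgsyn.similarity import critical_r, pearson_r


def _decomp(W, C=None, task=None):
    k = W.shape[1]
    C = C if C is not None else np.ones((k, 10))
    return SynergyDecomposition(W=W, C=C, k=k, tvaf=99.0, restarts=1,
                                best_restart_seed=0, converged=True,
                                iterations_used=1, task_id=task)


def _orthogonal_contrast_matrix(m, k, rng):
    """Columns built on disjoint muscle groups: pairwise r is negative or
    near zero, never above threshold."""
    W = np.full((m, k), 0.01)
    for j in range(k):
        W[j * (m // k):(j + 1) * (m // k), j] = 1.0
    return W


class TestCountShared:
    def test_identical_matrices_share_everything(self, rng):
        W = rng.random((16, 4))
        n, pairs = count_shared(W, W)
        assert n == 4
        assert all(i == j for i, j, _ in pairs)

    def test_misaligned_support_matrices_share_nothing(self, rng):
        # half-block shift: every column pair overlaps on at most 2 of 4
        # dominant muscles, r ~ 0.33, below the 0.623 threshold
        W1 = _orthogonal_contrast_matrix(16, 4, rng)
        W2 = np.roll(W1, 2, axis=0)
        n, _ = count_shared(W1, W2)
        assert n == 0

    def test_noisy_copies_detected(self):
        """3 columns of W2 are noisy copies of W1 columns, 1 is independent:
        the count is 3 in nearly every draw, matching brute force."""
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            W1 = g.random((16, 4))
            W2 = np.empty_like(W1)
            W2[:, :3] = np.clip(W1[:, :3] + g.normal(0, 0.05, (16, 3)), 0, None)
            W2[:, 3] = g.random(16)
            n, pairs = count_shared(W1, W2)
            hits += (n == 3 and all(i == j for i, j, _ in pairs[:3]
                                    if i < 3))
        assert hits >= 18

    def test_symmetry(self, rng):
        W1, W2 = rng.random((16, 3)), rng.random((16, 4))
        n12, p12 = count_shared(W1, W2, r_threshold=0.2)
        n21, p21 = count_shared(W2, W1, r_threshold=0.2)
        assert n12 == n21
        assert sorted((j, i) for i, j, _ in p12) == sorted((i, j) for i, j, _ in p21)

    def test_default_threshold_is_critical_r(self, rng):
        # columns correlated just below/above 0.623 flip the verdict
        g = np.random.default_rng(0)
        base = g.random(16)
        thr = critical_r(16, 0.01)
        for target, expected in ((thr - 0.05, 0), (thr + 0.05, 1)):
            # mix base with noise to hit the target correlation approximately
            for _ in range(500):
                cand = np.clip(base + g.normal(0, 0.35, 16), 0, None)
                if abs(pearson_r(base, cand) - target) < 0.01:
                    break
            n, _ = count_shared(base[:, None], cand[:, None])
            assert n == expected

    def test_muscle_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="muscle"):
            count_shared(rng.random((16, 2)), rng.random((8, 2)))


class TestPctShared:
    def test_full_sharing_is_100(self):
        assert pct_shared(4, 4, 4) == pytest.approx(100.0)

    def test_no_sharing_is_0(self):
        assert pct_shared(0, 4, 5) == 0.0

    def test_partial_sharing_formula(self):
        assert pct_shared(2, 4, 4) == pytest.approx(100 * 2 / 6)

    def test_unequal_counts(self):
        assert pct_shared(2, 3, 5) == pytest.approx(100 * 2 / 6)

    def test_strictly_increasing_in_n(self):
        vals = [pct_shared(n, 4, 4) for n in range(5)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            pct_shared(5, 4, 4)


class TestSharedOaInd:
    def test_identical_tasks_fully_shared(self, rng):
        W = rng.random((16, 4)); C = rng.random((4, 50))
        decomps = {t: _decomp(W, C, t) for t in ("x", "y", "z")}
        res = shared_oa(decomps)
        assert all(r.n_shared == 4 and r.pct_shared == 100.0 for r in res)
        assert len(all_task_shared(res)) == 4

    def test_disjoint_tasks_share_nothing(self, rng):
        decomps = {}
        for t in range(3):
            W = np.full((16, 4), 0.01)
            for j in range(4):
                rowset = (np.arange(4) + 4 * ((j + t) % 4)) % 16
                W[rowset, j] = 1.0
            decomps[f"t{t}"] = _decomp(np.roll(W, t, axis=0), task=f"t{t}")
        # construct explicitly uncorrelated designs
        g = np.random.default_rng(3)
        decomps = {f"t{t}": _decomp(np.eye(16)[:, 4 * t:4 * t + 4] + 0.01)
                   for t in range(3)}
        res = shared_oa(decomps)
        assert all(r.n_shared == 0 and r.pct_shared == 0.0 for r in res)
        assert all_task_shared(res) == []

    def test_mismatched_k_rejected_for_oa_allowed_for_ind(self, rng):
        decomps = {"a": _decomp(rng.random((16, 3))),
                   "b": _decomp(rng.random((16, 5)))}
        with pytest.raises(ValueError, match="NoSoA"):
            shared_oa(decomps)
        res = shared_ind(decomps)
        assert res[0].k1 == 3 and res[0].k2 == 5

    def test_unequal_k_uses_eq1_with_both_counts(self, rng):
        W1 = rng.random((16, 3))
        W2 = np.hstack([np.clip(W1[:, :2] + rng.normal(0, 0.03, (16, 2)), 0, None),
                        rng.random((16, 3))])
        res = shared_ind({"a": _decomp(W1), "b": _decomp(W2)})
        r = res[0]
        if r.n_shared == 2:
            assert r.pct_shared == pytest.approx(100 * 2 / 6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_count_bounded_by_smaller_k(self, seed):
        g = np.random.default_rng(seed)
        k1, k2 = g.integers(1, 6), g.integers(1, 6)
        n, _ = count_shared(g.random((16, k1)), g.random((16, k2)),
                            r_threshold=float(g.uniform(0.1, 0.7)))
        assert 0 <= n <= min(k1, k2)

    def test_greedy_matches_exhaustive_cardinality_on_most_instances(self):
        """For k <= 5 the greedy threshold matching finds the maximum
        number of shared pairs in >= 95% of random instances."""
        import itertools as it
        agree = 0
        trials = 60
        for seed in range(trials):
            g = np.random.default_rng(seed)
            W1, W2 = g.random((16, 4)), g.random((16, 4))
            thr = 0.3
            n_greedy, _ = count_shared(W1, W2, r_threshold=thr)
            R = np.array([[pearson_r(W1[:, i], W2[:, j]) for j in range(4)]
                          for i in range(4)])
            n_opt = max(sum(R[i, p[i]] > thr for i in range(4))
                        for p in it.permutations(range(4)))
            agree += (n_greedy == n_opt)
        assert agree / trials >= 0.95


class TestAllTaskShared:
    def test_single_shared_synergy_detected_noiselessly(self, noiseless_study):
        """The generator's one declared all-task synergy is the only one
        flagged as shared across all three tasks."""
        _trials, gt, envelopes = noiseless_study
        decomps = {task: nmf(envelopes["P01"][task].E, 4, restarts=5, seed=0,
                             max_iter=300)
                   for task in gt.tasks()}
        res = shared_oa(decomps, participant_id="P01")
        assert len(all_task_shared(res)) == 1

    def test_requires_three_tasks(self, rng):
        W = rng.random((16, 2))
        res = shared_oa({t: _decomp(W) for t in "ab"})
        with pytest.raises(ValueError, match="3 tasks"):
            all_task_shared(res)


class TestCrossTaskReconstruction:
    def test_identical_tasks_reconstruct_perfectly(self, rng):
        W = rng.random((16, 3)) + 0.05; C = rng.random((3, 200))
        E = W @ C
        own = tvaf(E, W, C)
        decomps = {t: _decomp(W, C, t) for t in ("u", "v", "w")}
        df = cross_task_reconstruction(decomps, {t: E for t in "uvw"})
        assert np.allclose(df["tvaf_rec"], own, atol=1e-6)
        assert np.allclose(df["cossim"].dropna(), 1.0, atol=1e-5)

    def test_two_reconstructions_per_task_per_direction(self, rng):
        decomps, envs = {}, {}
        for t in "abc":
            W = rng.random((8, 2)) + 0.05; C = rng.random((2, 60))
            decomps[t] = _decomp(W, C, t)
            envs[t] = W @ C
        df = cross_task_reconstruction(decomps, envs)
        counts = (df.drop_duplicates(["target", "source", "direction"])
                  .groupby(["target", "direction"])["source"].nunique())
        assert (counts == 2).all()

    def test_shared_synergy_better_reconstructed_than_specific(self, noiseless_study):
        """Reconstructing across tasks, the all-task shared synergy's refit
        similarity exceeds the mean of the task-specific synergies'."""
        _trials, gt, envelopes = noiseless_study
        decomps = {task: nmf(envelopes["P01"][task].E, 4, restarts=5, seed=0,
                             max_iter=300)
                   for task in gt.tasks()}
        res = shared_oa(decomps, participant_id="P01")
        triples = all_task_shared(res)
        assert triples
        shared_idx = {t: idx for t, idx in zip(sorted(decomps), triples[0])}
        envs = {t: envelopes["P01"][t].E for t in decomps}
        df = cross_task_reconstruction(decomps, envs)
        w = df[df.part == "W"]
        shared_vals, spec_vals = [], []
        for task in decomps:
            sub = w[w.target == task]
            shared_vals.extend(sub[sub.synergy == shared_idx[task]]["cossim"])
            spec_vals.extend(sub[sub.synergy != shared_idx[task]]["cossim"])
        assert np.nanmean(shared_vals) > np.nanmean(spec_vals)
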