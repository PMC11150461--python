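"""NNLS reconstruction, cross-participant studies and randomized nulls."""

import itertools

import numpy as np
import pytest

from emgsyn.factorization import SynergyDecomposition, nmf, tvaf
from emgsyn.reconstruction import (cross_participant_study, randomized_null,
                                   reconstruct_C, reconstruct_W)


def _decomp(W, C, pid=None):
    return SynergyDecomposition(W=W, C=C, k=W.shape[1], tvaf=99.0, restarts=1,
                                best_restart_seed=0, converged=True,
                                iterations_used=1, participant_id=pid)


class TestReconstructC:
    def test_consistent_system_recovers_exact_coefficients(self, rng):
        W = rng.random((8, 3)); C_true = rng.random((3, 40))
        C_rec, t = reconstruct_C(W @ C_true, W)
        assert np.abs(C_rec - C_true).max() < 1e-6
        assert t >= 99.999

    def test_orthogonal_design_matches_closed_form(self, rng):
        # orthogonal non-negative columns (disjoint supports): NNLS is the
        # per-column scaled projection clipped at zero
        W = np.zeros((6, 2))
        W[:3, 0] = rng.random(3) + 0.5
        W[3:, 1] = rng.random(3) + 0.5
        E = rng.standard_normal((6, 20))
        C_rec, _ = reconstruct_C(np.abs(E), W)
        expected = np.maximum((W.T @ np.abs(E)) / (W * W).sum(axis=0)[:, None], 0)
        assert np.allclose(C_rec, expected, atol=1e-10)

    def test_beats_grid_search_oracle_per_column(self):
        """NNLS residual never exceeds a brute-force grid search over the
        coefficient simplex on random small problems."""
        grid = np.arange(0, 2.0001, 0.01)
        for seed in range(10):
            g = np.random.default_rng(seed)
            W = g.random((4, 3)); E = g.random((4, 5))
            C_rec, _ = reconstruct_C(E, W)
            for col in range(5):
                r_nnls = np.linalg.norm(W @ C_rec[:, col] - E[:, col])
                # coordinate-wise refinement of the best grid point
                best = min(
                    (np.linalg.norm(W @ np.array(c) - E[:, col])
                     for c in itertools.product(grid[::10], repeat=3)))
                assert r_nnls <= best + 1e-9

    def test_zero_column_in_design_rejected(self, rng):
        W = rng.random((5, 2)); W[:, 1] = 0
        with pytest.raises(ValueError, match="zero"):
            reconstruct_C(rng.random((5, 10)), W)

    def test_first_order_optimality_of_active_coordinates(self, rng):
        W = rng.random((6, 3)); E = rng.random((6, 8))
        C_rec, _ = reconstruct_C(E, W)
        for col in range(8):
            r0 = np.linalg.norm(W @ C_rec[:, col] - E[:, col]) ** 2
            for j in range(3):
                for d in (1e-3, -1e-3):
                    c = C_rec[:, col].copy()
                    if c[j] + d < 0:
                        continue
                    c[j] += d
                    assert np.linalg.norm(W @ c - E[:, col]) ** 2 >= r0 - 1e-12

    def test_scale_equivariance(self, rng):
        W = rng.random((6, 3)) + 0.1; E = rng.random((6, 12))
        C1, _ = reconstruct_C(E, W)
        W2 = W.copy(); W2[:, 1] *= 2.0
        C2, _ = reconstruct_C(E, W2)
        assert np.allclose(C2[1], C1[1] / 2.0, atol=1e-8)
        assert np.allclose(C2[[0, 2]], C1[[0, 2]], atol=1e-8)


class TestReconstructW:
    def test_consistent_system_recovers_exact_vectors(self, rng):
        W_true = rng.random((8, 3)); C = rng.random((3, 40))
        W_rec, t = reconstruct_W(W_true @ C, C)
        assert np.abs(W_rec - W_true).max() < 1e-6

    def test_zero_envelope_propagates_tvaf_error(self, rng):
        C = rng.random((2, 30))
        with pytest.raises(ValueError, match="zero"):
            reconstruct_W(np.zeros((4, 30)), C)

    def test_transpose_duality_with_reconstruct_C(self, rng):
        E = rng.random((5, 20)); C = rng.random((3, 20))
        W_rec, _ = reconstruct_W(E, C)
        C_dual, _ = reconstruct_C(E.T, C.T)
        assert np.allclose(W_rec, C_dual.T, atol=1e-10)


class TestCrossParticipantStudy:
    def test_six_reconstructions_per_participant_for_seven(self, rng):
        decomps, envs = {}, {}
        for i in range(7):
            W = rng.random((6, 2)) + 0.05; C = rng.random((2, 100))
            decomps[f"P{i}"] = _decomp(W, C, f"P{i}")
            envs[f"P{i}"] = W @ C
        df = cross_participant_study(decomps, envs)
        per = df[df.part == "W"].groupby("target")["source"].nunique()
        assert (per == 6).all()

    def test_identical_participants_reach_own_tvaf(self, rng):
        W = rng.random((8, 3)) + 0.05; C = rng.random((3, 120))
        E = W @ C
        own = tvaf(E, W, C)
        decomps = {p: _decomp(W, C, p) for p in "ab"}
        df = cross_participant_study(decomps, {"a": E, "b": E})
        assert np.allclose(df["tvaf_rec"], own, atol=1e-6)
        assert np.allclose(df["cossim"].dropna(), 1.0, atol=1e-5)

    def test_tvaf_rec_never_exceeds_jointly_fit_tvaf(self, rng):
        # the target's own NMF minimizes the same objective over BOTH factors
        E1 = rng.random((8, 60)); E2 = rng.random((8, 60))
        d1 = nmf(E1, 3, restarts=4, seed=0)
        d2 = nmf(E2, 3, restarts=4, seed=0)
        d1.participant_id, d2.participant_id = "a", "b"
        df = cross_participant_study({"a": d1, "b": d2}, {"a": E1, "b": E2})
        assert (df["tvaf_rec"] <= df["tvaf_own"] + 1e-6).all()


class TestRandomizedNull:
    def test_deterministic_for_fixed_seed(self, rng):
        W = rng.random((8, 3)) + 0.05; C = rng.random((3, 100))
        target = _decomp(W, C, "t")
        sources = [_decomp(rng.random((8, 3)) + 0.05, rng.random((3, 100)))]
        a = randomized_null(target, W @ C, sources, "W", seed=42)
        b = randomized_null(target, W @ C, sources, "W", seed=42)
        assert np.allclose(a["tvaf_rand"], b["tvaf_rand"])

    def test_null_tvaf_bounded_by_own_tvaf(self, rng):
        E = rng.random((8, 80))
        d = nmf(E, 3, restarts=4, seed=1)
        d.participant_id = "t"
        sources = [_decomp(rng.random((8, 3)) + 0.05, rng.random((3, 80)))
                   for _ in range(3)]
        for part in ("W", "C"):
            df = randomized_null(d, E, sources, part, seed=3)
            assert (df["tvaf_rand"] <= d.tvaf + 1e-6).all()

    def test_one_random_source_per_real_source(self, rng):
        W = rng.random((6, 2)) + 0.05; C = rng.random((2, 50))
        target = _decomp(W, C, "t")
        sources = [_decomp(rng.random((6, 2)) + 0.05, rng.random((2, 50)))
                   for _ in range(6)]
        df = randomized_null(target, W @ C, sources, "C", seed=0)
        assert df["source"].nunique() == 6

    def test_invalid_fixed_part_rejected(self, rng):
        W = rng.random((4, 2)) + 0.05; C = rng.random((2, 30))
        with pytest.raises(ValueError, match="fixed_part"):
            randomized_null(_decomp(W, C), W @ C, [_decomp(W, C)], "X", seed=0)


def test_real_sources_explain_more_than_random_on_shared_structure():
    """With genuinely shared synergy structure across participants, fixing a
    real participant's W explains a target better than a random W (the
    tVAF > tVAF_rec > tVAF_rand ordering)."""
    from emgsyn.io import PipelineConfig
    from emgsyn.pipeline import preprocess_dataset
    from emgsyn.similarity import reorder_to_reference
    from emgsyn.synthetic import GeneratorConfig, generate_dataset

    wins_rec, wins_rand = 0, 0
    n_seeds = 6
    for seed in range(n_seeds):
        cfg = GeneratorConfig(participants=3, tasks=1, trials_per_task=4,
                              participant_variation=0.15,
                              envelope_noise_sd=0.05, seed=100 + seed)
        trials, gt = generate_dataset(cfg)
        envs = preprocess_dataset(trials, gt.muscle_names, PipelineConfig())
        decomps = {}
        for pid in envs:
            d = nmf(envs[pid]["task1"].E, 4, restarts=4, seed=0, max_iter=250,
                    tol=1e-5)
            d.participant_id = pid
            decomps[pid] = d
        reordered, _ = reorder_to_reference(decomps, sorted(decomps)[0])
        E_by_pid = {pid: envs[pid]["task1"].E for pid in envs}
        df = cross_participant_study(reordered, E_by_pid)
        rec = df.drop_duplicates(["target", "source", "direction"])
        mean_own = rec["tvaf_own"].mean()
        mean_rec = rec["tvaf_rec"].mean()
        nulls = []
        for pid in reordered:
            others = [reordered[q] for q in reordered if q != pid]
            for part in ("W", "C"):
                n = randomized_null(reordered[pid], E_by_pid[pid], others,
                                    part, seed=seed)
                nulls.append(n.drop_duplicates(["source", "direction"])
                             ["tvaf_rand"].mean())
        mean_rand = np.mean(nulls)
        wins_rec += mean_own >= mean_rec - 1e-9
        wins_rand += mean_rec > mean_rand
    assert wins_rec == n_seeds
    assert wins_rand >= n_seeds - 1
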