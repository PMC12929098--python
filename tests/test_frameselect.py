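import numpy as np
import pytest

from _oracles import brute_force_purity
from melafuse.frameselect import (
    PurityConfig,
    SelectionResult,
    grid_search_embeddings,
    identity_provider,
    pca_provider,
    prefix_and_window_candidates,
    purity,
    select_frame_subset,
)


class TestPurity:
    def test_single_label_is_one(self):
        rng = np.random.default_rng(0)
        points = rng.random((20, 2))
        assert purity(points, ["A"] * 20, k=5) == 1.0

    def test_two_separated_pairs(self):
        # nearest neighbors enumerated by hand: 0<->1 (A), 10<->11 (B)
        points = np.array([0.0, 1.0, 10.0, 11.0])
        assert purity(points, ["A", "A", "B", "B"], k=1) == 1.0

    def test_alternating_line_with_index_tie_rule(self):
        # each interior point ties between its two unit-distance neighbors;
        # the rule picks the lower index, which always carries the other label
        points = np.array([0.0, 1.0, 2.0, 3.0])
        assert purity(points, ["A", "B", "A", "B"], k=1) == 0.0

    def test_rigid_motion_invariance_euclidean(self):
        rng = np.random.default_rng(1)
        points = rng.random((40, 2))
        labels = rng.integers(0, 3, 40)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = points @ rot.T + np.array([5.0, -3.0])
        assert purity(moved, labels, k=5) == pytest.approx(
            purity(points, labels, k=5), abs=1e-12
        )

    def test_bounds_and_perfection_iff_pure_neighborhoods(self):
        rng = np.random.default_rng(2)
        clusters = np.concatenate([rng.normal(0, 0.1, (15, 2)),
                                   rng.normal(10, 0.1, (15, 2))])
        labels = [0] * 15 + [1] * 15
        assert purity(clusters, labels, k=5) == 1.0
        mixed = rng.random((30, 2))
        assert 0.0 <= purity(mixed, rng.integers(0, 3, 30), k=5) <= 1.0

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            purity(np.random.default_rng(0).random((5, 2)), [0, 1, 0, 1, 0], k=5)

    def test_nonfinite_rejected(self):
        points = np.array([[0.0, 1.0], [np.nan, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            purity(points, [0, 1, 0], k=1)

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "hamming", "cosine"])
    def test_matches_bruteforce_oracle(self, metric):
        rng = np.random.default_rng(hash(metric) % 2**31)
        for _ in range(5):
            n = int(rng.integers(10, 60))
            if metric == "cosine":
                points = rng.normal(1.0, 1.0, (n, 3))
            else:
                points = rng.integers(0, 5, (n, 3)).astype(float)
            labels = rng.integers(0, 3, n)
            k = int(rng.integers(1, min(8, n)))
            assert purity(points, labels, k=k, metric=metric) == pytest.approx(
                brute_force_purity(points, labels, k, metric), abs=0
            )

    def test_noise_columns_never_help_separated_embedding(self):
        """Appending pure-noise coordinates to a perfectly separated
        embedding never increases purity (over several seeds)."""
        base = np.concatenate([np.full((20, 1), 0.0), np.full((20, 1), 50.0)])
        labels = [0] * 20 + [1] * 20
        clean = purity(base, labels, k=5)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = np.hstack([base, rng.normal(0, 30.0, (40, 3))])
            assert purity(noisy, labels, k=5) <= clean


class TestGridSearch:
    def test_single_config(self, noisy_curves):
        curves, labels = noisy_curves
        matrix = np.stack([c.values for c in curves])
        out = grid_search_embeddings(matrix, labels, [PurityConfig(k=3)])
        assert len(out) == 1 and out[0][1] is not None

    def test_separated_clusters_score_one_with_identity(self):
        points = np.concatenate([np.zeros((10, 2)), np.full((10, 2), 9.0)])
        labels = [0] * 10 + [1] * 10
        out = grid_search_embeddings(points, labels, [PurityConfig(k=3)],
                                     embed=identity_provider)
        assert out[0][1] == 1.0

    def test_collapsing_provider_never_beats_identity(self, noisy_curves):
        curves, labels = noisy_curves
        matrix = np.stack([c.values for c in curves])

        def collapse(m, y, params, seed):
            return np.zeros((len(m), 1))

        collapsed = grid_search_embeddings(matrix, labels, [PurityConfig(k=5)],
                                           embed=collapse)[0][1]
        identity = grid_search_embeddings(matrix, labels, [PurityConfig(k=5)],
                                          embed=identity_provider)[0][1]
        oracle_collapsed = brute_force_purity(np.zeros((len(matrix), 1)), labels, 5)
        assert collapsed == pytest.approx(oracle_collapsed)
        assert collapsed <= identity

    def test_provider_failure_recorded_and_search_continues(self, noisy_curves):
        curves, labels = noisy_curves
        matrix = np.stack([c.values for c in curves])

        def flaky(m, y, params, seed):
            if params.get("boom"):
                raise RuntimeError("provider exploded")
            return pca_provider(m, y, params, seed)

        grid = [PurityConfig(k=3, embed_params={"boom": True}), PurityConfig(k=3)]
        out = grid_search_embeddings(matrix, labels, grid, embed=flaky)
        scores = [s for _, s in out]
        assert None in scores and any(s is not None for s in scores)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_embeddings(np.zeros((5, 2)), [0, 1, 0, 1, 0], [])

    def test_ranking_is_descending(self, noisy_curves):
        curves, labels = noisy_curves
        matrix = np.stack([c.values for c in curves])
        grid = [PurityConfig(k=k) for k in (1, 3, 5, 9)]
        out = grid_search_embeddings(matrix, labels, grid)
        scores = [s for _, s in out if s is not None]
        assert scores == sorted(scores, reverse=True)


class TestSelectFrameSubset:
    def test_single_candidate_returned(self, noisy_curves):
        curves, labels = noisy_curves
        matrix = np.stack([c.values for c in curves])
        result = select_frame_subset(matrix, labels, candidates=[(0, 1, 2)])
        assert result.subset == (0, 1, 2)

    def test_duplicate_candidates_tie_break_smaller_then_earlier(self):
        # two identical columns: all candidates give identical embeddings,
        # so the smallest, earliest subset must win
        rng = np.random.default_rng(3)
        col = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 20)])
        matrix = np.stack([col, col], axis=1)
        labels = [0] * 20 + [1] * 20
        result = select_frame_subset(
            matrix, labels, candidates=[(0, 1), (1,), (0,), (0, 1)],
            embed=identity_provider,
        )
        assert result.subset == (0,)

    def test_empty_candidates_rejected(self, noisy_curves):
        curves, labels = noisy_curves
        matrix = np.stack([c.values for c in curves])
        with pytest.raises(ValueError):
            select_frame_subset(matrix, labels, candidates=[])

    def test_out_of_range_candidate_rejected(self, noisy_curves):
        curves, labels = noisy_curves
        matrix = np.stack([c.values for c in curves])
        with pytest.raises(ValueError):
            select_frame_subset(matrix, labels, candidates=[(0, 99)])

    def test_selection_result_invariants(self):
        with pytest.raises(ValueError):
            SelectionResult(subset=(), purity=0.5, config=PurityConfig())
        with pytest.raises(ValueError):
            SelectionResult(subset=(0, 0), purity=0.5, config=PurityConfig())
        with pytest.raises(ValueError):
            SelectionResult(subset=(0,), purity=1.5, config=PurityConfig())


def test_prefix_and_window_candidates_cover_prefixes():
    candidates = prefix_and_window_candidates(5)
    for length in range(1, 6):
        assert tuple(range(length)) in candidates
    assert (2, 3) in candidates
    assert len(set(candidates)) == len(candidates)


def test_pca_provider_deterministic(noisy_curves):
    curves, labels = noisy_curves
    matrix = np.stack([c.values for c in curves])
    a = pca_provider(matrix, labels, {"n_components": 2}, 0)
    b = pca_provider(matrix, labels, {"n_components": 2}, 99)
    assert np.array_equal(a, b)  # seed-independent by design
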