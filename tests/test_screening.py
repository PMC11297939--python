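"""Subgrouped screening, max-ratio selection and the two summary scenarios."""

import numpy as np
import pytest

from mrdcscreen import (
    PredictorTensor,
    ScoreTable,
    SimulationConfig,
    cutoff_s,
    gen_study1,
    max_ratio_cutoff,
    min_model_size,
    screen,
    select_scenario1,
    select_scenario2,
    subgroup_response,
)
from conftest import spawn_seeds


class TestSubgroupResponse:
    @pytest.mark.parametrize("q,size,blocks", [(10_000, 5, 2000), (16_260, 5, 3252)])
    def test_block_counts(self, q, size, blocks):
        spans = subgroup_response(np.zeros((2, q)), size)
        assert len(spans) == blocks
        assert spans[0] == (0, size) and spans[-1] == (q - size, q)

    def test_remainder_block(self):
        spans = subgroup_response(np.zeros((2, 7)), 5)
        assert [hi - lo for lo, hi in spans] == [5, 2]

    def test_oversized_group_warns_and_yields_single_block(self):
        with pytest.warns(UserWarning, match="single block"):
            assert subgroup_response(np.zeros((2, 3)), 10) == [(0, 3)]


class TestMaxRatioCutoff:
    def test_hand_example(self):
        assert max_ratio_cutoff(np.array([10, 5, 4.8, 0.1, 0.09])) == 3

    def test_tie_takes_first_maximal_index(self):
        assert max_ratio_cutoff(np.array([9.0, 3.0, 1.0])) == 1

    def test_geometric_scores_select_one_with_warning(self):
        w = 5.0 * 0.5 ** np.arange(12)
        with pytest.warns(UserWarning, match="no separable gap"):
            assert max_ratio_cutoff(w) == 1

    def test_all_equal_selects_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert max_ratio_cutoff(np.full(6, 2.0)) == 1

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            max_ratio_cutoff(np.array([1.0, 5.0, 2.0]))

    def test_search_restricted_to_signal_region(self):
        # a huge ratio deep in the near-zero tail must not win
        w = np.array([10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 1e-6, 1e-13, 1e-14, 1e-15])
        assert max_ratio_cutoff(w) <= 5


class TestScreen:
    def test_pearson_self_correlation(self, rng):
        X = rng.standard_normal((50, 3))
        y = X[:, 0].copy()
        table = screen(y, X, method="pearson-abs")
        assert table.scores[0, 0] == pytest.approx(1.0)
        assert table.scores.shape == (1, 3)

    def test_flattening_convention(self):
        table = ScoreTable(np.arange(8.0).reshape(2, 4), 5, [(0, 5), (5, 10)],
                           [f"X{j}" for j in range(1, 5)], "mrdc")
        assert table.flat_position(2, 3) == 7
        assert table.flat_scores()[6] == table.scores[1, 2]

    def test_column_permutation_equivariance(self, rng):
        Y = rng.standard_normal((40, 6))
        X = rng.standard_normal((40, 8))
        perm = rng.permutation(8)
        a = screen(Y, X, method="mrdc", group_size=3).scores
        b = screen(Y, X[:, perm], method="mrdc", group_size=3).scores
        np.testing.assert_allclose(b, a[:, perm], atol=1e-12)

    def test_response_rank_cache_is_transparent(self, rng):
        Y = rng.standard_cauchy((30, 7))
        X = PredictorTensor(rng.standard_cauchy((30, 5, 2)))
        a = screen(Y, X, method="mrdc", group_size=3, cache_response_ranks=True)
        b = screen(Y, X, method="mrdc", group_size=3, cache_response_ranks=False)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_method_shape_incompatibility_fails_fast(self, rng):
        with pytest.raises(ValueError, match="pearson-abs"):
            screen(rng.standard_normal((20, 2)), rng.standard_normal((20, 4)),
                   method="pearson-abs")
        with pytest.raises(ValueError, match="sample mismatch"):
            screen(rng.standard_normal(20), rng.standard_normal((21, 4)))

    def test_top_predictor_tracks_the_signal_across_seeds(self):
        # scaled-down heavy-tailed draws: the best-scoring predictor is a true
        # one in most seeds, and with rho = 0.8 the remaining winners are
        # immediate AR(1) neighbours of a true predictor (corr 0.8 with it)
        truth = {1, 6, 12, 22}
        neighbourhood = truth | {t + off for t in truth for off in (-1, 1)}
        exact = near = 0
        for seed in spawn_seeds(11, 50):
            ds = gen_study1(SimulationConfig(study="study1", n=200, p=300, seed=seed))
            table = screen(ds.Y, ds.X, method="mrdc")
            top = int(np.argmax(table.scores[0])) + 1
            exact += top in truth
            near += top in neighbourhood
        assert exact >= 30
        assert near >= 45

    def test_sure_screening_tendency_with_growing_n(self):
        # P(all truth within [n/log n]) should not decrease as n grows
        rates = []
        for i, n in enumerate([100, 200, 400]):
            cut = cutoff_s(n)
            ok = 0
            for seed in spawn_seeds(100 + i, 10):
                ds = gen_study1(SimulationConfig(study="study1", n=n, p=1000, seed=seed))
                S = min_model_size(screen(ds.Y, ds.X, method="mrdc"),
                                   ds.truth_positions(5))
                ok += S <= cut
            rates.append(ok / 10)
        assert rates == sorted(rates)


class TestScenarios:
    def _table(self, scores):
        scores = np.asarray(scores, dtype=float)
        G, p = scores.shape
        return ScoreTable(scores, 5, [(5 * g, 5 * g + 5) for g in range(G)],
                          [f"X{j + 1}" for j in range(p)], "mrdc")

    def test_scenario1_dominant_gap(self):
        scores = np.full((3, 4), 0.1)
        scores[1, 2] = 0.9
        sel = select_scenario1(self._table(scores))
        assert sel.scenario1 == [(2, 3)]
        assert sel.scenario1_positions == [7]

    def test_scenario1_all_equal_selects_one_with_warning(self):
        with pytest.warns(UserWarning):
            sel = select_scenario1(self._table(np.full((2, 3), 0.5)))
        assert len(sel.scenario1) == 1

    def test_scenario2_detects_pleiotropy(self, rng):
        # predictor 1 weakly linked to every subgroup; predictor 2 strongly
        # linked to subgroup 1 only
        n, p, G = 150, 12, 8
        X = rng.standard_normal((n, p))
        Y = 0.35 * np.tile(X[:, [0]], (1, 5 * G)) + rng.standard_normal((n, 5 * G))
        Y[:, 0] += 5.0 * X[:, 1]
        table = screen(Y, X, method="mrdc", group_size=5)
        sel = select_scenario2(table)
        counts = sel.per_predictor_count
        assert counts[0] == max(counts)
        assert counts[0] >= G - 2  # near-every-subgroup selection
        assert counts[1] <= counts[0] / 2
        # the strong single link dominates the per-predictor maxima instead
        assert sel.per_predictor_max[1] == table.scores[:, 1].max()
        s1 = select_scenario1(table)
        assert (1, 2) in s1.scenario1

    def test_single_group_counts_are_binary(self, rng):
        Y = rng.standard_normal((40, 2))
        X = rng.standard_normal((40, 5))
        sel = select_scenario2(screen(Y, X, method="mrdc", group_size=2))
        assert set(np.unique(sel.per_predictor_count)) <= {0, 1}
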