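"""Egocentric k-NN neighborhoods: expansion rule, aggregates, invariances."""

import numpy as np
import pandas as pd
import pytest

from neighbordep.errors import DataError, InsufficientPopulationError
from neighbordep.neighborhoods import (
    build_grid,
    contexts_for_mothers,
    contexts_to_frame,
    frame_to_contexts,
    knn_context,
)
from neighbordep.studies import brute_force_context

from conftest import random_person_table


def _person_table(rows):
    """rows: list of (person_id, e, n, income, percentile)."""
    return pd.DataFrame(
        rows, columns=["person_id", "square_e", "square_n", "equiv_income", "income_percentile"]
    )


def _square(e, n, count, start_id, income=1e5, pct=50):
    return [(start_id + i, e, n, income, pct) for i in range(count)]


class TestBuildGrid:
    def test_three_persons_one_square(self):
        grid = build_grid(_person_table(_square(3, 4, 3, 0)))
        assert grid.coords.tolist() == [[3, 4]]
        assert grid.counts.tolist() == [3]
        assert grid.hist[0].sum() == 3

    def test_empty_table(self):
        grid = build_grid(_person_table([]))
        assert grid.total_population == 0

    def test_negative_square_rejected(self):
        with pytest.raises(DataError):
            build_grid(_person_table([(0, -1, 2, 1e5, 50)]))

    def test_counts_match_groupby_oracle(self, small_population):
        grid = build_grid(small_population)
        oracle = small_population.groupby(["square_e", "square_n"]).size()
        assert grid.total_population == len(small_population)
        for (e, n), cnt in oracle.items():
            assert grid.counts[grid.row_of((e, n))] == cnt
        # per-square histogram sums to that square's count
        assert np.array_equal(grid.hist.sum(axis=1), grid.counts)


class TestKnnContext:
    def test_overshoot_when_focal_square_exceeds_k(self):
        grid = build_grid(_person_table(_square(5, 5, 150, 0)))
        ctx = knn_context(grid, (5, 5), 100)
        assert ctx.squares.tolist() == [[5, 5]]
        assert ctx.n_neighbors == 150
        assert ctx.mean_distance_m == 0.0

    def test_equidistant_batch_included_atomically(self):
        rows = _square(5, 5, 10, 0)
        for i, (e, n) in enumerate([(4, 5), (6, 5), (5, 4), (5, 6)]):
            rows += _square(e, n, 30, 1000 * (i + 1))
        grid = build_grid(_person_table(rows))
        ctx = knn_context(grid, (5, 5), 100)
        # 10 focal + the whole ring of 4 x 30 equidistant squares
        assert ctx.n_neighbors == 130
        assert len(ctx.squares) == 5

    def test_k_one_returns_focal_square_only(self):
        rows = _square(2, 2, 4, 0) + _square(3, 2, 4, 100)
        grid = build_grid(_person_table(rows))
        ctx = knn_context(grid, (2, 2), 1)
        assert ctx.squares.tolist() == [[2, 2]]
        assert ctx.n_neighbors == 4  # whole square included

    def test_insufficient_population(self):
        grid = build_grid(_person_table(_square(0, 0, 5, 0)))
        with pytest.raises(InsufficientPopulationError) as err:
            knn_context(grid, (0, 0), 100)
        assert err.value.k_level == 100

    def test_minimality_of_last_batch(self):
        rng = np.random.default_rng(4)
        grid = build_grid(random_person_table(rng, 20, 3_000))
        for k in (50, 400, 1111):
            ctx = knn_context(grid, (10, 10), k)
            d2 = ((ctx.squares - np.array([10, 10])) ** 2).sum(axis=1)
            last = d2.max()
            inner = ctx.squares[d2 < last]
            inner_count = sum(
                grid.counts[grid.row_of(tuple(sq))] for sq in inner
            )
            assert ctx.n_neighbors >= k
            assert inner_count < k


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(6):
            extent = int(rng.integers(4, 40))
            n = int(rng.integers(100, 4_000))
            grid = build_grid(random_person_table(rng, extent, n))
            k = int(rng.integers(1, n + 1))
            focal = (int(rng.integers(extent)), int(rng.integers(extent)))
            got = knn_context(grid, focal, k)
            want = brute_force_context(grid, focal, k)
            assert sorted(map(tuple, got.squares.tolist())) == want["squares"]
            assert got.n_neighbors == want["n_neighbors"]
            assert np.array_equal(got.percentile_hist, want["hist"])
            assert got.mean_income == pytest.approx(want["mean_income"], rel=1e-12)
            assert got.mean_distance_m == pytest.approx(
                want["mean_distance_m"], rel=1e-9
            )


class TestInvariances:
    def test_monotone_and_nested_across_k(self, small_population):
        grid = build_grid(small_population)
        mothers = small_population.sample(15, random_state=1)
        ks = [50, 200, 800, 1999]
        contexts = contexts_for_mothers(grid, mothers, ks)
        by_mother = {}
        for c in contexts:
            by_mother.setdefault(c.mother_id, []).append(c)
        for seq in by_mother.values():
            seq.sort(key=lambda c: c.k_level)
            for a, b in zip(seq, seq[1:]):
                assert a.n_neighbors <= b.n_neighbors
                assert a.mean_distance_m <= b.mean_distance_m + 1e-9
                assert set(map(tuple, a.squares.tolist())) <= set(
                    map(tuple, b.squares.tolist())
                )
            for c in seq:
                assert c.percentile_hist.sum() == c.n_neighbors

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        tab = random_person_table(rng, 15, 800)
        shifted = tab.assign(square_e=tab.square_e + 37, square_n=tab.square_n + 11)
        a = knn_context(build_grid(tab), (7, 7), 300)
        b = knn_context(build_grid(shifted), (7 + 37, 7 + 11), 300)
        assert a.n_neighbors == b.n_neighbors
        assert np.array_equal(a.percentile_hist, b.percentile_hist)
        assert a.mean_distance_m == pytest.approx(b.mean_distance_m, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        tab = random_person_table(rng, 12, 500)
        perm = tab.sample(frac=1, random_state=3).reset_index(drop=True)
        a = knn_context(build_grid(tab), (6, 6), 200)
        b = knn_context(build_grid(perm), (6, 6), 200)
        assert a.n_neighbors == b.n_neighbors
        assert np.array_equal(a.percentile_hist, b.percentile_hist)
        assert a.mean_income == pytest.approx(b.mean_income, rel=1e-12)


class TestContextsForMothers:
    def test_matches_per_mother_knn(self, small_population):
        grid = build_grid(small_population)
        mothers = small_population.sample(10, random_state=2)
        contexts = contexts_for_mothers(grid, mothers, [100, 500])
        for c in contexts:
            m = mothers[mothers.person_id == c.mother_id].iloc[0]
            ref = knn_context(grid, (m.square_e, m.square_n), c.k_level)
            assert c.n_neighbors == ref.n_neighbors
            assert np.array_equal(c.percentile_hist, ref.percentile_hist)
            assert c.mean_income == pytest.approx(ref.mean_income, rel=1e-12)

    def test_exclude_self_removes_one_neighbor(self, small_population):
        grid = build_grid(small_population)
        mothers = small_population.sample(8, random_state=4)
        inc = contexts_for_mothers(grid, mothers, [100], include_self=True)
        exc = contexts_for_mothers(grid, mothers, [100], include_self=False)
        for a, b in zip(inc, exc):
            assert b.percentile_hist.sum() == b.n_neighbors
            assert b.n_neighbors >= 100
            m = mothers[mothers.person_id == a.mother_id].iloc[0]
            # the mother's percentile loses exactly one count unless the
            # reduced focal count pulled in an extra batch
            if a.n_neighbors - 1 >= 100:
                assert a.n_neighbors - b.n_neighbors == 1
                diff = a.percentile_hist - b.percentile_hist
                assert diff[int(m.income_percentile) - 1] == 1
                assert diff.sum() == 1

    def test_isolated_dense_square_identical_at_all_k(self):
        grid = build_grid(_person_table(_square(9, 9, 10_000, 0)))
        mothers = _person_table(_square(9, 9, 1, 50_000))
        contexts = contexts_for_mothers(grid, mothers, [100, 400, 1600, 6400])
        for c in contexts:
            assert c.squares.tolist() == [[9, 9]]
            assert c.n_neighbors == 10_000

    def test_round_trip_through_frame(self, small_population):
        grid = build_grid(small_population)
        mothers = small_population.sample(5, random_state=5)
        contexts = contexts_for_mothers(grid, mothers, [100])
        back = frame_to_contexts(contexts_to_frame(contexts))
        for a, b in zip(contexts, back):
            assert a.n_neighbors == b.n_neighbors
            assert np.array_equal(a.percentile_hist, b.percentile_hist)
            assert a.mean_income == pytest.approx(b.mean_income)
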