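"""Individualized (egocentric) neighborhoods on a 100 m population grid.

Each mother's neighborhood of approximate size ``k`` is built by including
whole grid squares in order of centroid distance from her home square until
the cumulative resident count reaches at least ``k``.  Squares at identical
distance form an atomic batch (all included or none), so results do not
depend on any arbitrary ordering of tied squares; because whole squares are
included, the realized neighbor count can overshoot ``k``.

Distances are planar Euclidean distances between square centroids
(``centroid = (100 e + 50, 100 n + 50)`` meters); residents of the focal
square sit at distance zero and are always included first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientPopulationError
from .indices import N_PERCENTILES

SQUARE_SIZE_M = 100.0


@dataclass
class PopulationGrid:
    """Sparse per-square aggregates of the adult population.

    Only occupied squares are represented.  ``hist`` rows sum to ``counts``;
    ``person_ids`` and ``incomes`` keep per-square resident arrays for
    raw-income sensitivity analyses.
    """

    coords: np.ndarray  # (S, 2) int square indices (e, n)
    counts: np.ndarray  # (S,)
    hist: np.ndarray  # (S, 100)
    income_sum: np.ndarray  # (S,)
    person_ids: list  # list of arrays
    incomes: list  # list of arrays
    square_index: dict  # (e, n) -> row

    @property
    def total_population(self) -> int:
        return int(self.counts.sum())

    def row_of(self, square: tuple[int, int]) -> int | None:
        return self.square_index.get((int(square[0]), int(square[1])))


@dataclass
class NeighborhoodContext:
    """One mother x one k-level individualized neighborhood."""

    mother_id: object
    k_level: int
    squares: np.ndarray  # (m, 2) included square indices
    n_neighbors: int
    percentile_hist: np.ndarray  # (100,)
    mean_distance_m: float
    mean_income: float


def build_grid(persons: pd.DataFrame) -> PopulationGrid:
    """Aggregate a person table (with assigned percentiles) into a grid.

    ``persons`` needs columns ``person_id, square_e, square_n,
    equiv_income, income_percentile``.
    """
    required = {"person_id", "square_e", "square_n", "equiv_income", "income_percentile"}
    missing = required - set(persons.columns)
    if missing:
        raise DataError(f"person table missing columns: {sorted(missing)}")
    if len(persons) == 0:
        return PopulationGrid(
            coords=np.empty((0, 2), dtype=np.int64),
            counts=np.empty(0, dtype=np.int64),
            hist=np.empty((0, N_PERCENTILES), dtype=np.int64),
            income_sum=np.empty(0),
            person_ids=[],
            incomes=[],
            square_index={},
        )
    if (persons["square_e"].min() < 0) or (persons["square_n"].min() < 0):
        raise DataError("negative grid-square index in person table")
    pct = persons["income_percentile"].to_numpy()
    if np.any(pd.isna(pct)) or pct.min() < 1 or pct.max() > N_PERCENTILES:
        raise DataError("income percentiles must be assigned (1..100) before gridding")

    df = persons.sort_values(["square_n", "square_e"], kind="stable")
    keys = df["square_e"].to_numpy() * np.int64(2**32) + df["square_n"].to_numpy()
    uniq, start_idx, counts = np.unique(keys, return_index=True, return_counts=True)
    order = np.argsort(start_idx, kind="stable")
    uniq, start_idx, counts = uniq[order], start_idx[order], counts[order]

    e = (uniq // 2**32).astype(np.int64)
    n = (uniq % 2**32).astype(np.int64)
    coords = np.column_stack([e, n])
    S = coords.shape[0]

    pct_arr = df["income_percentile"].to_numpy(dtype=np.int64)
    inc_arr = df["equiv_income"].to_numpy(dtype=float)
    pid_arr = df["person_id"].to_numpy()

    hist = np.zeros((S, N_PERCENTILES), dtype=np.int64)
    income_sum = np.zeros(S)
    person_ids, incomes = [], []
    pos = 0
    for i in range(S):
        sl = slice(pos, pos + counts[i])
        np.add.at(hist[i], pct_arr[sl] - 1, 1)
        income_sum[i] = inc_arr[sl].sum()
        person_ids.append(pid_arr[sl])
        incomes.append(inc_arr[sl])
        pos += counts[i]

    square_index = {(int(ee), int(nn)): i for i, (ee, nn) in enumerate(coords)}
    return PopulationGrid(
        coords=coords,
        counts=counts.astype(np.int64),
        hist=hist,
        income_sum=income_sum,
        person_ids=person_ids,
        incomes=incomes,
        square_index=square_index,
    )


def _expansion_order(grid: PopulationGrid, focal: tuple[int, int]):
    """Occupied squares sorted by squared centroid distance from ``focal``.

    Squared distances are exact integers (in square units), so tie batches
    are exact, not floating-point accidents.
    """
    de = grid.coords[:, 0] - int(focal[0])
    dn = grid.coords[:, 1] - int(focal[1])
    d2 = de * de + dn * dn
    order = np.argsort(d2, kind="stable")
    return order, d2


def _batch_closed_cut(d2_sorted: np.ndarray, cum: np.ndarray, k: int) -> int:
    """Index (inclusive) of the last square once the tie batch reaching
    cumulative count >= k is closed."""
    idx = int(np.searchsorted(cum, k))
    last_d2 = d2_sorted[idx]
    hi = int(np.searchsorted(d2_sorted, last_d2, side="right")) - 1
    return hi


def knn_context(
    grid: PopulationGrid,
    focal_square: tuple[int, int],
    k_level: int,
    mother_id=None,
    focal_count_adjust: int = 0,
) -> NeighborhoodContext:
    """Individualized neighborhood of approximate size ``k_level`` around the
    centroid of ``focal_square``.

    ``focal_count_adjust`` (-1 when the focal mother is excluded from her own
    neighbor count) is applied to the focal square before the expansion
    threshold and the aggregates.
    """
    if k_level < 1:
        raise DataError("k_level must be >= 1")
    total = grid.total_population + focal_count_adjust
    if total < k_level:
        raise InsufficientPopulationError(k_level, total)

    order, d2 = _expansion_order(grid, focal_square)
    d2_sorted = d2[order].astype(float)
    counts = grid.counts[order].astype(np.int64)
    if focal_count_adjust:
        frow = grid.row_of(focal_square)
        if frow is None:
            raise DataError("cannot adjust focal count: focal square is empty")
        counts = counts.copy()
        counts[np.nonzero(order == frow)[0][0]] += focal_count_adjust
    cum = np.cumsum(counts)
    hi = _batch_closed_cut(d2_sorted, cum, k_level)

    inc_rows = order[: hi + 1]
    n_neighbors = int(cum[hi])
    hist = grid.hist[inc_rows].sum(axis=0)
    income = float(grid.income_sum[inc_rows].sum())
    dist = SQUARE_SIZE_M * np.sqrt(d2_sorted[: hi + 1])
    wdist = float((counts[: hi + 1] * dist).sum())
    return NeighborhoodContext(
        mother_id=mother_id,
        k_level=int(k_level),
        squares=grid.coords[inc_rows],
        n_neighbors=n_neighbors,
        percentile_hist=hist.copy(),
        mean_distance_m=wdist / n_neighbors,
        mean_income=income / n_neighbors,
    )


def contexts_for_mothers(
    grid: PopulationGrid,
    mothers: pd.DataFrame,
    k_levels: Sequence[int],
    include_self: bool = True,
) -> list[NeighborhoodContext]:
    """One context per mother x k-level.

    Mothers sharing a home square share the expansion, so the distance sort
    is done once per occupied focal square.  With ``include_self=False`` the
    mother is removed from her own square's count, histogram and income sum
    before thresholding and aggregation.

    ``mothers`` needs ``person_id, square_e, square_n`` and, when
    ``include_self=False``, ``income_percentile`` and ``equiv_income``.
    """
    ks = [int(k) for k in k_levels]
    if not ks or ks != sorted(ks):
        raise DataError("k_levels must be non-empty and ascending")
    adjust = 0 if include_self else -1
    total = grid.total_population + adjust
    for k in ks:
        if total < k:
            raise InsufficientPopulationError(k, total)

    out: list[NeighborhoodContext] = []
    for (se, sn), group in mothers.groupby(["square_e", "square_n"], sort=True):
        focal = (int(se), int(sn))
        order, d2 = _expansion_order(grid, focal)
        d2_sorted = d2[order].astype(float)
        counts = grid.counts[order].astype(np.int64)
        if adjust:
            frow = grid.row_of(focal)
            if frow is None:
                raise DataError(
                    f"mother registered in empty square {focal}; cannot exclude self"
                )
            counts = counts.copy()
            counts[np.nonzero(order == frow)[0][0]] += adjust
        cum = np.cumsum(counts)
        dist = SQUARE_SIZE_M * np.sqrt(d2_sorted)

        per_k = []
        for k in ks:
            hi = _batch_closed_cut(d2_sorted, cum, k)
            inc_rows = order[: hi + 1]
            n_base = int(cum[hi])
            hist = grid.hist[inc_rows].sum(axis=0)
            income = float(grid.income_sum[inc_rows].sum())
            wdist = float((counts[: hi + 1] * dist[: hi + 1]).sum())
            per_k.append((k, grid.coords[inc_rows], n_base, hist, income, wdist))

        for _, m in group.iterrows():
            for k, squares, n_base, hist, income, wdist in per_k:
                if include_self:
                    h, inc, n_nb = hist, income, n_base
                else:
                    h = hist.copy()
                    h[int(m["income_percentile"]) - 1] -= 1
                    inc = income - float(m["equiv_income"])
                    n_nb = n_base
                out.append(
                    NeighborhoodContext(
                        mother_id=m["person_id"],
                        k_level=k,
                        squares=squares,
                        n_neighbors=n_nb,
                        percentile_hist=h if include_self is False else hist.copy(),
                        mean_distance_m=wdist / n_nb,
                        mean_income=inc / n_nb,
                    )
                )
    return out


def contexts_to_frame(contexts: list[NeighborhoodContext]) -> pd.DataFrame:
    """Long-format contexts table with p01..p100 histogram columns."""
    rows = {
        "mother_id": [c.mother_id for c in contexts],
        "k_level": [c.k_level for c in contexts],
        "n_neighbors": [c.n_neighbors for c in contexts],
        "mean_distance_m": [c.mean_distance_m for c in contexts],
        "mean_income": [c.mean_income for c in contexts],
    }
    H = (
        np.stack([c.percentile_hist for c in contexts])
        if contexts
        else np.empty((0, N_PERCENTILES), dtype=np.int64)
    )
    df = pd.DataFrame(rows)
    hist_df = pd.DataFrame(
        H, columns=[f"p{i:02d}" for i in range(1, N_PERCENTILES + 1)]
    )
    return pd.concat([df.reset_index(drop=True), hist_df], axis=1)


def frame_to_contexts(df: pd.DataFrame) -> list[NeighborhoodContext]:
    """Inverse of :func:`contexts_to_frame` (square lists are not persisted)."""
    hist_cols = [f"p{i:02d}" for i in range(1, N_PERCENTILES + 1)]
    H = df[hist_cols].to_numpy(dtype=np.int64)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        out.append(
            NeighborhoodContext(
                mother_id=row.mother_id,
                k_level=int(row.k_level),
                squares=np.empty((0, 2), dtype=np.int64),
                n_neighbors=int(row.n_neighbors),
                percentile_hist=H[i],
                mean_distance_m=float(row.mean_distance_m),
                mean_income=float(row.mean_income),
            )
        )
    return out
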