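"""Income percentiles, Gini inequality and Yitzhaki/Deaton relative deprivation.

The neighborhood analysis characterizes each individualized context by how
many neighbors fall in each national income percentile, so the inequality and
deprivation indices are computed on the percentile *representative incomes*
(the national within-percentile mean equivalized income), not on raw incomes;
a raw-income mode is available for sensitivity analyses.

Definitions
-----------
Gini index of incomes ``y_1..y_n`` with mean ``mu``::

    G = sum_i sum_j |y_i - y_j| / (2 n^2 mu)

Yitzhaki index of a person with income ``y`` in reference group ``R``::

    RD = (1/|R|) * sum_{y_j in R, y_j > y} (y_j - y)

Deaton index: ``D = RD / mean(R)``, in [0, 1].

The ``n^2`` Gini denominator is the form under which the population mean of
the Deaton index equals the group's Gini index exactly; that identity is this
module's primary internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedIndexError, PipelineError

N_PERCENTILES = 100


@dataclass
class PercentileScale:
    """National income-percentile scale.

    breakpoints
        99 non-decreasing income thresholds; the upper bound of percentiles
        1..99 in the reference population.
    representative_income
        length-100 vector of mean equivalized income within each percentile.
    """

    breakpoints: np.ndarray
    representative_income: np.ndarray

    def __post_init__(self):
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.representative_income = np.asarray(
            self.representative_income, dtype=float
        )
        if self.breakpoints.shape != (N_PERCENTILES - 1,):
            raise DataError("breakpoints must have length 99")
        if self.representative_income.shape != (N_PERCENTILES,):
            raise DataError("representative_income must have length 100")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": np.arange(1, N_PERCENTILES + 1),
                "representative_income": self.representative_income,
                "upper_break": np.append(self.breakpoints, np.nan),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PercentileScale":
        df = df.sort_values("percentile")
        return cls(
            breakpoints=df["upper_break"].to_numpy()[:-1],
            representative_income=df["representative_income"].to_numpy(),
        )


def compute_income_percentiles(
    incomes: Sequence[float], person_ids: Sequence | None = None
) -> tuple[np.ndarray, PercentileScale]:
    """Assign each person a percentile 1..100 and build the national scale.

    Percentile ``p`` contains the ranks in ``((p-1)*n/100, p*n/100]`` of the
    stable ordering by ``(income, person_id)``, so equal incomes split
    deterministically across percentile boundaries.

    Returns ``(percentiles, scale)`` where ``percentiles[i]`` is the
    percentile of ``incomes[i]``.
    """
    y = np.asarray(incomes, dtype=float)
    n = y.size
    if n < N_PERCENTILES:
        raise DataError(
            f"need at least {N_PERCENTILES} incomes to form percentiles, got {n}"
        )
    if np.any(y < 0):
        raise DataError("incomes must be floored at 0 before percentile computation")
    if person_ids is None:
        person_ids = np.arange(n)
    pid = np.asarray(person_ids)
    order = np.lexsort((pid, y))  # stable: income, then person_id
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    # rank r -> percentile ceil(r * 100 / n)
    percentiles = -(-ranks * N_PERCENTILES // n)

    sorted_y = y[order]
    rep = np.empty(N_PERCENTILES)
    breaks = np.empty(N_PERCENTILES - 1)
    bounds = (np.arange(N_PERCENTILES + 1) * n) // N_PERCENTILES
    for p in range(N_PERCENTILES):
        rep[p] = sorted_y[bounds[p] : bounds[p + 1]].mean()
        if p < N_PERCENTILES - 1:
            breaks[p] = sorted_y[bounds[p + 1] - 1]
    return percentiles.astype(np.int64), PercentileScale(breaks, rep)


def gini_exact(incomes: Iterable[float]) -> float:
    """Gini index of a non-negative income vector (``n^2`` denominator).

    Computed via the sorted-rank identity, which equals the normalized mean
    absolute pairwise difference exactly, ties included.
    """
    y = np.sort(np.asarray(list(incomes) if not hasattr(incomes, "dtype") else incomes, dtype=float))
    n = y.size
    if n == 0:
        raise UndefinedIndexError("Gini undefined for an empty income vector")
    if np.any(y < 0):
        raise DataError("Gini requires non-negative incomes")
    total = y.sum()
    if total == 0:
        raise UndefinedIndexError("Gini undefined when all incomes are zero")
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * y) - (n + 1) * total) / (n * total))


def _rep_abs_diff(rep: np.ndarray) -> np.ndarray:
    return np.abs(rep[:, None] - rep[None, :])


def gini_from_histogram(
    percentile_hist: Sequence[float], scale: PercentileScale
) -> float:
    """Gini of a neighborhood given its percentile histogram.

    Equals :func:`gini_exact` applied to the multiset that repeats the
    percentile representative income ``hist[p]`` times.
    """
    h = np.asarray(percentile_hist, dtype=float)
    if h.shape != (N_PERCENTILES,):
        raise DataError("percentile histogram must have length 100")
    n = h.sum()
    if n < 1:
        raise UndefinedIndexError("Gini undefined for an empty histogram")
    rep = scale.representative_income
    mu = float(h @ rep) / n
    if mu == 0:
        raise UndefinedIndexError("Gini undefined when all incomes are zero")
    pair = float(h @ _rep_abs_diff(rep) @ h)
    return pair / (2.0 * n * n * mu)


def yitzhaki(own_income: float, ref_incomes: Iterable[float]) -> float:
    """Mean shortfall relative to richer members of the reference group.

    ``RD = (1/N) * sum_{y_j > own} (y_j - own)`` in the income unit (SEK/year).
    """
    ref = np.asarray(list(ref_incomes) if not hasattr(ref_incomes, "dtype") else ref_incomes, dtype=float)
    if ref.size == 0:
        raise DataError("Yitzhaki index needs a non-empty reference group")
    excess = ref - own_income
    return float(excess[excess > 0].sum() / ref.size)


def deaton(own_income: float, ref_incomes: Iterable[float]) -> float:
    """Yitzhaki index normalized by the reference-group mean income; in [0, 1]."""
    ref = np.asarray(list(ref_incomes) if not hasattr(ref_incomes, "dtype") else ref_incomes, dtype=float)
    if ref.size == 0:
        raise DataError("Deaton index needs a non-empty reference group")
    mu = ref.mean()
    if mu <= 0:
        raise UndefinedIndexError("Deaton index undefined for zero mean income")
    # mathematically in [0, 1]; clamp float round-off at the top
    return min(yitzhaki(own_income, ref) / mu, 1.0)


def deaton_from_histogram(
    own_percentile: int, percentile_hist: Sequence[float], scale: PercentileScale
) -> float:
    """Deaton index of a mother in percentile ``own_percentile`` against her
    neighborhood's percentile histogram."""
    h = np.asarray(percentile_hist, dtype=float)
    rep = scale.representative_income
    n = h.sum()
    if n < 1:
        raise DataError("empty neighborhood histogram")
    own = rep[own_percentile - 1]
    mu = float(h @ rep) / n
    if mu <= 0:
        raise UndefinedIndexError("Deaton index undefined for zero mean income")
    excess = np.maximum(rep - own, 0.0)
    return min(float(h @ excess) / (n * mu), 1.0)


def exposures_for_mothers(
    contexts,
    scale: PercentileScale,
    mothers: pd.DataFrame,
) -> pd.DataFrame:
    """Build the per-mother x k-level exposure table.

    Parameters
    ----------
    contexts
        list of :class:`~neighbordep.neighborhoods.NeighborhoodContext`, one
        per mother x k-level.
    scale
        national percentile scale.
    mothers
        DataFrame with columns ``person_id`` and ``income_percentile``.

    Returns a DataFrame with columns ``mother_id, k_level, gini, deaton,
    mean_income, mean_distance_m``.  Vectorized over contexts: the Gini is a
    quadratic form of the histogram in the representative-income difference
    matrix, and the Deaton numerator is the histogram-weighted positive excess
    over the mother's representative income.
    """
    if len(contexts) == 0:
        return pd.DataFrame(
            columns=["mother_id", "k_level", "gini", "deaton", "mean_income", "mean_distance_m"]
        )
    pct_by_mother = mothers.set_index("person_id")["income_percentile"]
    rep = scale.representative_income

    H = np.stack([c.percentile_hist for c in contexts]).astype(float)
    mids = np.array([c.mother_id for c in contexts])
    try:
        own_pct = pct_by_mother.loc[mids].to_numpy(dtype=np.int64)
    except KeyError as exc:
        raise PipelineError(f"mother missing from percentile table: {exc}") from exc

    n = H.sum(axis=1)
    if np.any(n < 1):
        raise PipelineError("context with empty histogram")
    mu = (H @ rep) / n
    A = _rep_abs_diff(rep)
    gini = np.einsum("ij,jk,ik->i", H, A, H) / (2.0 * n * n * mu)
    # positive excess of every percentile over each context's mother
    excess = np.maximum(rep[None, :] - rep[own_pct - 1][:, None], 0.0)
    dtn = (H * excess).sum(axis=1) / (n * mu)

    return pd.DataFrame(
        {
            "mother_id": mids,
            "k_level": [c.k_level for c in contexts],
            "gini": gini,
            "deaton": dtn,
            "mean_income": [c.mean_income for c in contexts],
            "mean_distance_m": [c.mean_distance_m for c in contexts],
        }
    )


def raw_exposures_for_mothers(contexts, grid, mothers: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity variant of :func:`exposures_for_mothers` on exact incomes.

    Computes Gini and Deaton over the actual equivalized incomes of the
    residents of each context's included squares (the mother's own income as
    her reference point), instead of percentile representative incomes.
    Requires contexts that still carry their ``squares`` arrays and the grid
    they came from.
    """
    own_income = mothers.set_index("person_id")["equiv_income"]
    rows = []
    for c in contexts:
        sq_rows = [grid.square_index[(int(e), int(n))] for e, n in c.squares]
        incomes = np.concatenate([grid.incomes[i] for i in sq_rows])
        rows.append(
            {
                "mother_id": c.mother_id,
                "k_level": c.k_level,
                "gini": gini_exact(incomes),
                "deaton": deaton(float(own_income.loc[c.mother_id]), incomes),
                "mean_income": c.mean_income,
                "mean_distance_m": c.mean_distance_m,
            }
        )
    return pd.DataFrame(rows)
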