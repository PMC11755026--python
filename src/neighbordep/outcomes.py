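"""Dichotomous neonatal outcomes from continuous birth measures.

Five outcomes, all strict-inequality cutoffs:

- preterm: gestational age < 259 days (before completed week 37)
- lbw:     birthweight < 2500 g
- vlbw:    birthweight < 1500 g
- low_apgar: 5-minute Apgar score < 7
- sga:     birthweight below the within-cohort empirical 10th percentile for
  the completed gestational week

Missing continuous fields leave the corresponding flag missing, so the
record drops out of any downstream complete-case model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

PRETERM_DAYS = 37 * 7  # 259
LBW_G = 2500.0
VLBW_G = 1500.0
LOW_APGAR = 7


def dichotomize(births: pd.DataFrame) -> pd.DataFrame:
    """Threshold flags (preterm, lbw, vlbw, low_apgar) for each record.

    Returns a DataFrame indexed like ``births`` with nullable integer flags;
    a missing continuous field yields a missing flag.
    """
    out = pd.DataFrame(index=births.index)
    bw = pd.to_numeric(births.get("birthweight_g"), errors="coerce")
    ga = pd.to_numeric(births.get("gest_age_days"), errors="coerce")
    ap = pd.to_numeric(births.get("apgar5"), errors="coerce")
    out["preterm"] = (ga < PRETERM_DAYS).astype("Int64").where(ga.notna())
    out["lbw"] = (bw < LBW_G).astype("Int64").where(bw.notna())
    out["vlbw"] = (bw < VLBW_G).astype("Int64").where(bw.notna())
    out["low_apgar"] = (ap < LOW_APGAR).astype("Int64").where(ap.notna())
    return out


@dataclass
class SgaReference:
    """Within-cohort 10th-percentile birthweight threshold per completed week.

    Sparse weeks (fewer than ``min_cell_size`` births) are pooled with the
    nearest adjacent week before the percentile is taken; thresholds are then
    made non-decreasing across weeks by a running maximum, since biologically
    the reference curve cannot fall with gestational age.
    """

    thresholds: dict  # completed week -> threshold (g)
    min_cell_size: int = 50

    def threshold_for(self, week: int) -> float:
        if week in self.thresholds:
            return self.thresholds[week]
        weeks = np.array(sorted(self.thresholds))
        nearest = int(weeks[np.argmin(np.abs(weeks - week))])
        return self.thresholds[nearest]


def _empirical_p10(values: np.ndarray) -> float:
    """Lowest order statistic at rank ceil(0.1 n): the empirical 10th
    percentile used as the SGA cutoff."""
    v = np.sort(values)
    r = int(np.ceil(0.1 * v.size))
    return float(v[max(r - 1, 0)])


def build_sga_reference(cohort: pd.DataFrame, min_cell_size: int = 50) -> SgaReference:
    """Empirical SGA reference from a birth cohort.

    ``cohort`` needs ``birthweight_g`` and ``gest_age_days``; completed week
    = floor(days / 7).
    """
    df = cohort.dropna(subset=["birthweight_g", "gest_age_days"])
    if len(df) == 0:
        raise DataError("cannot build SGA reference from an empty cohort")
    weeks = (df["gest_age_days"].to_numpy(dtype=float) // 7).astype(np.int64)
    weights = df["birthweight_g"].to_numpy(dtype=float)

    # pool sparse weeks with the nearest week until every cell is big enough
    cells = {int(w): list(weights[weeks == w]) for w in np.unique(weeks)}
    members = {w: [w] for w in cells}
    while len(cells) > 1:
        sizes = {w: len(v) for w, v in cells.items()}
        small = [w for w, s in sizes.items() if s < min_cell_size]
        if not small:
            break
        w = min(small, key=lambda x: sizes[x])
        others = sorted(set(cells) - {w})
        tgt = min(others, key=lambda o: (abs(o - w), o))
        cells[tgt] = cells[tgt] + cells[w]
        members[tgt] = members[tgt] + members[w]
        del cells[w], members[w]
    if max(len(v) for v in cells.values()) < min_cell_size:
        raise DataError(
            f"cohort of {len(df)} births cannot form any SGA cell of size "
            f">= {min_cell_size}"
        )

    thr_by_cell = {w: _empirical_p10(np.asarray(v)) for w, v in cells.items()}
    thresholds = {}
    for cell_week, weeks_in in members.items():
        for w in weeks_in:
            thresholds[w] = thr_by_cell[cell_week]
    # enforce a non-decreasing reference curve
    run = -np.inf
    for w in sorted(thresholds):
        run = max(run, thresholds[w])
        thresholds[w] = run
    return SgaReference(thresholds=thresholds, min_cell_size=min_cell_size)


def sga_flag(births: pd.DataFrame, ref: SgaReference) -> pd.Series:
    """SGA indicator: birthweight strictly below the week's reference
    threshold; missing where either continuous field is missing."""
    bw = pd.to_numeric(births["birthweight_g"], errors="coerce")
    ga = pd.to_numeric(births["gest_age_days"], errors="coerce")
    ok = bw.notna() & ga.notna()
    thr = pd.Series(np.nan, index=births.index)
    wk = (ga[ok] // 7).astype(int)
    thr[ok] = [ref.threshold_for(w) for w in wk]
    return (bw < thr).astype("Int64").where(ok)


def derive_outcomes(births: pd.DataFrame, min_cell_size: int = 50) -> pd.DataFrame:
    """Full outcome table (mother_id + five flags) from continuous measures."""
    flags = dichotomize(births)
    ref = build_sga_reference(births, min_cell_size=min_cell_size)
    flags.insert(0, "sga", sga_flag(births, ref))
    flags = flags[["sga", "lbw", "vlbw", "preterm", "low_apgar"]]
    if "person_id" in births.columns:
        flags.insert(0, "mother_id", births["person_id"].to_numpy())
    return flags
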