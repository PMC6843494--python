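"""Univariate statistics: per-metabolite Welch t-tests and 2×2 chi-square
tests for baseline characteristics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import PeakTable, SampleMeta

logger = logging.getLogger(__name__)


def welch_t(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    """Two-sample, unequal-variance, two-tailed t-test.

    Uses Welch–Satterthwaite degrees of freedom; returns (t, p).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(x1, x2, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def metabolite_ttests(
    table: PeakTable,
    meta: Sequence[SampleMeta],
    timepoint: str = "T18",
    adjust: bool = False,
) -> pd.DataFrame:
    """Welch t-test per metabolite (active vs placebo) at one time point.

    Only non-missing values enter each test; metabolites with fewer than
    two usable values in either group are flagged untestable and excluded
    (with a log entry).  Raw p-values are reported; ``adjust=True`` adds a
    Benjamini–Hochberg ``q`` column.

    Returns a DataFrame with columns metabolite, direction (sign of the
    active−placebo mean difference), t, p, testable.
    """
    lookup = {m.sample_id: m for m in meta}
    rows_at_tp = [i for i, s in enumerate(table.sample_ids)
                  if lookup[s].timepoint == timepoint]
    groups = np.array([lookup[table.sample_ids[i]].group for i in rows_at_tp])
    if np.unique(groups).size < 2:
        raise ValueError(f"both groups must be present at timepoint {timepoint!r}")
    sub_areas = table.areas[rows_at_tp]
    sub_miss = table.missing_mask[rows_at_tp]

    records = []
    for j, met in enumerate(table.metabolite_ids):
        ok = ~sub_miss[:, j]
        x1 = sub_areas[(groups == 1) & ok, j]
        x0 = sub_areas[(groups == 0) & ok, j]
        if x1.size < 2 or x0.size < 2:
            logger.info("metabolite %s untestable at %s (n_active=%d, n_placebo=%d)",
                        met, timepoint, x1.size, x0.size)
            records.append((met, 0, np.nan, np.nan, False))
            continue
        t, p = welch_t(x1, x0)
        records.append((met, int(np.sign(x1.mean() - x0.mean())), t, p, True))
    df = pd.DataFrame(records, columns=["metabolite", "direction", "t", "p", "testable"])
    if adjust:
        tested = df["testable"]
        q = np.full(len(df), np.nan)
        q[tested.to_numpy()] = sps.false_discovery_control(df.loc[tested, "p"])
        df["q"] = q
    return df


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b) = group-1 yes/no, (c, d) = group-2 yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_margins(cls, yes1: int, total1: int, yes2: int, total2: int) -> "Contingency2x2":
        return cls(yes1, total1 - yes1, yes2, total2 - yes2)


def chi2_2x2(tbl: Contingency2x2) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 table, df=1, no continuity correction.

    Raises on a zero margin (an expected cell of 0 makes the test
    undefined, reported as "n/a" in baseline tables).
    """
    obs = np.array([[tbl.a, tbl.b], [tbl.c, tbl.d]], dtype=float)
    if obs.sum() <= 0:
        raise ValueError("empty contingency table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square test undefined")
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def baseline_tests(table1: pd.DataFrame) -> pd.DataFrame:
    """Chi-square p-values for every testable baseline contingency row.

    Rows with a zero margin or a zero observed cell (e.g. a medication
    taken by no one in one group) get p = NaN, mirroring "n/a" entries in
    published baseline tables where the large-sample chi-square
    approximation is not trusted.
    """
    out = []
    for _, r in table1.iterrows():
        tbl = Contingency2x2.from_margins(
            r["active_n"], r["active_total"], r["placebo_n"], r["placebo_total"]
        )
        try:
            if min(tbl.a, tbl.b, tbl.c, tbl.d) == 0:
                raise ValueError("zero observed cell")
            chi2, p = chi2_2x2(tbl)
        except ValueError:
            chi2, p = np.nan, np.nan
        out.append((r["variable"], chi2, p, r.get("printed_p", "")))
    return pd.DataFrame(out, columns=["variable", "chi2", "p", "printed_p"])
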