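"""Cross-contrast concordance of differential calls.

Two differential contrasts over a shared feature universe (e.g. the
disease-vs-control and drug-vs-vehicle contrasts of the same peak set) are
compared by signed quadrant: features significant in both are placed in
++/--/+-/-+ cells, each cell is tested against the hypergeometric
expectation n*K/N, and direction-stratified fractions report how the
second contrast distributes within each sign stratum of the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .differential import STATUS_DOWN, STATUS_ND, STATUS_UP

QUADRANTS = ("++", "--", "+-", "-+")


class JoinError(ValueError):
    pass


@dataclass
class QuadrantTable:
    n_universe: int
    n_a_up: int
    n_a_down: int
    n_b_up: int
    n_b_down: int
    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def n_double_differential(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class HypergeomResult:
    quadrant: str
    observed: int
    expected: float
    fold: float
    p_upper: float  # P(X >= k), enrichment
    p_lower: float  # P(X <= k), depletion


def _status_frame(results: pd.DataFrame, label: str) -> pd.DataFrame:
    need = {"feature_id", "status"}
    if not need <= set(results.columns):
        raise JoinError(f"contrast {label} lacks columns {need - set(results.columns)}")
    return results[["feature_id", "status"]].set_index("feature_id")


def _join(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    a = _status_frame(results_a, "A")
    b = _status_frame(results_b, "B")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        orphans = list(a.index[:5]) + list(b.index[:5])
        raise JoinError(f"no shared feature ids between contrasts; e.g. {orphans}")
    only_a, only_b = len(a) - len(shared), len(b) - len(shared)
    if only_a or only_b:
        warnings.warn(
            f"{only_a} features only in A and {only_b} only in B were "
            "excluded from the shared universe",
            stacklevel=3,
        )
    return pd.DataFrame(
        {"status_a": a.loc[shared, "status"], "status_b": b.loc[shared, "status"]}
    )


def quadrant_counts(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> QuadrantTable:
    """Signed quadrant counts over the shared tested universe.

    Features differential (status != nd) in both contrasts fall in exactly
    one of ++, --, +-, -+; fractions are over that doubly-differential
    set.  Features tested in only one contrast are excluded from the
    universe with a warning.
    """
    joined = _join(results_a, results_b)
    sign = {STATUS_UP: "+", STATUS_DOWN: "-"}
    both = joined[(joined["status_a"] != STATUS_ND) & (joined["status_b"] != STATUS_ND)]
    counts = {q: 0 for q in QUADRANTS}
    for _, row in both.iterrows():
        counts[sign[row["status_a"]] + sign[row["status_b"]]] += 1
    total = sum(counts.values())
    fractions = {q: (c / total if total else 0.0) for q, c in counts.items()}
    return QuadrantTable(
        n_universe=len(joined),
        n_a_up=int((joined["status_a"] == STATUS_UP).sum()),
        n_a_down=int((joined["status_a"] == STATUS_DOWN).sum()),
        n_b_up=int((joined["status_b"] == STATUS_UP).sum()),
        n_b_down=int((joined["status_b"] == STATUS_DOWN).sum()),
        counts=counts,
        fractions=fractions,
    )


def hypergeom_tests(
    table: QuadrantTable,
    population: Literal["tested", "double_diff"] = "tested",
) -> list[HypergeomResult]:
    """Hypergeometric enrichment/depletion per signed quadrant.

    For quadrant ``++`` the draw is K = #A-up marked items, n = #B-up
    draws from a population of N shared tested features (sign-stratified
    margins; analogous per quadrant).  ``population="double_diff"``
    restricts N to the doubly-differential features instead.  p_upper is
    the enrichment tail P(X >= k); p_lower the depletion tail P(X <= k);
    they share P(X = k), so p_upper + p_lower >= 1.
    """
    N = table.n_universe if population == "tested" else table.n_double_differential
    margins = {
        "+": (table.n_a_up, table.n_b_up),
        "-": (table.n_a_down, table.n_b_down),
    }
    out = []
    for quad in QUADRANTS:
        K = margins[quad[0]][0]
        n = margins[quad[1]][1]
        k = table.counts[quad]
        if N == 0 or K == 0 or n == 0:
            out.append(
                HypergeomResult(quad, k, 0.0, np.nan,
                                p_upper=1.0 if k == 0 else 0.0, p_lower=1.0)
            )
            continue
        expected = n * K / N
        fold = k / expected
        p_upper = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_lower = float(stats.hypergeom.cdf(k, N, K, n))
        out.append(HypergeomResult(quad, k, expected, fold, p_upper, p_lower))
    return out


def direction_fractions(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    stratify_by: Literal["A", "B"] = "A",
) -> pd.DataFrame:
    """Distribution of one contrast's statuses within the other's strata.

    Rows are the up/down strata of the stratifying contrast; columns are
    the up/down/nd fractions of the other contrast; each row sums to 1.
    """
    joined = _join(results_a, results_b)
    if stratify_by == "B":
        joined = joined.rename(
            columns={"status_a": "status_b", "status_b": "status_a"}
        )
    rows = {}
    for stratum in (STATUS_UP, STATUS_DOWN):
        sub = joined[joined["status_a"] == stratum]
        n = len(sub)
        rows[stratum] = {
            s: (float((sub["status_b"] == s).sum()) / n if n else np.nan)
            for s in (STATUS_UP, STATUS_DOWN, STATUS_ND)
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        [STATUS_UP, STATUS_DOWN, STATUS_ND]
    ]
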