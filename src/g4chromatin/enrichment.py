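"""Permutation/resampling enrichment of one interval set within another.

Observed overlap is compared against a null distribution obtained either by
shuffling the query across the genome (length-preserving, excluded regions
respected) or by resampling the query from a stated universe (e.g. the TSS
of differential genes resampled from the TSS of all expressed genes).  The
summary is a z score against the permutation mean/sd, an add-one empirical
p-value, and the fold enrichment observed / expected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .intervals import (
    GenomeSpec,
    IntervalSet,
    overlap_join,
    resample_within_universe,
    shuffle,
)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    n_perm: int
    z: float
    p_empirical: float
    p_normal: float
    fold: float
    alternative: str = "enrichment"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.p_empirical <= 1.0):
            raise ValueError("p_empirical must lie in (0, 1]")


def count_overlaps(
    query: IntervalSet,
    subject: IntervalSet,
    mode: Literal["subject", "pairs"] = "subject",
    min_overlap: int = 1,
) -> int:
    """Overlap count between two interval sets.

    ``subject`` mode (default): number of subject elements overlapped by at
    least one query element.  ``pairs`` mode: number of overlapping
    (query, subject) pairs.
    """
    pairs = overlap_join(query, subject, min_overlap=min_overlap)
    if mode == "pairs":
        return len(pairs)
    if mode == "subject":
        return len({j for _, j, _ in pairs})
    raise ValueError(f"unknown counting mode {mode!r}")


def enrichment_stats(
    observed: float,
    null_draws: Sequence[float] | None = None,
    null_mean: float | None = None,
    null_sd: float | None = None,
    n_perm: int | None = None,
    alternative: str = "enrichment",
) -> EnrichmentResult:
    """Enrichment summary from an observed count plus a null description.

    Accepts either raw permutation draws or a (mean, sd, n) summary.  The
    fold enrichment is observed / null_mean; z = (observed - mean) / sd
    with a two-tail-free normal p for the stated alternative.  Rounding is
    left to presentation.
    """
    if null_draws is not None:
        draws = np.asarray(null_draws, dtype=float)
        if draws.size < 2:
            raise ValueError("need >= 2 null draws for an sd")
        null_mean = float(draws.mean())
        null_sd = float(draws.std(ddof=1))
        n_perm = int(draws.size)
        if alternative == "enrichment":
            exceed = int((draws >= observed).sum())
        else:
            exceed = int((draws <= observed).sum())
        p_emp = (1 + exceed) / (1 + n_perm)
    else:
        if null_mean is None or null_sd is None or n_perm is None:
            raise ValueError("need null_draws or (null_mean, null_sd, n_perm)")
        p_emp = np.nan
    if null_sd == 0:
        warnings.warn("null sd is 0; z reported as inf", stacklevel=2)
        z = math.inf if observed > null_mean else (-math.inf if observed < null_mean else 0.0)
    else:
        z = (observed - null_mean) / null_sd
    if null_mean == 0:
        warnings.warn("null mean is 0; fold undefined", stacklevel=2)
        fold = math.nan
    else:
        fold = observed / null_mean
    p_normal = float(stats.norm.sf(z) if alternative == "enrichment" else stats.norm.cdf(z))
    if np.isnan(p_emp):
        p_emp = max(p_normal, 1.0 / (1 + n_perm))
    return EnrichmentResult(
        observed=float(observed),
        null_mean=float(null_mean),
        null_sd=float(null_sd),
        n_perm=int(n_perm),
        z=float(z),
        p_empirical=float(p_emp),
        p_normal=p_normal,
        fold=float(fold),
        alternative=alternative,
    )


def permutation_enrichment(
    query: IntervalSet,
    subject: IntervalSet,
    genome: GenomeSpec | None = None,
    excluded: IntervalSet | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    null: Literal["shuffle", "resample"] = "shuffle",
    universe: IntervalSet | None = None,
    mode: Literal["subject", "pairs"] = "subject",
    same_chrom: bool = True,
    alternative: str = "enrichment",
) -> EnrichmentResult:
    """Permutation enrichment of ``query`` overlaps with ``subject``.

    ``null="shuffle"`` relocates the query uniformly across the genome
    (outside excluded regions); ``null="resample"`` draws |query| elements
    from ``universe`` without replacement.  The empirical p uses the
    add-one rule (1 + #{null >= observed}) / (1 + n_perm) for enrichment,
    mirrored for depletion, and can therefore never be 0.
    """
    rng = np.random.default_rng(seed)
    observed = count_overlaps(query, subject, mode=mode)
    draws = np.empty(n_perm, dtype=float)
    if null == "shuffle":
        if genome is None:
            raise ValueError("shuffle null requires a genome")
        for k in range(n_perm):
            perm = shuffle(query, genome, excluded=excluded,
                           same_chrom=same_chrom, rng=rng)
            draws[k] = count_overlaps(perm, subject, mode=mode)
    elif null == "resample":
        if universe is None:
            raise ValueError("resample null requires a universe")
        for k in range(n_perm):
            perm = resample_within_universe(query, universe, rng=rng)
            draws[k] = count_overlaps(perm, subject, mode=mode)
    else:
        raise ValueError(f"unknown null {null!r}")
    return enrichment_stats(observed, null_draws=draws, alternative=alternative)
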