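"""Simplified count-based differential testing.

A deliberately transparent stand-in for the DESeq2/edgeR/DiffBind stages of
a chromatin/expression differential workflow: median-of-ratios size
factors (with a trended loess alternative for skewed MA plots),
method-of-moments negative-binomial dispersion, a per-feature NB Wald test
with a log link and a two-level condition covariate, Benjamini-Hochberg
adjustment and up/down/nd status calls at p_adj < alpha.

No fold-change shrinkage, Cook's filtering or independent filtering is
performed, so numeric parity with DESeq2 is not claimed; recovery is
validated against planted truth instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_ND = "nd"


class NormalizationError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer feature-by-sample count matrix with a condition design.

    ``counts`` has feature ids as the row index and sample ids as columns;
    ``conditions`` maps each sample to "case" or "control" (at least two
    samples per condition).
    """

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.conditions):
            raise ValueError("sample ids in counts and conditions differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for cond in ("case", "control"):
            if sum(v == cond for v in self.conditions.values()) < 2:
                raise ValueError(f"need >= 2 samples in condition {cond!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=np.float64)

    def copy_with(self, counts: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(counts, dict(self.conditions))


@dataclass
class DifferentialResult:
    feature_id: str
    log2fc: float
    p_value: float
    mean_expression: float
    p_adj: float = np.nan
    status: str = STATUS_ND


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    factor_j = median over features positive in every sample of
    count_ij / geometric_mean_i(count_i.).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = mat.to_numpy(dtype=np.float64)
    pos = (x > 0).all(axis=1)
    if not pos.any():
        raise NormalizationError("no feature with positive counts in all samples")
    logx = np.log(x[pos])
    log_gm = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_gm, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def loess_offset_normalize(
    counts: CountMatrix | pd.DataFrame, span: float = 0.5
) -> pd.DataFrame:
    """Per-feature-per-sample log2 normalization offsets from an MA loess.

    For each sample, M = log2(count) - log2(reference) is regressed on
    A = (log2(count) + log2(reference)) / 2 against the geometric-mean
    reference pseudo-sample; the fitted trend is the offset, so
    offset-corrected log counts have a flat residual MA trend.  A pseudo
    count of 0.5 guards zeros.  Degenerate A ranges fall back to flat
    log2 size-factor offsets with a warning.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if len(mat) < 100:
        raise ValueError("need >= 100 features for a stable loess trend")
    logx = np.log2(mat.to_numpy(dtype=np.float64) + 0.5)
    ref = logx.mean(axis=1)
    offsets = np.empty_like(logx)
    for j in range(logx.shape[1]):
        m = logx[:, j] - ref
        a = (logx[:, j] + ref) / 2.0
        if np.ptp(a) < 1e-8:
            warnings.warn(
                "degenerate A range; falling back to size-factor offsets",
                stacklevel=2,
            )
            sf = size_factors(mat)
            return pd.DataFrame(
                np.tile(np.log2(sf.to_numpy()), (len(mat), 1)),
                index=mat.index,
                columns=mat.columns,
            )
        fitted = lowess(m, a, frac=span, return_sorted=False)
        offsets[:, j] = fitted
    return pd.DataFrame(offsets, index=mat.index, columns=mat.columns)


def estimate_dispersion(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    floor: float = 1e-8,
    shrink: float = 0.0,
) -> pd.Series:
    """Per-feature NB dispersion alpha (variance = mu + alpha * mu^2).

    Method of moments on size-factor-normalized counts, pooled across the
    two conditions with degrees-of-freedom weights and floored at
    ``floor``.  ``shrink`` in [0, 1] optionally pulls each estimate toward
    the across-feature mean dispersion, trading variance for bias when
    replicate numbers are small.
    """
    if factors is None:
        factors = size_factors(counts)
    x = counts.values() / factors.reindex(counts.sample_ids).to_numpy()
    num = np.zeros(x.shape[0])
    den = 0.0
    for cond in ("case", "control"):
        cols = [counts.sample_ids.index(s) for s in counts.samples_of(cond)]
        sub = x[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        w = len(cols) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - mu) / np.where(mu > 0, mu, 1.0) ** 2, 0.0)
        num += w * a
        den += w
    alpha = np.maximum(num / den, floor)
    if shrink > 0:
        alpha = np.maximum((1 - shrink) * alpha + shrink * alpha.mean(), floor)
    return pd.Series(alpha, index=counts.feature_ids, name="dispersion")


def _fit_group_rate(
    y: np.ndarray, norm: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """Vectorized per-feature MLE of the NB rate q with mu_ij = norm_ij * q.

    Solves sum_j (y_ij - norm_ij q) / (1 + alpha_i norm_ij q) = 0 by Newton
    iteration.  Features with an all-zero group get half a pseudo-count so
    the log fold change stays finite.
    """
    tot_norm = norm.sum(axis=1)
    q = y.sum(axis=1) / tot_norm
    zero = q <= 0
    q = np.where(zero, 0.5 / tot_norm, q)
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = norm * q[:, None]
        denom = 1.0 + a * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(norm * (1.0 + a * y) / denom**2).sum(axis=1)
        step = np.where(fp != 0, f / fp, 0.0)
        q_new = np.clip(q - step, 1e-12, None)
        if np.max(np.abs(q_new - q) / np.maximum(q, 1e-12)) < 1e-10:
            q = q_new
            break
        q = q_new
    return np.where(zero & (y.sum(axis=1) == 0), 0.5 / tot_norm, q)


def nb_wald_test(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    offsets: pd.DataFrame | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB log-link Wald test of case vs control.

    Normalization comes either from per-sample size ``factors`` or from a
    per-feature-per-sample log2 ``offsets`` matrix (loess).  The Wald
    statistic is beta_hat / se(beta_hat) with beta the log rate difference;
    p-values use the two-sided normal reference; log2fc = beta / ln 2.
    Features that are all-zero in both conditions are flagged with NaN
    p-values and excluded from later adjustment.
    """
    if offsets is not None:
        norm = np.power(2.0, offsets.to_numpy(dtype=np.float64))
    else:
        if factors is None:
            factors = size_factors(counts)
        norm = np.tile(
            factors.reindex(counts.sample_ids).to_numpy(), (len(counts.counts), 1)
        )
    if dispersions is None:
        dispersions = estimate_dispersion(counts, factors=factors)
    alpha = dispersions.reindex(counts.feature_ids).to_numpy()
    y = counts.values()

    cols = {c: [counts.sample_ids.index(s) for s in counts.samples_of(c)]
            for c in ("case", "control")}
    q = {}
    info = {}
    for cond, idx in cols.items():
        qc = _fit_group_rate(y[:, idx], norm[:, idx], alpha)
        mu = norm[:, idx] * qc[:, None]
        info[cond] = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
        q[cond] = qc

    beta = np.log(q["case"]) - np.log(q["control"])
    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / info["case"] + 1.0 / info["control"])
    wald = beta / se
    p = 2.0 * stats.norm.sf(np.abs(wald))

    all_zero = y.sum(axis=1) == 0
    p[all_zero] = np.nan
    beta[all_zero] = np.nan

    base_mean = (y / norm).mean(axis=1)
    return pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "baseMean": base_mean,
            "log2fc": beta / LN2,
            "se_log2fc": se / LN2,
            "stat": wald,
            "p": p,
        }
    ).set_index("feature_id", drop=False)


def classify(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust p-values and call up/down/nd status at p_adj < alpha.

    Features with NaN p (untestable) keep NaN p_adj, status nd, and do not
    count toward the BH m.
    """
    out = results.copy()
    if len(out) == 0:
        out["p_adj"] = pd.Series(dtype=float)
        out["status"] = pd.Series(dtype=object)
        return out
    tested = out["p"].notna()
    p_adj = np.full(len(out), np.nan)
    if tested.any():
        p_adj[tested.to_numpy()] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    out["p_adj"] = p_adj
    status = np.where(
        (out["p_adj"] < alpha) & (out["log2fc"] > 0),
        STATUS_UP,
        np.where((out["p_adj"] < alpha) & (out["log2fc"] < 0), STATUS_DOWN, STATUS_ND),
    )
    status[~tested.to_numpy()] = STATUS_ND
    out["status"] = status
    return out


def run_differential(
    counts: CountMatrix,
    alpha: float = 0.05,
    normalization: Literal["mor", "loess"] = "mor",
    dispersion_shrink: float = 0.75,
) -> pd.DataFrame:
    """Full pipeline: normalize, estimate dispersion, test, classify.

    Per-feature method-of-moments dispersions are noisy at typical
    replicate numbers and leave the Wald test anticonservative, so by
    default they are moderated by shrinking 75% of the way toward the
    across-feature mean (an edgeR-common-dispersion-flavoured compromise);
    set ``dispersion_shrink=0`` for raw per-feature estimates.
    """
    if normalization == "loess":
        offsets = loess_offset_normalize(counts)
        factors = size_factors(counts)
        disp = estimate_dispersion(counts, factors=factors, shrink=dispersion_shrink)
        res = nb_wald_test(counts, offsets=offsets, dispersions=disp)
    else:
        factors = size_factors(counts)
        disp = estimate_dispersion(counts, factors=factors, shrink=dispersion_shrink)
        res = nb_wald_test(counts, factors=factors, dispersions=disp)
    return classify(res, alpha=alpha)
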