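"""Peak-gene linking, expression normalization, correlations, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g4chromatin.integration import (
    CorrelationError,
    EstimationError,
    anova_interaction,
    build_trimodal,
    correlate_differentials,
    link_peaks_to_genes,
    normalize_expression,
    proximity_decay,
    simulate_trimodal,
    stratify_additive,
    zfpkm,
)
from g4chromatin.intervals import GeneModel, IntervalSet


def gene(gene_id, tss, strand="+", chrom="chr1"):
    # minimal two-exon gene with the requested TSS
    if strand == "+":
        exons = ((tss, tss + 500), (tss + 1000, tss + 1500))
    else:
        exons = ((tss - 1499, tss - 999), (tss - 499, tss + 1))
    return GeneModel(gene_id, chrom, strand, exons)


# ---------------------------------------------------------------------------
# linking


def test_link_distance_and_threshold():
    genes = [gene("g1", 5000)]
    peaks = IntervalSet.from_records(
        [("chr1", 4000, 4500),   # edge at 4499 -> distance 500... see below
         ("chr1", 1500, 2000),   # edge 1999 -> distance 3001, unlinked
         ("chr1", 4900, 5100)]   # covers TSS -> 0
    )
    links = {l.peak_index: l for l in link_peaks_to_genes(peaks, genes)}
    assert links[0].distance_bp == 501  # 5000 - 4499 (nearest covered base)
    assert 1 not in links
    assert links[2].distance_bp == 0


def test_link_exact_flank_boundary_excluded():
    genes = [gene("g1", 5000)]
    # nearest covered base at 2000 -> distance exactly 3000: not linked
    peaks = IntervalSet.from_records([("chr1", 1000, 2001)])
    assert link_peaks_to_genes(peaks, genes, flank=3000) == []
    peaks2 = IntervalSet.from_records([("chr1", 1000, 2002)])
    (l,) = link_peaks_to_genes(peaks2, genes, flank=3000)
    assert l.distance_bp == 2999


def test_link_nearest_tss_wins():
    genes = [gene("gA", 600), gene("gB", 900)]
    peaks = IntervalSet.from_records([("chr1", 0, 1)])
    (l,) = link_peaks_to_genes(peaks, genes)
    assert l.gene_id == "gA"


def test_link_stable_under_reordering(small_bundle):
    peaks = small_bundle.atac_peaks
    links1 = {
        peaks.df.loc[l.peak_index, "name"]: l.gene_id
        for l in link_peaks_to_genes(peaks, small_bundle.genes)
    }
    perm = np.random.default_rng(0).permutation(len(peaks))
    shuffled = peaks.subset(perm)
    links2 = {
        shuffled.df.loc[l.peak_index, "name"]: l.gene_id
        for l in link_peaks_to_genes(shuffled, small_bundle.genes)
    }
    assert links1 == links2
    for l in link_peaks_to_genes(peaks, small_bundle.genes):
        assert l.distance_bp < 3000


# ---------------------------------------------------------------------------
# expression normalization


def test_tpm_closed_form():
    out = normalize_expression([10, 90], [1000, 1000], ids=["a", "b"])
    assert out.loc["a", "tpm"] == pytest.approx(1e5)
    assert out.loc["b", "tpm"] == pytest.approx(9e5)


def test_rpkm_closed_form():
    counts = np.zeros(2)
    counts[0] = 10
    counts[1] = 1_000_000 - 10
    out = normalize_expression(counts, [1000, 100_000])
    assert out.iloc[0]["rpkm"] == pytest.approx(10.0)


def test_tpm_sums_to_a_million(rng):
    counts = rng.poisson(100, size=500)
    lengths = rng.integers(200, 10_000, size=500)
    out = normalize_expression(counts, lengths)
    assert out["tpm"].sum() == pytest.approx(1e6)


def test_zero_length_raises():
    with pytest.raises(ValueError):
        normalize_expression([1, 2], [1000, 0])


# ---------------------------------------------------------------------------
# zFPKM


def test_zfpkm_recovers_normal_parameters():
    rng = np.random.default_rng(21)
    fit = zfpkm(rng.normal(5.0, 2.0, size=10_000))
    assert 4.8 <= fit.mu <= 5.2
    assert 1.8 <= fit.sigma <= 2.2


def test_zfpkm_threshold_behaviour():
    rng = np.random.default_rng(22)
    x = np.concatenate([rng.normal(5, 2, 5000), [5 - 4 * 2]])
    fit = zfpkm(x)
    assert not fit.active[-1]  # x = mu - 4 sigma is inactive


def test_zfpkm_errors():
    with pytest.raises(EstimationError):
        zfpkm(np.ones(100))  # constant
    with pytest.raises(EstimationError):
        zfpkm(np.random.default_rng(0).normal(size=20))  # too few


# ---------------------------------------------------------------------------
# correlation


def test_pearson_examples():
    assert correlate_differentials([1, 2, 3], [3, 5, 7])[0] == pytest.approx(1.0)
    assert correlate_differentials([1, 2, 3], [-1, -2, -3])[0] == pytest.approx(-1.0)
    r, _ = correlate_differentials([1, 2, 3, 4], [2, 1, 4, 3])
    assert r == pytest.approx(0.6)


def test_pearson_na_dropped_and_errors(rng):
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    y = np.array([2.0, 4.0, 9.0, 8.0, np.nan])
    r, _ = correlate_differentials(x, y)
    assert r == pytest.approx(1.0)
    with pytest.raises(CorrelationError):
        correlate_differentials([1, 2], [3, 4])
    with pytest.raises(CorrelationError):
        correlate_differentials([1, 1, 1], [1, 2, 3])


def test_pearson_matches_closed_form(rng):
    for _ in range(20):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r, _ = correlate_differentials(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# proximity decay


def test_proximity_rank_assignment_hand_layout():
    # G4 at [1000, 1200); ATAC peaks: two left, one overlapping, two right
    g4 = IntervalSet.from_records([("chr1", 1000, 1200)])
    atac = IntervalSet.from_records(
        [
            ("chr1", 0, 100),      # rank -2
            ("chr1", 500, 600),    # rank -1
            ("chr1", 1100, 1300),  # rank 0 (overlap)
            ("chr1", 2000, 2100),  # rank +1
            ("chr1", 5000, 5100),  # rank +2
        ]
    )
    res = proximity_decay(
        g4, np.array([1.0]), atac, np.array([10.0, 20.0, 30.0, 40.0, 50.0]),
        max_rank=2,
    )
    by = res.by_rank.set_index("offset")
    assert by.loc[0, "n"] == 1
    # n < 3 pairs -> NaN r but counts still recorded per offset
    assert by["n"].tolist() == [1, 1, 1, 1, 1]
    assert by["r"].isna().all()


def test_proximity_empty_atac_all_na():
    g4 = IntervalSet.from_records([("chr1", 0, 100)])
    atac = IntervalSet.from_records([("chr2", 0, 100)])
    res = proximity_decay(g4, np.array([1.0]), atac, np.array([1.0]))
    assert res.by_rank["r"].isna().all()


def test_proximity_local_coupling_decays(small_bundle):
    """Effects planted only at overlapping promoter peaks: r(0) >> r(+/-1)."""
    truth = small_bundle.truth
    res = proximity_decay(
        small_bundle.g4_peaks,
        truth.g4["log2fc"].to_numpy(),
        small_bundle.atac_peaks,
        truth.atac["log2fc"].to_numpy(),
        max_rank=2,
    )
    by = res.by_rank.set_index("offset")
    assert by.loc[0, "r"] > 0.5
    assert by.loc[0, "r"] > abs(by.loc[1, "r"]) + 0.3
    assert by.loc[0, "r"] > abs(by.loc[-1, "r"]) + 0.3


# ---------------------------------------------------------------------------
# stratification and ANOVA


def test_stratify_additive_both_changed_strongest():
    rng = np.random.default_rng(31)
    df = simulate_trimodal(6000, rng=rng, atac_effect=0.8, g4_effect=0.5)
    out = stratify_additive(df)
    med = out.set_index(["atac_status", "g4_status"])["median_rna_log2fc"]
    assert med.loc[("up", "up")] > med.loc[("up", "nd")] > med.loc[("nd", "nd")]
    assert abs(med.loc[("up", "up")] - 1.3) < 0.15


def test_stratify_all_nd_single_cell():
    df = pd.DataFrame(
        {"rna_log2fc": np.zeros(10), "atac_status": ["nd"] * 10,
         "g4_status": ["nd"] * 10}
    )
    out = stratify_additive(df)
    filled = out[out["n"] > 0]
    assert len(filled) == 1 and np.isnan(filled["p"].iloc[0])


def test_ranksum_identical_groups_p_one():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=40)
    df = pd.DataFrame(
        {
            "rna_log2fc": np.concatenate([vals, vals]),
            "atac_status": ["nd"] * 40 + ["up"] * 40,
            "g4_status": ["nd"] * 80,
        }
    )
    out = stratify_additive(df)
    p = out.query("atac_status == 'up' and g4_status == 'nd'")["p"].iloc[0]
    assert p > 0.99


def test_anova_typ3_matches_rss_oracle():
    """Type-III F equals a full-vs-reduced residual-sum-of-squares fit."""
    import statsmodels.formula.api as smf
    from patsy import dmatrices

    rng = np.random.default_rng(41)
    df = simulate_trimodal(400, rng=rng, interaction=0.4)
    table = anova_interaction(df)
    y, X = dmatrices(
        "rna_log2fc ~ C(atac_status, Sum) * C(g4_status, Sum)", df,
        return_type="dataframe",
    )
    info = X.design_info
    beta, rss_full, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(rss_full[0])
    n, p_full = X.shape
    for term, label in [
        ("C(atac_status, Sum)", "atac"),
        ("C(g4_status, Sum)", "g4"),
        ("C(atac_status, Sum):C(g4_status, Sum)", "atac:g4"),
    ]:
        sl = info.term_name_slices[term]
        keep = np.ones(p_full, dtype=bool)
        keep[sl] = False
        Xr = X.to_numpy()[:, keep]
        _, rss_red, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        df_term = sl.stop - sl.start
        f_oracle = ((float(rss_red[0]) - rss_full) / df_term) / (
            rss_full / (n - p_full)
        )
        assert table.loc[label, "F"] == pytest.approx(f_oracle, rel=1e-8)


def test_anova_null_interaction_p_uniformish():
    rng = np.random.default_rng(43)
    ps = [
        anova_interaction(simulate_trimodal(1500, rng=rng)).loc["atac:g4", "p"]
        for _ in range(60)
    ]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_anova_empty_cell_flagged():
    df = simulate_trimodal(300, rng=np.random.default_rng(44))
    df = df[~((df["atac_status"] == "up") & (df["g4_status"] == "down"))]
    table = anova_interaction(df)
    assert np.isnan(table.loc["atac:g4", "F"])


# ---------------------------------------------------------------------------
# trimodal assembly


def test_full_pipeline_recovers_planted_correlation():
    """Study with concordance_rho = 0.6: the estimated G4-RNA fold-change
    correlation matches the value the generative model implies.

    The implied value is computed from the truth table, not assumed: the
    planted cross-modality correlation over promoter-linked genes,
    attenuated by the sampling noise of each modality's fold-change
    estimate (errors-in-variables: lambda_m = sd_true /
    sqrt(var_true + mean se^2))."""
    from g4chromatin.cnv import assign_segments, scale_counts
    from g4chromatin.differential import run_differential
    from g4chromatin.simulate import SimConfig, generate_study

    cfg = SimConfig(seed=77, concordance_rho=0.6, n_replicates=6)
    bundle = generate_study(cfg)
    assignments = assign_segments(bundle.g4_peaks, bundle.cnv_segments)
    res = {
        "g4": run_differential(scale_counts(bundle.counts["g4"], assignments)),
        "rna": run_differential(bundle.counts["rna"]),
    }
    truth_g4 = bundle.truth.g4[bundle.truth.g4["promoter_gene"] != ""]
    merged = pd.DataFrame(
        {
            "gene_id": truth_g4["promoter_gene"].to_numpy(),
            "true_g4": truth_g4["log2fc"].to_numpy(),
            "est_g4": res["g4"].loc[truth_g4["name"], "log2fc"].to_numpy(),
            "se_g4": res["g4"].loc[truth_g4["name"], "se_log2fc"].to_numpy(),
        }
    ).merge(
        pd.DataFrame(
            {
                "gene_id": bundle.truth.genes["gene_id"],
                "true_rna": bundle.truth.genes["log2fc"],
                "est_rna": res["rna"]["log2fc"].to_numpy(),
                "se_rna": res["rna"]["se_log2fc"].to_numpy(),
            }
        ),
        on="gene_id",
    ).dropna()
    r_est, _ = correlate_differentials(merged["est_g4"], merged["est_rna"])
    r_true = np.corrcoef(merged["true_g4"], merged["true_rna"])[0, 1]
    lam = 1.0
    for col, se_col in (("true_g4", "se_g4"), ("true_rna", "se_rna")):
        var_true = merged[col].var()
        lam *= np.sqrt(var_true / (var_true + (merged[se_col] ** 2).mean()))
    assert abs(r_est - r_true * lam) <= 0.1


def test_build_trimodal_joins_three_tables():
    rna = pd.DataFrame(
        {"feature_id": ["g1", "g2"], "log2fc": [1.0, -1.0],
         "status": ["up", "down"]}
    ).set_index("feature_id", drop=False)
    atac = pd.DataFrame(
        {"feature_id": ["a1", "a2"], "log2fc": [0.5, 0.2],
         "status": ["up", "nd"]}
    ).set_index("feature_id", drop=False)
    g4 = pd.DataFrame(
        {"feature_id": ["q1"], "log2fc": [0.8], "status": ["up"]}
    ).set_index("feature_id", drop=False)
    tm = build_trimodal(rna, atac, g4, {"a1": "g1", "a2": "g2"}, {"q1": "g1"})
    assert len(tm) == 1
    row = tm.iloc[0]
    assert row["gene_id"] == "g1" and row["atac_status"] == "up"
    assert row["g4_log2fc"] == 0.8 and row["rna_log2fc"] == 1.0
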