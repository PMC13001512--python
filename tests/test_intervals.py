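"""Interval engine: joins, nearest search, shuffles, windows, annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from g4chromatin.intervals import (
    FEATURE_PRECEDENCE,
    GeneModel,
    GenomeSpec,
    GenomicInterval,
    IntervalSet,
    PlacementError,
    ValidationError,
    annotate_features,
    closest,
    merge_intervals,
    overlap_join,
    peak_density,
    promoter_windows,
    resample_within_universe,
    shuffle,
)

from conftest import random_interval_set


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_overlap_join(a, b, min_overlap=1):
    out = []
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            if ai.chrom != bj.chrom:
                continue
            ov = min(ai.end, bj.end) - max(ai.start, bj.start)
            if ov >= min_overlap:
                out.append((i, j, ov))
    return sorted(out)


def brute_closest(query, subject):
    out = []
    for i, q in enumerate(query):
        best = None
        for j, s in enumerate(subject):
            if q.chrom != s.chrom:
                continue
            gap = max(s.start - q.end, q.start - s.end, 0)
            if best is None or gap < best[1] or (
                gap == best[1] and s.start < subject[best[0]].start
            ):
                best = (j, gap)
        if best is None:
            out.append((i, -1, float("inf")))
        else:
            out.append((i, best[0], float(best[1])))
    return out


def brute_density(x, flank):
    counts = []
    for i, a in enumerate(x):
        n = 0
        for j, b in enumerate(x):
            if i == j or a.chrom != b.chrom:
                continue
            if b.start < a.end + flank and b.end > a.start - flank:
                n += 1
        counts.append(n)
    return counts


# ---------------------------------------------------------------------------
# basic types


def test_interval_invariants():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 0, 5, strand="x")


def test_genome_spec_invariants():
    with pytest.raises(ValidationError):
        GenomeSpec(("chr1", "chr1"), (100, 100))
    with pytest.raises(ValidationError):
        GenomeSpec(("chr1",), (0,))
    bad_excl = IntervalSet.from_records([("chr1", 50, 200)])
    with pytest.raises(ValidationError):
        GenomeSpec(("chr1",), (100,), excluded=bad_excl)


def test_interval_set_rejects_out_of_bounds(toy_genome):
    with pytest.raises(ValidationError):
        IntervalSet.from_records([("chrX", 0, 10)], genome=toy_genome)
    with pytest.raises(ValidationError):
        IntervalSet.from_records([("chr2", 0, 600_000)], genome=toy_genome)


def test_sort_is_stable_and_normalized(rng):
    x = random_interval_set(rng, 50)
    s = x.sort()
    df = s.df
    key = list(zip(df["chrom"], df["start"], df["end"]))
    assert key == sorted(key)
    assert len(s) == len(x)


# ---------------------------------------------------------------------------
# overlap_join


def test_overlap_join_examples():
    a = IntervalSet.from_records([("chr1", 0, 200)])
    b = IntervalSet.from_records([("chr1", 100, 400)])
    assert overlap_join(a, b, min_overlap=1) == [(0, 0, 100)]
    # the "larger than 150 bp" rule: a 100-bp overlap fails min_overlap=151
    assert overlap_join(a, b, min_overlap=151) == []
    b2 = IntervalSet.from_records([("chr1", 40, 400)])
    assert overlap_join(a, b2, min_overlap=151) == [(0, 0, 160)]


def test_overlap_join_symmetry(rng):
    a = random_interval_set(rng, 60)
    b = random_interval_set(rng, 60)
    ab = {(i, j, ov) for i, j, ov in overlap_join(a, b)}
    ba = {(j, i, ov) for i, j, ov in overlap_join(b, a)}
    assert ab == ba


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_overlap_join_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    a = random_interval_set(rng, int(rng.integers(1, 60)))
    b = random_interval_set(rng, int(rng.integers(1, 60)))
    mo = int(rng.integers(1, 500))
    assert overlap_join(a, b, min_overlap=mo) == brute_overlap_join(a, b, mo)


# ---------------------------------------------------------------------------
# closest


def test_closest_examples():
    q = IntervalSet.from_records([("chr1", 500, 600)])
    s = IntervalSet.from_records([("chr1", 0, 100), ("chr1", 700, 800)])
    assert closest(q, s) == [(0, 1, 100.0)]
    q2 = IntervalSet.from_records([("chr1", 50, 90)])
    assert closest(q2, s) == [(0, 0, 0.0)]
    q3 = IntervalSet.from_records([("chrZ", 0, 10)])
    (qi, si, d) = closest(q3, s)[0]
    assert si == -1 and np.isinf(d)


def test_closest_tie_breaks_to_lower_start():
    q = IntervalSet.from_records([("chr1", 500, 600)])
    s = IntervalSet.from_records([("chr1", 700, 800), ("chr1", 300, 400)])
    # both at distance 100; the lower-start subject wins
    assert closest(q, s) == [(0, 1, 100.0)]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_closest_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    q = random_interval_set(rng, int(rng.integers(1, 50)))
    s = random_interval_set(rng, int(rng.integers(1, 50)))
    assert closest(q, s) == brute_closest(q, s)


# ---------------------------------------------------------------------------
# shuffle


def test_shuffle_preserves_lengths_and_is_seeded(toy_genome, rng):
    x = random_interval_set(rng, 40, size=400_000)
    s1 = shuffle(x, toy_genome, rng=1)
    s2 = shuffle(x, toy_genome, rng=1)
    assert s1 == s2
    assert sorted(s1.lengths()) == sorted(x.lengths())
    assert list(s1.df["chrom"]) == list(x.df["chrom"])  # same_chrom default


def test_shuffle_avoids_excluded(toy_genome, rng):
    excl = IntervalSet.from_records([("chr1", 0, 900_000)])
    x = IntervalSet.from_records([("chr1", 0, 1000)] * 30)
    s = shuffle(x, toy_genome, excluded=excl, rng=rng)
    assert (s.df["start"] >= 900_000).all()


def test_shuffle_cross_chromosome_mode(toy_genome, rng):
    x = IntervalSet.from_records([("chr1", 0, 1000)] * 200)
    s = shuffle(x, toy_genome, same_chrom=False, rng=rng)
    assert set(s.df["chrom"]) == {"chr1", "chr2"}


def test_shuffle_impossible_interval_raises(toy_genome):
    x = IntervalSet.from_records([("chr1", 0, 1_000_000)])
    small = GenomeSpec(("chr1",), (500,))
    with pytest.raises(PlacementError):
        shuffle(x, small, rng=0)


def test_shuffle_start_is_uniform():
    """10^4 single-interval shuffles on an empty genome: KS vs uniform."""
    genome = GenomeSpec(("chr1",), (1_000_000,))
    x = IntervalSet.from_records([("chr1", 0, 100)])
    gen = np.random.default_rng(7)
    starts = np.array(
        [shuffle(x, genome, rng=gen).df["start"].iloc[0] for _ in range(10_000)]
    )
    ks = stats.kstest(starts / (1_000_000 - 100), "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# resample_within_universe


def test_resample_full_universe_is_permutation(rng):
    u = random_interval_set(rng, 10)
    r = resample_within_universe(u, u, rng=rng)
    assert sorted(map(tuple, r.df[["chrom", "start", "end"]].to_numpy())) == sorted(
        map(tuple, u.df[["chrom", "start", "end"]].to_numpy())
    )


def test_resample_too_large_query_raises(rng):
    u = random_interval_set(rng, 5)
    q = random_interval_set(rng, 6)
    with pytest.raises(ValidationError):
        resample_within_universe(q, u, rng=rng)


def test_resample_selection_frequencies(rng):
    u = random_interval_set(rng, 10)
    q = u.subset([0, 1, 2])
    from collections import Counter

    gen = np.random.default_rng(5)
    n_rep = 10_000
    tally: Counter = Counter()
    for _ in range(n_rep):
        tally.update(resample_within_universe(q, u, rng=gen).df["name"])
    freq = np.array([tally[f"iv_{k}"] for k in range(10)]) / n_rep
    assert np.all(np.abs(freq - 0.3) < 0.02)


# ---------------------------------------------------------------------------
# promoter windows, gene anatomy


def _gene(strand, exons, gene_id="g1", chrom="chr1", cds=None):
    return GeneModel(gene_id, chrom, strand, tuple(exons), cds=cds)


def test_tss_strand_convention():
    plus = _gene("+", [(10_000, 12_000), (15_000, 20_000)])
    minus = _gene("-", [(10_000, 12_000), (15_000, 20_000)])
    assert plus.tss == 10_000
    assert minus.tss == 19_999  # last covered base, 0-based


def test_promoter_windows_clipping(toy_genome):
    g1 = _gene("+", [(5_000, 6_000), (7_000, 9_000)])
    g2 = _gene("+", [(1_000, 1_500), (2_000, 3_000)], gene_id="g2")
    wins = promoter_windows([g1, g2], flank=3000, genome=toy_genome)
    assert (wins.df.loc[0, "start"], wins.df.loc[0, "end"]) == (2_000, 8_000)
    assert (wins.df.loc[1, "start"], wins.df.loc[1, "end"]) == (0, 4_000)


def test_promoter_window_minus_strand_centered_on_3prime_end():
    g = _gene("-", [(10_000, 12_000), (15_000, 20_000)])
    wins = promoter_windows([g], flank=3000)
    assert (wins.df.loc[0, "start"], wins.df.loc[0, "end"]) == (16_999, 22_999)


# ---------------------------------------------------------------------------
# annotate_features


@pytest.fixture()
def annot_gene():
    # + strand: exon1 [10000,11000), intron1 [11000,13000), exon2 [13000,14000)
    # CDS [10500, 13500) -> 5'UTR [10000,10500), 3'UTR [13500,14000)
    return _gene(
        "+", [(10_000, 11_000), (13_000, 14_000)], cds=(10_500, 13_500)
    )


def test_annotate_tss_cover_is_promoter(annot_gene):
    x = IntervalSet.from_records([("chr1", 9_900, 10_100)])
    labels = annotate_features(x, [annot_gene])
    assert labels[0].category == "promoter/TSS"
    assert labels[0].gene_id == "g1"


def test_annotate_first_intron_away_from_junction(annot_gene):
    # promoter window reaches 13000; pick intron point beyond it
    g = _gene("+", [(10_000, 11_000), (20_000, 21_000)], cds=(10_500, 20_500))
    x = IntervalSet.from_records([("chr1", 15_000, 15_200)])
    assert annotate_features(x, [g])[0].category == "first intron"


def test_annotate_junction_beats_first_exon_and_intron():
    g = _gene("+", [(10_000, 16_000), (20_000, 30_000)], cds=(10_500, 29_000))
    x = IntervalSet.from_records([("chr1", 15_900, 16_100)])  # covers 16000
    assert annotate_features(x, [g])[0].category == "1st-Ex-Int junction"


def test_annotate_minus_strand_junction_is_last_exon_start():
    g = _gene("-", [(10_000, 11_000), (20_000, 30_000)], cds=(10_500, 29_000))
    # first exon in transcription order is [20000,30000); junction at 20000
    x = IntervalSet.from_records([("chr1", 19_950, 20_050)])
    assert annotate_features(x, [g])[0].category == "1st-Ex-Int junction"


def test_annotate_intergenic(annot_gene):
    x = IntervalSet.from_records([("chr1", 500_000, 500_100)])
    lab = annotate_features(x, [annot_gene])[0]
    assert lab.category == "intergenic" and lab.gene_id is None


def test_annotate_is_total(rng, small_bundle):
    labels = annotate_features(small_bundle.g4_peaks, small_bundle.genes)
    assert len(labels) == len(small_bundle.g4_peaks)
    assert all(lab.category in FEATURE_PRECEDENCE for lab in labels)


# ---------------------------------------------------------------------------
# peak_density


def test_peak_density_examples():
    lone = IntervalSet.from_records([("chr1", 100, 200)])
    assert peak_density(lone).tolist() == [0]
    pair = IntervalSet.from_records([("chr1", 0, 1000), ("chr1", 6_000, 7_000)])
    assert peak_density(pair, flank=10_000).tolist() == [1, 1]
    assert peak_density(pair, flank=1_000).tolist() == [0, 0]


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_peak_density_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    x = random_interval_set(rng, int(rng.integers(2, 60)), size=30_000)
    flank = int(rng.integers(100, 10_000))
    assert peak_density(x, flank=flank).tolist() == brute_density(x, flank)


def test_merge_intervals():
    ms, me = merge_intervals(
        np.array([10, 0, 5, 100]), np.array([20, 6, 12, 150])
    )
    assert ms.tolist() == [0, 100] and me.tolist() == [20, 150]
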