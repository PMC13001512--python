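"""Synthetic two-condition study generator with planted ground truth.

Emulates the interval/count structure of an integrative G4
ChIP-seq + ATAC-seq + RNA-seq case/control study: a small multi-chromosome
genome with excluded (gap/blacklist-like) regions, non-overlapping gene
models, open-chromatin and G4 peak sets with a planted promoter enrichment,
strand-resolved in-vitro G4 hits around the G4 peaks, copy-number segments
tiling the genome, and negative-binomial count matrices per modality with
planted, cross-modality-correlated differential effects.

Every planted quantity (per-feature log2 fold changes and statuses, true G4
strands, per-peak copy-number ratios, the promoter-enrichment fold) is
recorded in a :class:`GroundTruth` so downstream stages can be validated by
recovery rather than by fiat.

Randomness: one top-level seed; each generator consumes an independent
child stream derived from it via ``SeedSequence`` spawn keys, so adding a
generator does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .cnv import CnvSegment, read_segments, write_segments
from .differential import CountMatrix
from .intervals import (
    GeneModel,
    GenomeSpec,
    GenomicInterval,
    IntervalSet,
    PlacementError,
    ValidationError,
    _overlaps_any,
    merge_intervals,
    promoter_windows,
)
from . import io as gio


class ConfigurationError(ValueError):
    pass


class CapacityError(RuntimeError):
    pass


#: fixed spawn keys per random stream; append-only so existing streams are
#: stable when new generators are added
_STREAMS = {
    "genome": 0,
    "genes": 1,
    "intervals": 2,
    "cnv": 3,
    "truth": 4,
    "counts_atac": 5,
    "counts_g4": 6,
    "counts_rna": 7,
    "p0": 8,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a desk-scale study: a 4 x 25 Mb genome, 1000 genes,
    5000 open-chromatin peaks and 1200 G4 peaks of which 80% sit in
    promoters (TSS +/- 3 kb), ~30%/20%/30% planted differential fractions
    for ATAC/G4/RNA, log2 effects of magnitude N(1.0, 0.5) with
    cross-modality correlation 0.7, NB dispersion 0.05, and a 10% amplified
    (log2 ratio 1) plus 5% deleted (log2 ratio -1) copy-number landscape.
    """

    seed: int = 0
    n_chrom: int = 4
    chrom_size_bp: int = 25_000_000
    excluded_frac: float = 0.02
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    max_exons: int = 5
    n_atac_peaks: int = 5000
    n_g4_peaks: int = 1200
    frac_g4_in_promoter: float = 0.8
    g4_promoter_fold: float | None = None  # overrides frac when set
    atac_promoter_frac: float = 0.9
    promoter_flank: int = 3000
    atac_width_promoter: int = 988  # median widths of G4+/G4- open regions
    atac_width_background: int = 347
    g4_width: int = 300
    g4seq_hit_coverage: float = 0.8
    g4seq_hit_width: int = 100
    n_background_hits: int = 1000
    strand_frac_watson: float = 0.5
    frac_differential: dict[str, float] = field(
        default_factory=lambda: {"atac": 0.3, "g4": 0.2, "rna": 0.3}
    )
    planted_log2fc_mean: float = 1.0
    planted_log2fc_sd: float = 0.5
    concordance_rho: float = 0.7
    nb_dispersion: float = 0.05
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    library_size_range: tuple[float, float] = (0.7, 1.3)
    n_replicates: int = 4
    cnv: tuple[tuple[float, float], ...] = ((0.10, 1.0), (0.05, -1.0))

    def __post_init__(self) -> None:
        fracs = [
            self.excluded_frac,
            self.frac_g4_in_promoter,
            self.atac_promoter_frac,
            self.g4seq_hit_coverage,
            self.strand_frac_watson,
            *self.frac_differential.values(),
            *(f for f, _ in self.cnv),
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ConfigurationError("all fractions must lie in [0, 1]")
        if sum(f for f, _ in self.cnv) > 1.0:
            raise ConfigurationError("CNV segment fractions must sum to <= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not (-1.0 <= self.concordance_rho <= 1.0):
            raise ConfigurationError("concordance_rho must lie in [-1, 1]")
        if set(self.frac_differential) != {"atac", "g4", "rna"}:
            raise ConfigurationError(
                "frac_differential needs the atac, g4 and rna modalities"
            )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """All planted parameters: one row per simulated feature.

    ``genes``: gene_id, log2fc, status, regulated.
    ``atac`` / ``g4``: name, log2fc, status, cnr, promoter_gene (gene id or
    "" for background peaks); ``g4`` additionally carries the true strand.
    """

    genes: pd.DataFrame
    atac: pd.DataFrame
    g4: pd.DataFrame
    promoter_enrichment_fold: float
    promoter_background_rate: float


@dataclass
class StudyBundle:
    genome: GenomeSpec
    genes: list[GeneModel]
    atac_peaks: IntervalSet
    g4_peaks: IntervalSet
    g4seq_hits: IntervalSet
    cnv_segments: list[CnvSegment]
    counts: dict[str, CountMatrix]
    truth: GroundTruth
    config: SimConfig

    def validate(self) -> None:
        sizes = self.genome.sizes
        for name, xs in (
            ("atac", self.atac_peaks),
            ("g4", self.g4_peaks),
            ("hits", self.g4seq_hits),
        ):
            for iv in xs:
                if iv.chrom not in sizes or iv.end > sizes[iv.chrom]:
                    raise ValidationError(f"{name} interval out of bounds: {iv}")
        for modality, truth_df, n_feat in (
            ("atac", self.truth.atac, len(self.atac_peaks)),
            ("g4", self.truth.g4, len(self.g4_peaks)),
            ("rna", self.truth.genes, len(self.genes)),
        ):
            cm = self.counts[modality]
            if len(cm.counts) != n_feat or len(truth_df) != n_feat:
                raise ValidationError(f"{modality}: counts/truth/feature mismatch")
            bad = truth_df[
                ((truth_df["log2fc"] > 0) & (truth_df["status"] == "down"))
                | ((truth_df["log2fc"] < 0) & (truth_df["status"] == "up"))
            ]
            if len(bad):
                raise ValidationError(f"{modality}: status inconsistent with log2fc")


# ---------------------------------------------------------------------------
# component generators


def generate_genome(config: SimConfig) -> GenomeSpec:
    """Chromosomes chr1..chrN of equal size with sparse excluded regions."""
    if config.n_chrom < 1 or config.chrom_size_bp < 100_000:
        raise ConfigurationError("need n_chrom >= 1 and chrom_size_bp >= 1e5")
    if config.excluded_frac >= 0.10:
        raise ConfigurationError("excluded_frac must stay below 10%")
    rng = child_rng(config.seed, "genome")
    names = tuple(f"chr{i + 1}" for i in range(config.n_chrom))
    sizes = tuple(config.chrom_size_bp for _ in names)
    rows = []
    if config.excluded_frac > 0:
        per_block = 50_000
        for name in names:
            total = int(config.excluded_frac * config.chrom_size_bp)
            n_blocks = max(1, total // per_block)
            width = total // n_blocks
            starts: list[int] = []
            for _ in range(n_blocks):
                for _ in range(1000):
                    s = int(rng.integers(0, config.chrom_size_bp - width))
                    if all(abs(s - t) > 2 * width for t in starts):
                        starts.append(s)
                        break
            for s in starts:
                rows.append((name, s, s + width))
    excluded = (
        IntervalSet.from_records(rows) if rows else IntervalSet.empty()
    )
    return GenomeSpec(names, sizes, excluded=excluded)


def _excluded_arrays(genome: GenomeSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {c: genome.excluded_on(c) for c in genome.chrom_names}


def generate_genes(genome: GenomeSpec, config: SimConfig) -> list[GeneModel]:
    """Place non-overlapping multi-exon genes, ~50% per strand.

    Spans are rejection-sampled against previously placed genes and the
    excluded regions, capped at 10^4 attempts per gene.
    """
    rng = child_rng(config.seed, "genes")
    excl = _excluded_arrays(genome)
    placed: dict[str, tuple[list[int], list[int]]] = {
        c: ([], []) for c in genome.chrom_names
    }
    genes: list[GeneModel] = []
    names = list(genome.chrom_names)
    sizes = genome.sizes
    lo, hi = config.gene_length_range
    for gi in range(config.n_genes):
        chrom = names[gi % len(names)]
        length = int(rng.integers(lo, hi + 1))
        ms, me = excl[chrom]
        ps, pe = placed[chrom]
        start = None
        for _ in range(10_000):
            cand = int(rng.integers(0, sizes[chrom] - length))
            if _overlaps_any(cand, cand + length, ms, me):
                continue
            if any(cand < e and cand + length > s for s, e in zip(ps, pe)):
                continue
            start = cand
            break
        if start is None:
            raise CapacityError(
                f"could not place gene {gi} after 10000 attempts; "
                "genome too small for n_genes"
            )
        ps.append(start)
        pe.append(start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, config.max_exons + 1))
        # 2*(n_exons-1) interior cuts -> alternating exon/intron pieces
        cuts = np.sort(
            rng.choice(
                np.arange(start + 1, start + length), size=2 * (n_exons - 1),
                replace=False,
            )
        )
        bounds = [start, *cuts.tolist(), start + length]
        exons = tuple(
            (bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)
        )
        first_s, first_e = exons[0]
        last_s, last_e = exons[-1]
        cds = ((first_s + first_e) // 2, (last_s + last_e) // 2 + 1)
        genes.append(
            GeneModel(f"gene_{gi:05d}", chrom, strand, exons, cds=cds)
        )
    return genes


@dataclass
class IntervalData:
    """The three generated interval sets plus placement bookkeeping."""

    atac_peaks: IntervalSet
    g4_peaks: IntervalSet
    g4seq_hits: IntervalSet
    atac_promoter_gene: list[str]  # "" for background peaks
    g4_promoter_gene: list[str]
    g4_true_strand: list[str]
    promoter_background_rate: float
    promoter_fraction_used: float

    def __iter__(self) -> Iterator[IntervalSet]:
        return iter((self.atac_peaks, self.g4_peaks, self.g4seq_hits))


def _union_length(ms: np.ndarray, me: np.ndarray) -> int:
    return int((me - ms).sum())


def _intersect_unions(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> int:
    """Total length of the intersection of two merged interval unions."""
    total = 0
    i = j = 0
    as_, ae = a
    bs, be = b
    while i < len(as_) and j < len(bs):
        lo = max(as_[i], bs[j])
        hi = min(ae[i], be[j])
        if lo < hi:
            total += hi - lo
        if ae[i] <= be[j]:
            i += 1
        else:
            j += 1
    return int(total)


def _start_union(
    ms: np.ndarray, me: np.ndarray, width: int, lo: int, hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """Merged union of start positions s in [lo, hi) whose interval
    [s, s + width) intersects the given merged union."""
    if len(ms) == 0:
        return ms, me
    starts = np.maximum(ms - width + 1, lo)
    ends = np.minimum(me, hi)
    keep = starts < ends
    return merge_intervals(starts[keep], ends[keep])


def exact_hit_rate(
    genome: GenomeSpec,
    windows: IntervalSet,
    width: int,
) -> float:
    """Exact probability that an interval of ``width``, placed uniformly
    outside excluded regions on a uniformly chosen chromosome, overlaps a
    window.  Computed by interval arithmetic over legal start positions."""
    merged = {
        c: merge_intervals(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
        for c, sub in windows.df.groupby("chrom")
    }
    rates = []
    for chrom, size in zip(genome.chrom_names, genome.chrom_sizes):
        n_starts = size - width + 1
        if n_starts <= 0:
            rates.append(0.0)
            continue
        es, ee = genome.excluded_on(chrom)
        bad = _start_union(es, ee, width, 0, n_starts)
        n_allowed = n_starts - _union_length(*bad)
        ws, we = merged.get(chrom, (np.empty(0, np.int64),) * 2)
        hit = _start_union(ws, we, width, 0, n_starts)
        n_hit = _union_length(*hit) - _intersect_unions(hit, bad)
        rates.append(n_hit / n_allowed if n_allowed > 0 else 0.0)
    return float(np.mean(rates))


def estimate_promoter_hit_rate(
    genome: GenomeSpec,
    genes: Sequence[GeneModel],
    width_median: int,
    flank: int,
    rng: np.random.Generator,
    n_width_draws: int = 300,
) -> float:
    """Background rate at which a random peak overlaps a promoter window.

    Exact placement probability (no Monte-Carlo placement noise) averaged
    over the peak-width distribution via ``n_width_draws`` sampled widths.
    """
    from collections import Counter

    windows = promoter_windows(genes, flank=flank, genome=genome)
    widths = Counter(_peak_width(rng, width_median) for _ in range(n_width_draws))
    rate = 0.0
    for w, mult in widths.items():
        rate += mult * exact_hit_rate(genome, windows, w)
    return rate / n_width_draws


def _reject_sample_start(
    rng: np.random.Generator, width: int, size: int, ms: np.ndarray, me: np.ndarray
) -> int:
    for _ in range(10_000):
        s = int(rng.integers(0, size - width + 1))
        if not _overlaps_any(s, s + width, ms, me):
            return s
    raise PlacementError(f"no legal placement for width {width}")


def _peak_width(rng: np.random.Generator, median: int) -> int:
    """Log-normal width with the requested median, floored at 50 bp."""
    return max(50, int(round(median * np.exp(rng.normal(0.0, 0.35)))))


def generate_interval_data(
    genome: GenomeSpec, genes: Sequence[GeneModel], config: SimConfig
) -> IntervalData:
    """ATAC peaks, G4 peaks and strand-resolved G4-seq hits.

    A configurable fraction of G4 peaks is placed covering gene TSSs (the
    planted promoter enrichment); likewise most genes receive an
    open-chromatin peak over their TSS so that promoter-linked G4 and ATAC
    peaks overlap.  Background peaks go uniformly outside excluded
    regions.  Each G4 peak carries a true strand; in-vitro hits are placed
    on that strand inside a ``g4seq_hit_coverage`` fraction of peaks, plus
    uniform background hits with random strands.

    When ``config.g4_promoter_fold`` is set, the promoter fraction is
    derived so the expected promoter-overlap fold over the uniform
    background equals that fold.
    """
    rng = child_rng(config.seed, "intervals")
    p0 = estimate_promoter_hit_rate(
        genome, genes, config.g4_width, config.promoter_flank,
        child_rng(config.seed, "p0"),
    )
    if config.g4_promoter_fold is not None:
        fold = config.g4_promoter_fold
        frac = p0 * (fold - 1.0) / (1.0 - p0)
        if not (0.0 <= frac <= 1.0):
            raise ConfigurationError(
                f"g4_promoter_fold={fold} not plantable "
                f"(background promoter rate {p0:.3f})"
            )
    else:
        frac = config.frac_g4_in_promoter
    excl = _excluded_arrays(genome)
    sizes = genome.sizes
    names = list(genome.chrom_names)

    def cover_tss(g: GeneModel, width: int) -> tuple[str, int, int]:
        lo = max(g.tss - width + 1, 0)
        hi = min(g.tss, sizes[g.chrom] - width)
        if hi < lo:
            lo = hi = max(min(g.tss, sizes[g.chrom] - width), 0)
        start = int(rng.integers(lo, hi + 1))
        return g.chrom, start, start + width

    # --- ATAC peaks ------------------------------------------------------
    atac_rows: list[tuple] = []
    atac_gene: list[str] = []
    promoter_gene_idx = [
        i for i in range(len(genes)) if rng.random() < config.atac_promoter_frac
    ]
    if len(promoter_gene_idx) > config.n_atac_peaks:
        raise CapacityError("n_atac_peaks too small for atac_promoter_frac")
    for i in promoter_gene_idx:
        w = _peak_width(rng, config.atac_width_promoter)
        chrom, s, e = cover_tss(genes[i], w)
        atac_rows.append((chrom, s, e, f"atac_{len(atac_rows):05d}"))
        atac_gene.append(genes[i].gene_id)
    while len(atac_rows) < config.n_atac_peaks:
        w = _peak_width(rng, config.atac_width_background)
        chrom = names[int(rng.integers(0, len(names)))]
        s = _reject_sample_start(rng, w, sizes[chrom], *excl[chrom])
        atac_rows.append((chrom, s, s + w, f"atac_{len(atac_rows):05d}"))
        atac_gene.append("")

    # --- G4 peaks --------------------------------------------------------
    n_prom = int(round(frac * config.n_g4_peaks))
    if n_prom > len(genes):
        raise CapacityError(
            f"{n_prom} promoter G4 peaks requested but only {len(genes)} genes"
        )
    g4_rows: list[tuple] = []
    g4_gene: list[str] = []
    chosen = rng.choice(len(genes), size=n_prom, replace=False)
    for i in chosen:
        w = _peak_width(rng, config.g4_width)
        chrom, s, e = cover_tss(genes[i], w)
        g4_rows.append((chrom, s, e, f"g4_{len(g4_rows):05d}"))
        g4_gene.append(genes[i].gene_id)
    while len(g4_rows) < config.n_g4_peaks:
        w = _peak_width(rng, config.g4_width)
        chrom = names[int(rng.integers(0, len(names)))]
        s = _reject_sample_start(rng, w, sizes[chrom], *excl[chrom])
        g4_rows.append((chrom, s, s + w, f"g4_{len(g4_rows):05d}"))
        g4_gene.append("")
    g4_strand = [
        "+" if rng.random() < config.strand_frac_watson else "-"
        for _ in range(len(g4_rows))
    ]

    # --- G4-seq hits -----------------------------------------------------
    hit_rows: list[tuple] = []
    for (chrom, s, e, _), strand in zip(g4_rows, g4_strand):
        if rng.random() >= config.g4seq_hit_coverage:
            continue
        w = min(config.g4seq_hit_width, e - s)
        lo, hi = s, e - w
        hs = int(rng.integers(lo, hi + 1))
        hit_rows.append(
            (chrom, hs, hs + w, f"hit_{len(hit_rows):05d}", np.nan, strand)
        )
    for _ in range(config.n_background_hits):
        chrom = names[int(rng.integers(0, len(names)))]
        w = config.g4seq_hit_width
        s = _reject_sample_start(rng, w, sizes[chrom], *excl[chrom])
        strand = "+" if rng.random() < 0.5 else "-"
        hit_rows.append(
            (chrom, s, s + w, f"hit_{len(hit_rows):05d}", np.nan, strand)
        )

    def as_set(rows: list[tuple]) -> IntervalSet:
        if rows and len(rows[0]) == 4:
            rows = [r + (np.nan, ".") for r in rows]
        df = pd.DataFrame(rows, columns=list(IntervalSet.COLUMNS))
        return IntervalSet(df, genome=genome)

    realized_fold = (frac + (1.0 - frac) * p0) / p0 if p0 > 0 else np.nan
    return IntervalData(
        atac_peaks=as_set(atac_rows),
        g4_peaks=as_set(g4_rows),
        g4seq_hits=as_set(hit_rows),
        atac_promoter_gene=atac_gene,
        g4_promoter_gene=g4_gene,
        g4_true_strand=g4_strand,
        promoter_background_rate=p0,
        promoter_fraction_used=frac,
    )


def generate_cnv_segments(
    genome: GenomeSpec, config: SimConfig
) -> list[CnvSegment]:
    """Segments tiling every chromosome; altered fractions per config.

    Each chromosome is partitioned into the configured altered fractions
    plus neutral (log2 = 0) remainder pieces, laid down contiguously in a
    random order so altered segments sit at random positions.
    """
    rng = child_rng(config.seed, "cnv")
    segments: list[CnvSegment] = []
    for chrom, size in zip(genome.chrom_names, genome.chrom_sizes):
        pieces: list[tuple[int, float]] = []
        altered = 0
        for frac, log2r in config.cnv:
            length = int(round(frac * size))
            if length > 0:
                pieces.append((length, log2r))
                altered += length
        neutral = size - altered
        n_neutral = len(pieces) + 1
        for k in range(n_neutral):
            length = neutral // n_neutral + (1 if k < neutral % n_neutral else 0)
            if length > 0:
                pieces.append((length, 0.0))
        order = rng.permutation(len(pieces))
        pos = 0
        for k in order:
            length, log2r = pieces[k]
            segments.append(
                CnvSegment(GenomicInterval(chrom, pos, pos + length), log2r)
            )
            pos += length
        assert pos == size
    return segments


def _cnr_at(segments: Sequence[CnvSegment], chrom: str, point: int) -> float:
    for seg in segments:
        iv = seg.interval
        if iv.chrom == chrom and iv.start <= point < iv.end:
            return seg.cnr
    return 1.0


def generate_truth(
    genes: Sequence[GeneModel],
    interval_data: IntervalData,
    segments: Sequence[CnvSegment],
    config: SimConfig,
) -> GroundTruth:
    """Plant per-feature effects with cross-modality concordance.

    Each gene is "regulated" with probability frac_differential["rna"];
    regulated genes draw a shared random sign and a trivariate normal
    deviate with pairwise correlation ``concordance_rho``, giving
    correlated RNA/ATAC/G4 log2 fold changes of magnitude
    ~N(planted_log2fc_mean, planted_log2fc_sd).  The gene's effects are
    inherited by its promoter-linked ATAC and G4 peaks; background peaks
    draw independent effects at their own modality fractions.  Copy-number
    ratios are read off the segment containing each peak midpoint.
    """
    rng = child_rng(config.seed, "truth")
    rho = config.concordance_rho
    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    m, sd = config.planted_log2fc_mean, config.planted_log2fc_sd

    gene_fx: dict[str, tuple[float, float, float]] = {}
    g_rows = []
    for g in genes:
        if rng.random() < config.frac_differential["rna"]:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            z = rng.multivariate_normal(np.zeros(3), cov)
            fx = tuple(sign * (m + sd * zi) for zi in z)
            regulated = True
        else:
            fx = (0.0, 0.0, 0.0)
            regulated = False
        gene_fx[g.gene_id] = fx
        g_rows.append((g.gene_id, fx[0], _status(fx[0]), regulated))
    genes_df = pd.DataFrame(
        g_rows, columns=["gene_id", "log2fc", "status", "regulated"]
    )

    def peak_truth(
        xs: IntervalSet, prom_gene: list[str], modality: str, fx_slot: int
    ) -> pd.DataFrame:
        rows = []
        frac = config.frac_differential[modality]
        for i in range(len(xs)):
            row = xs.df.iloc[i]
            gid = prom_gene[i]
            if gid:
                lfc = gene_fx[gid][fx_slot]
            elif rng.random() < frac:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                lfc = sign * rng.normal(m, sd)
            else:
                lfc = 0.0
            mid = (int(row["start"]) + int(row["end"])) // 2
            cnr = _cnr_at(segments, row["chrom"], mid)
            rows.append((row["name"], lfc, _status(lfc), cnr, gid))
        return pd.DataFrame(
            rows, columns=["name", "log2fc", "status", "cnr", "promoter_gene"]
        )

    atac_df = peak_truth(interval_data.atac_peaks,
                         interval_data.atac_promoter_gene, "atac", 1)
    g4_df = peak_truth(interval_data.g4_peaks,
                       interval_data.g4_promoter_gene, "g4", 2)
    g4_df["strand"] = interval_data.g4_true_strand
    return GroundTruth(
        genes=genes_df,
        atac=atac_df,
        g4=g4_df,
        promoter_enrichment_fold=(
            (interval_data.promoter_fraction_used
             + (1 - interval_data.promoter_fraction_used)
             * interval_data.promoter_background_rate)
            / interval_data.promoter_background_rate
        ),
        promoter_background_rate=interval_data.promoter_background_rate,
    )


def _status(lfc: float) -> str:
    if lfc > 0:
        return "up"
    if lfc < 0:
        return "down"
    return "nd"


def generate_counts(
    feature_ids: Sequence[str],
    log2fc: np.ndarray,
    cnr: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> CountMatrix:
    """NB counts: mean = baseline * sizefactor * 2^(log2fc * cond) * CNR^cond.

    ``cond`` is 1 for case samples and 0 for controls, so the copy-number
    ratio multiplies case means only.  Variance is mu + alpha * mu^2 with
    alpha = config.nb_dispersion (a dispersion below 1e-8 degenerates to
    Poisson sampling).
    """
    if config.nb_dispersion <= 0:
        raise ConfigurationError("dispersion must be > 0")
    n = len(feature_ids)
    log2fc = np.asarray(log2fc, dtype=float)
    cnr = np.asarray(cnr, dtype=float)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    r = config.n_replicates
    samples = [f"case_{k + 1}" for k in range(r)] + [
        f"control_{k + 1}" for k in range(r)
    ]
    cond = np.array([1.0] * r + [0.0] * r)
    lo, hi = config.library_size_range
    sf = rng.uniform(lo, hi, size=2 * r)
    mu = (
        baseline[:, None]
        * sf[None, :]
        * np.power(2.0, log2fc[:, None] * cond[None, :])
        * np.power(cnr[:, None], cond[None, :])
    )
    alpha = config.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        nb_n = 1.0 / alpha
        nb_p = nb_n / (nb_n + mu)
        counts = rng.negative_binomial(nb_n, nb_p)
    df = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                      columns=samples)
    conditions = {s: ("case" if s.startswith("case") else "control")
                  for s in samples}
    return CountMatrix(df, conditions)


def generate_study(config: SimConfig) -> StudyBundle:
    """Compose all generators into a validated study bundle."""
    genome = generate_genome(config)
    genes = generate_genes(genome, config)
    idata = generate_interval_data(genome, genes, config)
    segments = generate_cnv_segments(genome, config)
    truth = generate_truth(genes, idata, segments, config)
    counts = {
        "atac": generate_counts(
            truth.atac["name"], truth.atac["log2fc"].to_numpy(),
            truth.atac["cnr"].to_numpy(), config,
            child_rng(config.seed, "counts_atac"),
        ),
        "g4": generate_counts(
            truth.g4["name"], truth.g4["log2fc"].to_numpy(),
            truth.g4["cnr"].to_numpy(), config,
            child_rng(config.seed, "counts_g4"),
        ),
        "rna": generate_counts(
            truth.genes["gene_id"], truth.genes["log2fc"].to_numpy(),
            np.ones(len(genes)), config,
            child_rng(config.seed, "counts_rna"),
        ),
    }
    bundle = StudyBundle(
        genome=genome,
        genes=genes,
        atac_peaks=idata.atac_peaks,
        g4_peaks=idata.g4_peaks,
        g4seq_hits=idata.g4seq_hits,
        cnv_segments=segments,
        counts=counts,
        truth=truth,
        config=config,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# serialization


def write_study(bundle: StudyBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_chrom_sizes(bundle.genome, outdir / "genome.chrom.sizes")
    gio.write_bed(
        bundle.genome.excluded or IntervalSet.empty(), outdir / "excluded.bed"
    )
    gio.write_bed12(bundle.genes, outdir / "genes.bed12")
    gio.write_bed(bundle.atac_peaks, outdir / "atac_peaks.bed")
    gio.write_bed(bundle.g4_peaks, outdir / "g4_peaks.bed")
    gio.write_bed(bundle.g4seq_hits, outdir / "g4seq_hits.bed")
    write_segments(bundle.cnv_segments, outdir / "cnv_segments.tsv")
    for modality, cm in bundle.counts.items():
        cm.counts.to_csv(outdir / f"counts_{modality}.tsv", sep="\t")
    design = pd.concat(
        [
            pd.DataFrame(
                {
                    "modality": modality,
                    "sample": list(cm.conditions),
                    "condition": list(cm.conditions.values()),
                }
            )
            for modality, cm in bundle.counts.items()
        ]
    )
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    bundle.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    bundle.truth.atac.to_csv(outdir / "truth_atac.tsv", sep="\t", index=False)
    bundle.truth.g4.to_csv(outdir / "truth_g4.tsv", sep="\t", index=False)
    meta = dataclasses.asdict(bundle.config)
    meta["_promoter_enrichment_fold"] = bundle.truth.promoter_enrichment_fold
    meta["_promoter_background_rate"] = bundle.truth.promoter_background_rate
    (outdir / "config.json").write_text(json.dumps(meta, indent=2))


def read_study(indir: str | Path) -> StudyBundle:
    indir = Path(indir)
    meta = json.loads((indir / "config.json").read_text())
    fold = meta.pop("_promoter_enrichment_fold")
    p0 = meta.pop("_promoter_background_rate")
    meta["gene_length_range"] = tuple(meta["gene_length_range"])
    meta["library_size_range"] = tuple(meta["library_size_range"])
    meta["cnv"] = tuple(tuple(pair) for pair in meta["cnv"])
    config = SimConfig(**meta)
    genome_plain = gio.read_chrom_sizes(indir / "genome.chrom.sizes")
    excluded = gio.read_bed(indir / "excluded.bed")
    genome = GenomeSpec(
        genome_plain.chrom_names, genome_plain.chrom_sizes, excluded=excluded
    )
    design = pd.read_csv(indir / "design.tsv", sep="\t")
    counts = {}
    for modality, sub in design.groupby("modality"):
        mat = pd.read_csv(indir / f"counts_{modality}.tsv", sep="\t", index_col=0)
        counts[modality] = CountMatrix(
            mat, dict(zip(sub["sample"], sub["condition"]))
        )
    truth = GroundTruth(
        genes=pd.read_csv(indir / "truth_genes.tsv", sep="\t"),
        atac=pd.read_csv(indir / "truth_atac.tsv", sep="\t",
                         keep_default_na=False,
                         dtype={"promoter_gene": str}),
        g4=pd.read_csv(indir / "truth_g4.tsv", sep="\t",
                       keep_default_na=False,
                       dtype={"promoter_gene": str, "strand": str}),
        promoter_enrichment_fold=fold,
        promoter_background_rate=p0,
    )
    for df in (truth.atac, truth.g4, truth.genes):
        for col in ("log2fc", "cnr"):
            if col in df.columns:
                df[col] = df[col].astype(float)
    bundle = StudyBundle(
        genome=genome,
        genes=gio.read_bed12(indir / "genes.bed12"),
        atac_peaks=gio.read_bed(indir / "atac_peaks.bed", genome=genome),
        g4_peaks=gio.read_bed(indir / "g4_peaks.bed", genome=genome),
        g4seq_hits=gio.read_bed(indir / "g4seq_hits.bed", genome=genome),
        cnv_segments=read_segments(indir / "cnv_segments.tsv"),
        counts=counts,
        truth=truth,
        config=config,
    )
    bundle.validate()
    return bundle
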