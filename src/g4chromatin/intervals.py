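"""Genomic-interval engine.

All coordinates are 0-based, half-open ``[start, end)``.  An
:class:`IntervalSet` is the universal currency for peaks, hits, windows and
segments; :class:`GenomeSpec` describes the chromosome space intervals live
in, and :class:`GeneModel` carries the gene anatomy (TSS, exons, CDS) needed
for promoter windows and feature annotation.

Overlap joins, nearest-feature search, genome shuffling and
universe-resampling nulls, promoter windows, feature annotation and local
peak density all live here.  Strand is deliberately ignored in overlap
computations (G4 ChIP peaks are unstranded); it matters only for promoter
orientation and strand inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNSTRANDED = "."

#: category labels for :func:`annotate_features`, in precedence order
FEATURE_PRECEDENCE = (
    "promoter/TSS",
    "5'UTR",
    "1st-Ex-Int junction",
    "first exon",
    "first intron",
    "other exon",
    "other intron",
    "3'UTR",
    "intergenic",
)


class ValidationError(ValueError):
    """An interval or interval set violates its invariants."""


class PlacementError(RuntimeError):
    """No legal random placement found for an interval."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", UNSTRANDED):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome space: names, sizes and excluded (gap/blacklist) regions."""

    chrom_names: tuple[str, ...]
    chrom_sizes: tuple[int, ...]
    excluded: "IntervalSet | None" = None

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_sizes):
            raise ValidationError("chrom_names and chrom_sizes length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("chromosome names must be unique")
        if any(s <= 0 for s in self.chrom_sizes):
            raise ValidationError("chromosome sizes must be positive")
        if self.excluded is not None:
            sizes = self.sizes
            for iv in self.excluded:
                if iv.chrom not in sizes or iv.end > sizes[iv.chrom]:
                    raise ValidationError(
                        f"excluded interval {iv.chrom}:{iv.start}-{iv.end} "
                        "outside chromosome bounds"
                    )

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_sizes))

    def excluded_on(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted, merged (starts, ends) of excluded regions on ``chrom``."""
        if self.excluded is None or len(self.excluded) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        sub = self.excluded.df[self.excluded.df["chrom"] == chrom]
        if sub.empty:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return merge_intervals(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )


class IntervalSet:
    """Ordered collection of genomic intervals backed by a DataFrame.

    Columns: chrom, start, end, name, score, strand.  Row position is the
    interval index used by the join/closest/density operations.
    """

    COLUMNS = ("chrom", "start", "end", "name", "score", "strand")

    def __init__(self, df: pd.DataFrame, genome: GenomeSpec | None = None):
        df = df.copy().reset_index(drop=True)
        for col, default in (("name", None), ("score", np.nan), ("strand", UNSTRANDED)):
            if col not in df.columns:
                df[col] = default
        df = df.loc[:, list(self.COLUMNS)]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            raise ValidationError("intervals must satisfy 0 <= start < end")
        if genome is not None:
            sizes = genome.sizes
            for chrom, sub in df.groupby("chrom"):
                if chrom not in sizes:
                    raise ValidationError(f"unknown chromosome {chrom!r}")
                if (sub["end"] > sizes[chrom]).any():
                    raise ValidationError(f"interval beyond end of {chrom}")
        self.df = df
        self.genome = genome
        self._index_cache: dict | None = None

    def _chrom_index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, row indices, cummax ends), start-
        sorted.  Cached; the backing frame is treated as immutable."""
        if self._index_cache is None:
            cache = {}
            for chrom, sub in self.df.groupby("chrom"):
                bs = sub["start"].to_numpy(np.int64)
                be = sub["end"].to_numpy(np.int64)
                idx = sub.index.to_numpy(np.int64)
                order = np.lexsort((idx, bs))
                bs, be, idx = bs[order], be[order], idx[order]
                cache[chrom] = (bs, be, idx, np.maximum.accumulate(be))
            self._index_cache = cache
        return self._index_cache

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple | GenomicInterval],
        genome: GenomeSpec | None = None,
    ) -> "IntervalSet":
        rows = []
        for r in records:
            if isinstance(r, GenomicInterval):
                rows.append(
                    (r.chrom, r.start, r.end, r.name, r.score, r.strand)
                )
            else:
                r = tuple(r)
                rows.append(tuple(r) + (None, np.nan, UNSTRANDED)[len(r) - 3 :])
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df, genome=genome)

    @classmethod
    def empty(cls, genome: GenomeSpec | None = None) -> "IntervalSet":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)), genome=genome)

    # -- container protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, i: int) -> GenomicInterval:
        row = self.df.iloc[i]
        score = None if pd.isna(row["score"]) else float(row["score"])
        name = None if row["name"] is None or pd.isna(row["name"]) else str(row["name"])
        return GenomicInterval(
            row["chrom"], int(row["start"]), int(row["end"]),
            strand=row["strand"], name=name, score=score,
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df.fillna({"score": -1}).astype({"name": "object"})
        b = other.df.fillna({"score": -1}).astype({"name": "object"})
        return a.equals(b)

    # -- helpers ----------------------------------------------------------
    def sort(self) -> "IntervalSet":
        """Normalized copy sorted by (chrom, start, end); stable."""
        df = self.df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet(df, genome=self.genome)

    def subset(self, indices: Sequence[int]) -> "IntervalSet":
        return IntervalSet(self.df.iloc[list(indices)], genome=self.genome)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy(np.int64)

    def _by_chrom(self) -> dict[str, pd.DataFrame]:
        return {c: sub for c, sub in self.df.groupby("chrom", sort=True)}


@dataclass(frozen=True)
class GeneModel:
    """A gene: strand, TSS, ordered exons and an optional CDS span.

    ``exons`` are genomic-coordinate (start, end) pairs sorted by start;
    transcription order is start-to-end of that list on "+" genes and the
    reverse on "-" genes.  The TSS is the 5'-most transcribed base: span
    start on "+", ``span end - 1`` (last covered base, 0-based) on "-".
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be +/-")
        if len(self.exons) < 2:
            raise ValidationError(f"gene {self.gene_id}: need >= 2 exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e) or s < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons must be ordered, non-overlapping"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        s, e = self.span
        return s if self.strand == "+" else e - 1

    @property
    def first_exon(self) -> tuple[int, int]:
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def first_intron(self) -> tuple[int, int] | None:
        if len(self.exons) < 2:
            return None
        if self.strand == "+":
            return self.exons[0][1], self.exons[1][0]
        return self.exons[-2][1], self.exons[-1][0]

    @property
    def first_junction(self) -> int:
        """Boundary coordinate between first exon and first intron."""
        return self.exons[0][1] if self.strand == "+" else self.exons[-1][0]

    def utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR, 3'UTR) exonic pieces, empty when no CDS is annotated."""
        if self.cds is None:
            return [], []
        cs, ce = self.cds
        lo = [  # exonic sequence genomically left of the CDS
            (s, min(e, cs)) for s, e in self.exons if s < cs
        ]
        hi = [(max(s, ce), e) for s, e in self.exons if e > ce]
        lo = [(s, e) for s, e in lo if s < e]
        hi = [(s, e) for s, e in hi if s < e]
        return (lo, hi) if self.strand == "+" else (hi, lo)


@dataclass(frozen=True)
class FeatureLabel:
    category: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in FEATURE_PRECEDENCE:
            raise ValidationError(f"unknown feature category {self.category!r}")


# ---------------------------------------------------------------------------
# primitive helpers


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into a disjoint sorted union."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _overlaps_any(start: int, end: int, ms: np.ndarray, me: np.ndarray) -> bool:
    """Does [start, end) intersect a sorted merged interval union?"""
    if len(ms) == 0:
        return False
    i = np.searchsorted(ms, end)  # ms[i-1] < end
    return i > 0 and me[i - 1] > start


# ---------------------------------------------------------------------------
# operations


def overlap_join(
    a: IntervalSet, b: IntervalSet, min_overlap: int = 1
) -> list[tuple[int, int, int]]:
    """All (a_index, b_index, overlap_bp) pairs with overlap >= min_overlap.

    Strand-agnostic; output sorted by (a_index, b_index).  A sweep over
    start-sorted ``b`` with a running maximum of ends keeps this close to
    O(n log n) for typical peak sets.
    """
    if min_overlap < 1:
        raise ValidationError("min_overlap must be >= 1")
    out: list[tuple[int, int, int]] = []
    b_by_chrom = b._chrom_index()
    for ai, (chrom, s, e) in enumerate(
        zip(a.df["chrom"], a.df["start"], a.df["end"])
    ):
        if chrom not in b_by_chrom:
            continue
        bs, be, idx, cummax = b_by_chrom[chrom]
        j = int(np.searchsorted(bs, e)) - 1  # last b with start < e
        while j >= 0 and cummax[j] > s:
            ov = min(e, be[j]) - max(s, bs[j])
            if ov >= min_overlap:
                out.append((ai, int(idx[j]), int(ov)))
            j -= 1
    out.sort()
    return out


def closest(
    query: IntervalSet, subject: IntervalSet
) -> list[tuple[int, int, float]]:
    """Nearest subject per query: (query_index, subject_index, distance_bp).

    Distance is 0 for overlapping (or directly abutting) intervals, else the
    gap between nearest edges.  Equidistant subjects: the one with the lower
    start coordinate wins.  Queries on chromosomes absent from the subject
    set are reported with subject_index -1 and infinite distance.
    """
    subj = {c: v[:3] for c, v in subject._chrom_index().items()}
    out: list[tuple[int, int, float]] = []
    for qi, (chrom, qs, qe) in enumerate(
        zip(query.df["chrom"], query.df["start"], query.df["end"])
    ):
        if chrom not in subj:
            out.append((qi, -1, float("inf")))
            continue
        bs, be, idx = subj[chrom]
        gap = np.maximum(np.maximum(bs - qe, qs - be), 0)
        best = gap.min()
        cands = np.flatnonzero(gap == best)
        j = cands[np.argmin(bs[cands])]  # lowest start wins ties
        out.append((qi, int(idx[j]), float(best)))
    return out


def _sample_start(
    rng: np.random.Generator,
    length: int,
    chrom_size: int,
    ms: np.ndarray,
    me: np.ndarray,
    max_attempts: int = 10_000,
) -> int:
    hi = chrom_size - length
    if hi < 0:
        raise PlacementError(
            f"interval of length {length} does not fit on chromosome "
            f"of size {chrom_size}"
        )
    if len(ms) == 0:
        return int(rng.integers(0, hi + 1))
    for _ in range(max_attempts):
        start = int(rng.integers(0, hi + 1))
        if not _overlaps_any(start, start + length, ms, me):
            return start
    raise PlacementError(
        f"no legal placement for interval of length {length} after "
        f"{max_attempts} attempts"
    )


def shuffle(
    x: IntervalSet,
    genome: GenomeSpec,
    excluded: IntervalSet | None = None,
    same_chrom: bool = True,
    rng: np.random.Generator | int | None = None,
) -> IntervalSet:
    """Randomly relocate every interval, preserving its length.

    Placement is uniform over legal start positions; draws overlapping the
    excluded regions are rejected (up to 10^4 attempts per interval).  The
    default keeps each interval on its own chromosome; with
    ``same_chrom=False`` a target chromosome is drawn with probability
    proportional to the number of legal start positions.
    """
    rng = np.random.default_rng(rng)
    if excluded is None:
        excluded = genome.excluded
    excl: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in genome.chrom_names:
        if excluded is None or len(excluded) == 0:
            excl[c] = (np.empty(0, np.int64), np.empty(0, np.int64))
        else:
            sub = excluded.df[excluded.df["chrom"] == c]
            excl[c] = merge_intervals(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
            )
    sizes = genome.sizes
    names = list(genome.chrom_names)
    out = x.df.copy()
    new_chroms, new_starts = [], []
    for chrom, s, e in zip(x.df["chrom"], x.df["start"], x.df["end"]):
        length = e - s
        if same_chrom:
            target = chrom
        else:
            weights = np.array(
                [max(sizes[c] - length + 1, 0) for c in names], dtype=float
            )
            if weights.sum() == 0:
                raise PlacementError(
                    f"interval of length {length} longer than every chromosome"
                )
            target = names[rng.choice(len(names), p=weights / weights.sum())]
        ms, me = excl[target]
        start = _sample_start(rng, length, sizes[target], ms, me)
        new_chroms.append(target)
        new_starts.append(start)
    out["chrom"] = new_chroms
    out["start"] = np.asarray(new_starts, dtype=np.int64)
    out["end"] = out["start"] + x.lengths()
    return IntervalSet(out, genome=genome)


def resample_within_universe(
    query: IntervalSet,
    universe: IntervalSet,
    rng: np.random.Generator | int | None = None,
) -> IntervalSet:
    """Sample |query| elements uniformly without replacement from universe."""
    if len(query) > len(universe):
        raise ValidationError(
            f"cannot resample {len(query)} from a universe of {len(universe)}"
        )
    rng = np.random.default_rng(rng)
    pick = rng.choice(len(universe), size=len(query), replace=False)
    return universe.subset(pick)


def promoter_windows(
    genes: Sequence[GeneModel],
    flank: int = 3000,
    genome: GenomeSpec | None = None,
) -> IntervalSet:
    """Per gene, [TSS - flank, TSS + flank) clipped to chromosome bounds."""
    sizes = genome.sizes if genome is not None else None
    rows = []
    for g in genes:
        lo = max(g.tss - flank, 0)
        hi = g.tss + flank
        if sizes is not None:
            hi = min(hi, sizes[g.chrom])
        rows.append((g.chrom, lo, hi, g.gene_id, np.nan, g.strand))
    return IntervalSet(
        pd.DataFrame(rows, columns=list(IntervalSet.COLUMNS)), genome=genome
    )


def annotate_features(
    x: IntervalSet, genes: Sequence[GeneModel], promoter_flank: int = 3000
) -> list[FeatureLabel]:
    """Assign each interval exactly one genomic-feature category.

    Precedence when categories overlap: promoter/TSS > 5'UTR > first
    exon-intron junction > first exon > first intron > other exon > other
    intron > 3'UTR > intergenic.  The junction category requires the
    interval to cover the boundary coordinate between the first exon and the
    first intron in transcription order (both flanking bases included).
    """
    cat_sets: dict[str, list[tuple[str, int, int, str]]] = {
        c: [] for c in FEATURE_PRECEDENCE[:-1]
    }
    junctions: list[tuple[str, int, str]] = []
    for g in genes:
        cat_sets["promoter/TSS"].append(
            (g.chrom, max(g.tss - promoter_flank, 0), g.tss + promoter_flank, g.gene_id)
        )
        utr5, utr3 = g.utr_intervals()
        for s, e in utr5:
            cat_sets["5'UTR"].append((g.chrom, s, e, g.gene_id))
        for s, e in utr3:
            cat_sets["3'UTR"].append((g.chrom, s, e, g.gene_id))
        fe = g.first_exon
        cat_sets["first exon"].append((g.chrom, fe[0], fe[1], g.gene_id))
        fi = g.first_intron
        if fi is not None and fi[0] < fi[1]:
            cat_sets["first intron"].append((g.chrom, fi[0], fi[1], g.gene_id))
        junctions.append((g.chrom, g.first_junction, g.gene_id))
        ordered = g.exons if g.strand == "+" else g.exons[::-1]
        for s, e in ordered[1:]:
            cat_sets["other exon"].append((g.chrom, s, e, g.gene_id))
        for (s1, e1), (s2, e2) in zip(ordered[1:], ordered[2:]):
            lo, hi = (e1, s2) if g.strand == "+" else (e2, s1)
            if lo < hi:
                cat_sets["other intron"].append((g.chrom, lo, hi, g.gene_id))

    def hit(rows: list[tuple[str, int, int, str]], chrom: str, s: int, e: int):
        best = None
        for c, fs, fe_, gid in rows:
            if c == chrom and fs < e and fe_ > s:
                if best is None or fs < best[0]:
                    best = (fs, gid)
        return None if best is None else best[1]

    labels: list[FeatureLabel] = []
    for chrom, s, e in zip(x.df["chrom"], x.df["start"], x.df["end"]):
        assigned = None
        for cat in FEATURE_PRECEDENCE[:-1]:
            if cat == "1st-Ex-Int junction":
                gid = next(
                    (g for c, j, g in junctions if c == chrom and s < j < e), None
                )
            else:
                gid = hit(cat_sets[cat], chrom, s, e)
            if gid is not None:
                assigned = FeatureLabel(cat, gid)
                break
        labels.append(assigned or FeatureLabel("intergenic"))
    return labels


def peak_density(x: IntervalSet, flank: int = 10_000) -> np.ndarray:
    """Number of *other* intervals within flank bp of each interval.

    Counts set members overlapping ``[start - flank, end + flank)``, self
    excluded.
    """
    if len(x) == 0:
        return np.zeros(0, dtype=np.int64)
    expanded = x.df.copy()
    expanded["start"] = np.maximum(expanded["start"] - flank, 0)
    expanded["end"] = expanded["end"] + flank
    pairs = overlap_join(IntervalSet(expanded), x, min_overlap=1)
    counts = np.zeros(len(x), dtype=np.int64)
    for i, j, _ in pairs:
        if i != j:
            counts[i] += 1
    return counts
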