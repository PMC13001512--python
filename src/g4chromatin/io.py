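"""Readers and writers for the plain-text genomics formats used here.

BED is read and written natively in the package's 0-based half-open
convention.  GTF (1-based, inclusive) is converted to internal coordinates
at the parser boundary via :mod:`gffutils`.  Malformed lines raise with the
offending line number.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomeSpec,
    IntervalSet,
    UNSTRANDED,
    ValidationError,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> GenomeSpec:
    names, sizes = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated fields")
        try:
            size = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: size is not an integer") from exc
        names.append(parts[0])
        sizes.append(size)
    return GenomeSpec(tuple(names), tuple(sizes))


def write_chrom_sizes(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in zip(genome.chrom_names, genome.chrom_sizes):
            fh.write(f"{name}\t{size}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, genome: GenomeSpec | None = None) -> IntervalSet:
    """Read BED3 or BED6 (extra columns ignored)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: fewer than 3 BED fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        name = parts[3] if len(parts) > 3 and parts[3] != "." else None
        score = np.nan
        if len(parts) > 4 and parts[4] != ".":
            try:
                score = float(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        strand = parts[5] if len(parts) > 5 else UNSTRANDED
        if strand not in ("+", "-", UNSTRANDED):
            raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
        rows.append((parts[0], start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=list(IntervalSet.COLUMNS))
    try:
        return IntervalSet(df, genome=genome)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bed(x: IntervalSet, path: str | Path) -> None:
    """Write 6-column BED."""
    with open(path, "w") as fh:
        for _, r in x.df.iterrows():
            name = "." if r["name"] is None or pd.isna(r["name"]) else str(r["name"])
            score = "." if pd.isna(r["score"]) else format(r["score"], "g")
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\t{score}\t{r['strand']}\n"
            )


# ---------------------------------------------------------------------------
# BED12 gene models


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            span_s, span_e = g.span
            cds_s, cds_e = g.cds if g.cds is not None else (span_s, span_s)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - span_s) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        g.chrom, span_s, span_e, g.gene_id, 0, g.strand,
                        cds_s, cds_e, 0, len(g.exons), sizes, offsets,
                    )
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ParseError(f"{path}:{lineno}: fewer than 12 BED12 fields")
        try:
            chrom = parts[0]
            span_s = int(parts[1])
            gene_id = parts[3]
            strand = parts[5]
            cds_s, cds_e = int(parts[6]), int(parts[7])
            n = int(parts[9])
            sizes = [int(v) for v in parts[10].rstrip(",").split(",")]
            offsets = [int(v) for v in parts[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed BED12 line") from exc
        if len(sizes) != n or len(offsets) != n:
            raise ParseError(f"{path}:{lineno}: block count mismatch")
        exons = tuple(
            (span_s + off, span_s + off + sz) for off, sz in zip(offsets, sizes)
        )
        cds = None if cds_s == cds_e else (cds_s, cds_e)
        genes.append(GeneModel(gene_id, chrom, strand, exons, cds=cds))
    return genes


# ---------------------------------------------------------------------------
# GTF (genes/exons only)


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene models (exons + optional CDS) from a GTF file.

    1-based inclusive GTF coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ParseError(f"{path}: {feat.featuretype} without gene_id")
        meta.setdefault(gid, (feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(gid, []).append((feat.start - 1, feat.end))
    genes = []
    for gid, ex in exons.items():
        chrom, strand = meta[gid]
        ex = tuple(sorted(ex))
        cds_span = None
        if gid in cds:
            cs = min(s for s, _ in cds[gid])
            ce = max(e for _, e in cds[gid])
            cds_span = (cs, ce)
        genes.append(GeneModel(gid, chrom, strand, ex, cds=cds_span))
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# tables


def read_tsv(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
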