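"""Copy-number normalization of peak count matrices.

Cell lines from different donors can differ in DNA copy number; a peak
sitting in an amplified segment of the case genome shows more fragments for
purely genomic reasons, which masquerades as a differential signal.  Prior
to differential testing each peak is assigned the copy-number ratio (CNR =
2^log2ratio, case/control) of its overlapping segment - or the closest
segment when none overlaps - and the counts are rescaled: CNR >= 1 divides
the case-sample counts by the CNR, CNR < 1 multiplies the control-sample
counts by the CNR.  Scaled counts are rounded half-up to keep the integer
contract of the count-based differential stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import CountMatrix
from .intervals import GenomicInterval, IntervalSet, closest, overlap_join


@dataclass(frozen=True)
class CnvSegment:
    interval: GenomicInterval
    log2_ratio: float

    @property
    def cnr(self) -> float:
        return float(2.0**self.log2_ratio)


@dataclass(frozen=True)
class CnrAssignment:
    peak_index: int
    segment_index: int  # -1 when unassignable
    relation: str  # "overlap", "closest" or "unassigned"
    cnr: float


def segments_to_intervals(segments: Sequence[CnvSegment]) -> IntervalSet:
    return IntervalSet.from_records([s.interval for s in segments])


def read_segments(path: str | Path) -> list[CnvSegment]:
    """Read a segment TSV (chromosome, start, end, log2; CNVkit .cns
    dialect accepted, extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    required = ["chromosome", "start", "end", "log2"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing segment columns {missing}")
    return [
        CnvSegment(
            GenomicInterval(str(r[cols["chromosome"]]), int(r[cols["start"]]),
                            int(r[cols["end"]])),
            float(r[cols["log2"]]),
        )
        for _, r in df.iterrows()
    ]


def write_segments(segments: Sequence[CnvSegment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chromosome": [s.interval.chrom for s in segments],
            "start": [s.interval.start for s in segments],
            "end": [s.interval.end for s in segments],
            "log2": [s.log2_ratio for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def assign_segments(
    peaks: IntervalSet, segments: Sequence[CnvSegment]
) -> list[CnrAssignment]:
    """Assign every peak a segment: overlap first, else closest.

    Overlap is preferred over proximity; a peak overlapping several
    segments takes the one with the largest overlap length (ties: lower
    segment start).  Peaks on chromosomes without segments are flagged
    unassigned and treated as CNR = 1 downstream, with a warning.
    """
    seg_set = segments_to_intervals(segments)
    best_overlap: dict[int, tuple[int, int]] = {}
    for pi, si, ov in overlap_join(peaks, seg_set, min_overlap=1):
        cur = best_overlap.get(pi)
        if cur is None or ov > cur[0] or (
            ov == cur[0] and segments[si].interval.start
            < segments[cur[1]].interval.start
        ):
            best_overlap[pi] = (ov, si)
    nearest = {qi: (si, d) for qi, si, d in closest(peaks, seg_set)}
    out: list[CnrAssignment] = []
    n_unassigned = 0
    for pi in range(len(peaks)):
        if pi in best_overlap:
            si = best_overlap[pi][1]
            out.append(CnrAssignment(pi, si, "overlap", segments[si].cnr))
        else:
            si, dist = nearest[pi]
            if si < 0 or not np.isfinite(dist):
                n_unassigned += 1
                out.append(CnrAssignment(pi, -1, "unassigned", 1.0))
            else:
                out.append(CnrAssignment(pi, si, "closest", segments[si].cnr))
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} peak(s) on chromosomes without CNV segments; "
            "treated as CNR = 1",
            stacklevel=2,
        )
    return out


def scale_counts(
    counts: CountMatrix, assignments: Sequence[CnrAssignment]
) -> CountMatrix:
    """Rescale counts by per-peak CNR before differential testing.

    Row order of ``counts`` must match the peak order the assignments were
    computed on.  CNR >= 1: case columns divided by CNR; CNR < 1: control
    columns multiplied by CNR.  Results are rounded half-up to integers.
    """
    if len(assignments) != len(counts.counts):
        raise ValueError("one assignment per count row required")
    cnr = np.array([a.cnr for a in assignments], dtype=float)
    if (cnr <= 0).any():
        raise ValueError("CNR values must be positive")
    mat = counts.values().copy()
    case_cols = [counts.sample_ids.index(s) for s in counts.samples_of("case")]
    ctrl_cols = [counts.sample_ids.index(s) for s in counts.samples_of("control")]
    ge1 = cnr >= 1.0
    mat[np.ix_(ge1, case_cols)] /= cnr[ge1, None]
    mat[np.ix_(~ge1, ctrl_cols)] *= cnr[~ge1, None]
    scaled = np.floor(mat + 0.5).astype(np.int64)  # round half-up
    return counts.copy_with(
        pd.DataFrame(scaled, index=counts.counts.index, columns=counts.counts.columns)
    )
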