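"""Strandedness of unstranded G4 ChIP peaks from strand-resolved hits.

G4 ChIP-seq does not capture strand; in-vitro polymerase-stalling hits do.
A peak intersecting hits on the Watson strand only is called Watson (and
symmetrically Crick); hits on both strands make it ambiguous, no hits leave
it unassigned.  Relative to a linked gene, a called G4 is then classified
as forming on the template ("transcribing") strand - the strand read by the
polymerase, i.e. Crick for a "+" gene - or the non-template strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import IntervalSet, overlap_join

WATSON = "watson"
CRICK = "crick"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"

TEMPLATE = "transcribing"
NON_TEMPLATE = "non-transcribing"
NOT_CALLABLE = "not-callable"


@dataclass(frozen=True)
class StrandCall:
    peak_index: int
    call: str
    n_watson_hits: int
    n_crick_hits: int


@dataclass(frozen=True)
class TemplateCall:
    peak_index: int
    gene_id: str | None
    relation: str


def split_hits_by_strand(hits: IntervalSet) -> tuple[IntervalSet, IntervalSet]:
    """Split a stranded BED6 hit set into (watson/+, crick/-) subsets."""
    df = hits.df
    return (
        IntervalSet(df[df["strand"] == "+"], genome=hits.genome),
        IntervalSet(df[df["strand"] == "-"], genome=hits.genome),
    )


def infer_strand(
    g4_peaks: IntervalSet,
    hits_watson: IntervalSet,
    hits_crick: IntervalSet,
    min_overlap: int = 1,
) -> list[StrandCall]:
    """Call each peak watson/crick/ambiguous/unassigned from hit overlaps."""
    n_w = [0] * len(g4_peaks)
    n_c = [0] * len(g4_peaks)
    for i, _, _ in overlap_join(g4_peaks, hits_watson, min_overlap=min_overlap):
        n_w[i] += 1
    for i, _, _ in overlap_join(g4_peaks, hits_crick, min_overlap=min_overlap):
        n_c[i] += 1
    calls = []
    for i in range(len(g4_peaks)):
        if n_w[i] and n_c[i]:
            call = AMBIGUOUS
        elif n_w[i]:
            call = WATSON
        elif n_c[i]:
            call = CRICK
        else:
            call = UNASSIGNED
        calls.append(StrandCall(i, call, n_w[i], n_c[i]))
    return calls


def classify_template(
    calls: Sequence[StrandCall],
    gene_links: Mapping[int, tuple[str, str]],
) -> list[TemplateCall]:
    """Template vs non-template relative to each peak's linked gene.

    ``gene_links`` maps peak_index -> (gene_id, gene_strand).  For a "+"
    gene the template strand is Crick, so a Crick-called G4 forms on the
    transcribing strand and a Watson-called one on the non-transcribing
    strand; mirrored for "-" genes.  Ambiguous/unassigned calls or missing
    links are not callable.
    """
    out = []
    for call in calls:
        link = gene_links.get(call.peak_index)
        if link is None or call.call not in (WATSON, CRICK):
            out.append(TemplateCall(call.peak_index, link[0] if link else None,
                                    NOT_CALLABLE))
            continue
        gene_id, gene_strand = link
        template_strand = CRICK if gene_strand == "+" else WATSON
        relation = TEMPLATE if call.call == template_strand else NON_TEMPLATE
        out.append(TemplateCall(call.peak_index, gene_id, relation))
    return out
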