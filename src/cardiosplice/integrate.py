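"""Coordinate-level joins between eCLIP peaks, splicing events, and
circRNA back-splice spans.

A splicing event is matched through its alternative exon and the two
flanking introns; a join is emitted whenever a peak or back-splice span
overlaps any of those sub-features by at least one base. Matching is
strand-blind; when both sides carry a gene identity, it must agree, to
suppress spurious cross-gene joins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .eclip import PeakSet
from .intervals import GenomicInterval


@dataclass(frozen=True)
class SplicingEvent:
    """Alternative-exon event coordinates with flanking introns."""

    event_id: str
    gene_id: str
    alt_exon: GenomicInterval
    intron_5p: GenomicInterval | None = None
    intron_3p: GenomicInterval | None = None

    def sub_features(self) -> list[tuple[str, GenomicInterval]]:
        feats = [("alt_exon", self.alt_exon)]
        if self.intron_5p is not None:
            feats.append(("flanking_intron_5p", self.intron_5p))
        if self.intron_3p is not None:
            feats.append(("flanking_intron_3p", self.intron_3p))
        return feats


@dataclass(frozen=True)
class FeatureJoin:
    left_id: str
    left_kind: str
    right_id: str
    right_kind: str
    sub_feature: str
    overlap: GenomicInterval
    gene_id: str = ""


def _event_tree(
    events: Sequence[SplicingEvent],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for ei, ev in enumerate(events):
        if ev.intron_5p is None and ev.intron_3p is None:
            warnings.warn(
                f"event {ev.event_id} lacks flanking introns; exon-only matching",
                stacklevel=3,
            )
        for sub, iv in ev.sub_features():
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (ei, sub))
    return trees


def _join(
    items: Sequence[tuple[str, str, GenomicInterval, str]],
    events: Sequence[SplicingEvent],
    kind_right: str = "splicing_event",
) -> list[FeatureJoin]:
    trees = _event_tree(events)
    joins = []
    for item_id, kind, iv, gene in items:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for h in tree.overlap(iv.start, iv.end):
            ei, sub = h.data
            ev = events[ei]
            if gene and ev.gene_id and gene != ev.gene_id:
                continue
            span = GenomicInterval(
                iv.chrom, max(iv.start, h.begin), min(iv.end, h.end)
            )
            joins.append(
                FeatureJoin(item_id, kind, ev.event_id, kind_right, sub, span, ev.gene_id)
            )
    joins.sort(key=lambda j: (j.gene_id, j.overlap.chrom, j.overlap.start,
                              j.overlap.end, j.left_id, j.right_id, j.sub_feature))
    return joins


def overlap_peaks_events(
    peaks: PeakSet,
    events: Sequence[SplicingEvent],
    peak_genes: dict[str, str] | None = None,
) -> list[FeatureJoin]:
    """Joins between peaks and event exon/flanking-intron coordinates.

    ``peak_genes`` optionally maps peak name -> gene_id (e.g. from
    annotation); when provided, joins are restricted to the same gene.
    """
    items = []
    for i, p in enumerate(peaks.peaks):
        pid = p.name or f"peak{i + 1}"
        gene = (peak_genes or {}).get(pid, "")
        items.append((pid, "eclip_peak", p, gene))
    return _join(items, events)


def overlap_events_circrna(
    events: Sequence[SplicingEvent],
    circs: Sequence[tuple[str, str, GenomicInterval]],
) -> list[FeatureJoin]:
    """Joins between circRNA back-splice spans and splicing events.

    ``circs`` is a sequence of (circ_id, gene_id, back-splice span).
    """
    items = [(cid, "circrna", iv, gene) for cid, gene, iv in circs]
    return _join(items, events)
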