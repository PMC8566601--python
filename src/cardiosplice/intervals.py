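"""Genomic interval arithmetic and transcript-region derivation.

All coordinates are 0-based, half-open (BED convention). GTF input is
converted on read (1-based inclusive -> 0-based half-open). Transcript
bodies are partitioned into the region categories used for eCLIP peak
annotation: 5'UTR, CDS exon, proximal/distal intron, 3'UTR, and
noncoding exon for transcripts without a CDS.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}

#: Region categories, in the canonical order used by frequency profiles.
CATEGORIES = (
    "five_prime_utr",
    "cds_exon",
    "proximal_intron",
    "distal_intron",
    "three_prime_utr",
    "noncoding_exon",
)

#: Proximal-intron window: intronic bases within this many nt of a splice
#: site are "proximal", the remainder "distal".
DEFAULT_PROXIMAL_NT = 500


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand, name and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and "." not in (self.strand, other.strand) and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_span(self, other: "GenomicInterval") -> "GenomicInterval | None":
        """The intersection of two intervals, or None if they do not overlap."""
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end), self.strand
        )


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript; ``cds_span`` absent = non-coding.

    ``cds_span`` is the min-start..max-end envelope of the CDS records,
    so it may bridge introns; only its endpoints must fall in exons.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_span: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} and {b}")
        if self.cds_span is not None:
            for pos in (self.cds_span.start, self.cds_span.end - 1):
                if not any(e.start <= pos < e.end for e in exons):
                    raise ValueError(
                        f"{self.transcript_id}: CDS span {self.cds_span.start}-"
                        f"{self.cds_span.end} not contained in the exon union"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def cds_length(self) -> int:
        """Total exonic bases inside the CDS span (0 for non-coding)."""
        if self.cds_span is None:
            return 0
        return sum(
            max(0, min(e.end, self.cds_span.end) - max(e.start, self.cds_span.start))
            for e in self.exons
        )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class RegionAnnotation:
    """One category-labelled sub-interval of a transcript body."""

    interval: GenomicInterval
    category: str
    transcript_id: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown region category {self.category!r}")


# ---------------------------------------------------------------------------
# region derivation


def derive_regions(
    t: TranscriptModel, proximal_nt: int = DEFAULT_PROXIMAL_NT
) -> list[RegionAnnotation]:
    """Partition a transcript body into region categories.

    Exonic bases left of the CDS span are 5'UTR on the + strand and
    3'UTR on the - strand (and symmetrically on the right). Intronic
    bases within ``proximal_nt`` of either flanking splice site are
    proximal intron, the rest distal. Non-coding transcripts emit
    ``noncoding_exon`` plus introns. The output tiles the transcript
    span without overlap.
    """
    if proximal_nt <= 0:
        raise ValueError("proximal_nt must be positive")
    out: list[RegionAnnotation] = []

    def add(start: int, end: int, category: str) -> None:
        if end > start:
            out.append(
                RegionAnnotation(
                    GenomicInterval(t.chrom, start, end, t.strand),
                    category,
                    t.transcript_id,
                    t.gene_id,
                )
            )

    left_utr = "five_prime_utr" if t.strand != "-" else "three_prime_utr"
    right_utr = "three_prime_utr" if t.strand != "-" else "five_prime_utr"

    for exon in t.exons:
        if t.cds_span is None:
            add(exon.start, exon.end, "noncoding_exon")
            continue
        cs, ce = t.cds_span.start, t.cds_span.end
        add(exon.start, min(exon.end, cs), left_utr)
        add(max(exon.start, cs), min(exon.end, ce), "cds_exon")
        add(max(exon.start, ce), exon.end, right_utr)

    for a, b in zip(t.exons, t.exons[1:]):
        istart, iend = a.end, b.start
        if iend - istart <= 2 * proximal_nt:
            add(istart, iend, "proximal_intron")
        else:
            add(istart, istart + proximal_nt, "proximal_intron")
            add(istart + proximal_nt, iend - proximal_nt, "distal_intron")
            add(iend - proximal_nt, iend, "proximal_intron")

    out.sort(key=lambda r: r.interval.start)
    return out


def representative_transcripts(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """One transcript per gene: longest CDS, ties broken by transcript
    length then transcript_id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        key = (m.cds_length, m.length, m.transcript_id)
        cur_key = (cur.cds_length, cur.length, cur.transcript_id)
        # transcript_id descending would be wrong; prefer lexicographically
        # smaller id on exact ties, so compare ids negated via tuple trick:
        if (key[0], key[1]) > (cur_key[0], cur_key[1]) or (
            (key[0], key[1]) == (cur_key[0], cur_key[1]) and m.transcript_id < cur.transcript_id
        ):
            best[m.gene_id] = m
    return [best[g] for g in sorted(best)]


# ---------------------------------------------------------------------------
# interval engine


def _trees(
    intervals: Sequence[GenomicInterval], stranded: bool
) -> dict[tuple, IntervalTree]:
    trees: dict[tuple, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def intersect(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    stranded: bool = False,
) -> list[tuple[GenomicInterval, GenomicInterval, GenomicInterval]]:
    """All (query, subject, overlap-span) triples overlapping by >= 1 base.

    Query order is preserved; subjects within a query are ordered by
    coordinate. Strand is ignored unless ``stranded`` (bedtools default).
    """
    trees = _trees(subject, stranded)
    out = []
    for q in query:
        keys = [(q.chrom, q.strand)] if stranded else [(q.chrom,)]
        if stranded and q.strand == ".":
            keys = [(q.chrom, s) for s in ("+", "-", ".")]
        hits = []
        for key in keys:
            tree = trees.get(key)
            if tree is not None:
                hits.extend(tree.overlap(q.start, q.end))
        for h in sorted(hits, key=lambda h: (h.begin, h.end, h.data)):
            s = subject[h.data]
            span = q.overlap_span(s)
            assert span is not None
            out.append((q, s, span))
    return out


def merge_within(
    intervals: Sequence[GenomicInterval], window_nt: int = 0
) -> list[GenomicInterval]:
    """Union intervals on the same chrom/strand whose gap <= window_nt.

    window 0 merges overlapping and abutting intervals (bedtools merge);
    window 200 reproduces aggregation of nearby peaks into one site.
    """
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault((iv.chrom, iv.strand), []).append(iv)
    merged: list[GenomicInterval] = []
    for (chrom, strand), ivs in groups.items():
        ivs.sort(key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= window_nt:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    merged.sort(key=lambda x: (x.chrom, x.start, x.end, x.strand))
    return merged


# ---------------------------------------------------------------------------
# readers / writers


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED6 (or BED3/4/5) file into GenomicIntervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = f[3] if len(f) > 3 else ""
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def _parse_gtf_lines(path: str | Path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GTF line has {len(f)} fields, expected 9")
            try:
                int(f[3]), int(f[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            rows.append((lineno, f))
    return rows


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Requires gene_id and transcript_id attributes on exon/CDS features.
    The CDS span of a transcript is the envelope of its CDS records.
    Exons falling outside a declared gene span raise a validation error.
    Parsing of the attribute column is delegated to gffutils.
    """
    from gffutils.feature import feature_from_line

    gene_spans: dict[str, tuple[str, int, int]] = {}
    exons: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}

    for lineno, f in _parse_gtf_lines(path):
        feat = feature_from_line("\t".join(f), strict=False)
        ftype = feat.featuretype
        if ftype not in ("gene", "transcript", "exon", "CDS"):
            continue
        try:
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: missing gene_id attribute") from exc
        start0, end0 = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if ftype == "gene":
            gene_spans[gid] = (feat.seqid, start0, end0)
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: missing transcript_id attribute") from exc
        if ftype == "exon":
            rec = exons.setdefault(
                tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
            )
            rec["exons"].append((start0, end0, lineno))
        elif ftype == "CDS":
            cds.setdefault(tid, []).append((start0, end0))

    models = []
    for tid in sorted(exons):
        rec = exons[tid]
        gid = rec["gene_id"]
        if gid in gene_spans:
            gchrom, gstart, gend = gene_spans[gid]
            for s, e, lineno in rec["exons"]:
                if rec["chrom"] != gchrom or s < gstart or e > gend:
                    raise ValueError(
                        f"{path}:{lineno}: exon {s}-{e} of {tid} outside the "
                        f"declared span of gene {gid}"
                    )
        exon_ivs = tuple(
            GenomicInterval(rec["chrom"], s, e, rec["strand"]) for s, e, _ in rec["exons"]
        )
        cds_span = None
        if tid in cds:
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
            cds_span = GenomicInterval(rec["chrom"], cs, ce, rec["strand"])
        models.append(TranscriptModel(gid, tid, rec["strand"], exon_ivs, cds_span))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (gene/transcript/exon/CDS features)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.span.start, m.transcript_id)):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = m.span

            def row(ftype: str, start: int, end: int) -> str:
                return (
                    f"{m.chrom}\tcardiosplice\t{ftype}\t{start + 1}\t{end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )

            fh.write(row("gene", span.start, span.end).replace(attrs, f'gene_id "{m.gene_id}";'))
            fh.write(row("transcript", span.start, span.end))
            for e in m.exons:
                fh.write(row("exon", e.start, e.end))
            if m.cds_span is not None:
                for e in m.exons:
                    s = max(e.start, m.cds_span.start)
                    en = min(e.end, m.cds_span.end)
                    if en > s:
                        fh.write(row("CDS", s, en))


def write_regions_bed(regions: Iterable[RegionAnnotation], path: str | Path) -> None:
    write_bed(
        [
            replace(r.interval, name=f"{r.transcript_id}:{r.category}")
            for r in regions
        ],
        path,
    )
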