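"""Genome annotation model and strand-aware interval arithmetic.

All coordinates are 0-based, half-open.  Minus-strand logic is done in
transcript orientation and mapped back to genomic coordinates; nothing in
this module is strand-naive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

Interval = tuple[int, int]

STRANDS = ("+", "-")

#: Region classes in precedence order (highest first).  A position carrying
#: several classes across overlapping transcripts is assigned the first one.
REGION_CLASSES = ("CDS", "5'UTR", "3'UTR", "ncRNA_exon", "intron", "intergenic")
_CLASS_CODE = {name: i for i, name in enumerate(REGION_CLASSES)}


@dataclass
class Transcript:
    """A transcript model: sorted non-overlapping exons plus optional CDS."""

    tx_id: str
    exons: list[Interval]
    tsl: int = 1
    cds: Interval | None = None

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.tx_id} has no exons")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(f"transcript {self.tx_id}: exons unsorted or overlapping")
        s, e = self.exons[0][0], self.exons[-1][1]
        if s >= e:
            raise ValueError(f"transcript {self.tx_id}: empty span")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, genomic order."""
        return [
            (e0, s1)
            for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
            if s1 > e0
        ]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    biotype: str = "coding"

    def validate(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for tx in self.transcripts:
            tx.validate()

    @property
    def span(self) -> Interval:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return (min(starts), max(ends))


@dataclass
class GenomeAnnotation:
    """Chromosome sequences plus gene models.

    ``chromosomes`` maps name -> nucleotide string (DNA or RNA alphabet,
    upper case).  Gene intervals must lie within their chromosome.
    """

    chromosomes: dict[str, str]
    genes: list[Gene]

    def validate(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name} has empty sequence")
        for gene in self.genes:
            gene.validate()
            if gene.chrom not in self.chromosomes:
                raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
            s, e = gene.span
            if s < 0 or e > len(self.chromosomes[gene.chrom]):
                raise ValueError(f"gene {gene.gene_id} exceeds chromosome bounds")

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class FlatFeature:
    """Disjoint exonic part, junction or intron derived from transcript models.

    For a junction the interval is the spanned intron; its two edges are the
    splice-site anchors.
    """

    feature_id: str
    gene_id: str
    kind: str  # exonic_part | junction | intron
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def anchors(self) -> tuple[int, int]:
        return (self.start, self.end)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals; overlapping or touching intervals are merged."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def cotranscribed_region(gene: Gene) -> list[Interval]:
    """Union of the gene's transcript spans (merged, genomic order).

    This is the randomization universe for crosslink-site significance and
    k-mer shuffles.  Strands are treated independently; overlapping genes on
    the opposite strand do not contribute.
    """
    gene.validate()
    return merge_intervals(t.span for t in gene.transcripts)


def flatten_features(annotation: GenomeAnnotation, tsl_max: int = 1) -> list[FlatFeature]:
    """Partition each gene's exon union into disjoint exonic parts, junctions
    and introns, keeping only transcripts with support level <= ``tsl_max``.

    Exonic parts are cut at every distinct exon boundary of the retained
    transcripts; one junction feature is emitted per distinct intron, and the
    same intervals are emitted again as intron features.  Genes whose
    retained-transcript set is empty are skipped with a warning.
    """
    if tsl_max < 1:
        raise ValueError("tsl_max must be >= 1")
    annotation.validate()
    features: list[FlatFeature] = []
    for gene in annotation.genes:
        kept = [t for t in gene.transcripts if t.tsl <= tsl_max]
        if not kept:
            warnings.warn(
                f"gene {gene.gene_id}: no transcript with TSL <= {tsl_max}; skipped",
                stacklevel=2,
            )
            continue
        exon_union = merge_intervals(iv for t in kept for iv in t.exons)
        boundaries = sorted({b for t in kept for iv in t.exons for b in iv})
        parts: list[Interval] = []
        for us, ue in exon_union:
            cuts = [b for b in boundaries if us < b < ue]
            edges = [us] + cuts + [ue]
            parts.extend((a, b) for a, b in zip(edges, edges[1:]))
        introns = sorted({iv for t in kept for iv in t.introns()})
        for i, (s, e) in enumerate(parts, start=1):
            features.append(
                FlatFeature(f"{gene.gene_id}:E{i:03d}", gene.gene_id, "exonic_part",
                            gene.chrom, s, e, gene.strand)
            )
        for i, (s, e) in enumerate(introns, start=1):
            features.append(
                FlatFeature(f"{gene.gene_id}:J{i:03d}", gene.gene_id, "junction",
                            gene.chrom, s, e, gene.strand)
            )
        for i, (s, e) in enumerate(introns, start=1):
            features.append(
                FlatFeature(f"{gene.gene_id}:I{i:03d}", gene.gene_id, "intron",
                            gene.chrom, s, e, gene.strand)
            )
    return features


def transcript_window(
    site_position: int,
    offsets: tuple[int, int],
    strand: str,
    bounds: Interval,
) -> list[Interval]:
    """Map a closed offset interval around a site into genomic coordinates.

    Offsets are in transcript orientation (negative = 5' of the site) and
    inclusive at both ends, so ``(-30, -5)`` covers 26 positions.  On the
    minus strand the window is mirrored.  The result is clipped to
    ``bounds``; a site outside bounds yields an empty list.
    """
    lo, hi = offsets
    if lo > hi:
        raise ValueError("offset interval reversed")
    if strand not in STRANDS:
        raise ValueError(f"bad strand {strand!r}")
    bs, be = bounds
    if not (bs <= site_position < be):
        return []
    if strand == "+":
        gs, ge = site_position + lo, site_position + hi + 1
    else:
        gs, ge = site_position - hi, site_position - lo + 1
    gs, ge = max(gs, bs), min(ge, be)
    if gs >= ge:
        return []
    return [(gs, ge)]


class RegionIndex:
    """Per-(chromosome, strand) nucleotide-level region-class assignment.

    Classes are assigned with the documented precedence
    CDS > 5'UTR > 3'UTR > ncRNA exon > intron > intergenic.
    """

    def __init__(self, annotation: GenomeAnnotation):
        annotation.validate()
        self._codes: dict[tuple[str, str], np.ndarray] = {}
        inter = _CLASS_CODE["intergenic"]
        for chrom, seq in annotation.chromosomes.items():
            for strand in STRANDS:
                self._codes[(chrom, strand)] = np.full(len(seq), inter, dtype=np.uint8)
        for gene in annotation.genes:
            arr = self._codes[(gene.chrom, gene.strand)]
            for tx in gene.transcripts:
                self._paint(arr, gene, tx)

    @staticmethod
    def _paint(arr: np.ndarray, gene: Gene, tx: Transcript) -> None:
        def assign(s: int, e: int, cls: str) -> None:
            code = _CLASS_CODE[cls]
            seg = arr[s:e]
            np.minimum(seg, code, out=seg)

        for s, e in tx.introns():
            assign(s, e, "intron")
        if gene.biotype != "coding" or tx.cds is None:
            for s, e in tx.exons:
                assign(s, e, "ncRNA_exon")
            return
        cs, ce = tx.cds
        for s, e in tx.exons:
            # split exon around the CDS interval, strand-aware UTR labels
            left = (max(s, 0), min(e, cs))
            mid = (max(s, cs), min(e, ce))
            right = (max(s, ce), e)
            if left[0] < left[1]:
                assign(*left, "5'UTR" if gene.strand == "+" else "3'UTR")
            if mid[0] < mid[1]:
                assign(*mid, "CDS")
            if right[0] < right[1]:
                assign(*right, "3'UTR" if gene.strand == "+" else "5'UTR")

    def classify(self, chrom: str, strand: str, position: int) -> str:
        return REGION_CLASSES[self._codes[(chrom, strand)][position]]

    def class_lengths(self) -> dict[str, int]:
        totals = np.zeros(len(REGION_CLASSES), dtype=np.int64)
        for arr in self._codes.values():
            totals += np.bincount(arr, minlength=len(REGION_CLASSES))
        return {name: int(totals[i]) for i, name in enumerate(REGION_CLASSES)}


def region_density(sites, annotation: GenomeAnnotation) -> dict[str, float]:
    """Sites-per-nucleotide density per region class.

    ``sites`` is any iterable of objects with chrom/strand/position
    attributes (a BindingSiteSet works).  Classes with zero length and zero
    sites are omitted; classes with length but no sites report density 0.
    """
    index = RegionIndex(annotation)
    counts: dict[str, int] = {name: 0 for name in REGION_CLASSES}
    site_list = list(sites)
    for site in site_list:
        counts[index.classify(site.chrom, site.strand, site.position)] += 1
    lengths = index.class_lengths()
    out: dict[str, float] = {}
    for name in REGION_CLASSES:
        if lengths[name] == 0:
            if counts[name] == 0:
                continue
            raise ValueError(f"sites assigned to zero-length class {name}")
        out[name] = counts[name] / lengths[name]
    assert sum(counts.values()) == len(site_list)
    return out


def region_site_counts(sites, annotation: GenomeAnnotation) -> dict[str, int]:
    """Raw per-class assigned site counts (auditability companion of
    :func:`region_density`)."""
    index = RegionIndex(annotation)
    counts: dict[str, int] = {name: 0 for name in REGION_CLASSES}
    for site in sites:
        counts[index.classify(site.chrom, site.strand, site.position)] += 1
    return counts
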