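"""Chromatin-class segmentation, overlapping genomic bins, and gene classification.

The genome is described by a partition into four chromatin classes --
``active`` (transcribed euchromatin), ``inactive`` (H3K27me2-coated,
untranscribed), ``PcG`` (Polycomb domains, H3K27me3-enriched and
PRE-containing), and ``Hp1`` (H3K9me3 heterochromatin).  A nine-state input
segmentation collapses onto these four classes.  For ChIP quantification the
genome is tiled with fixed-width windows (5 kb by default) that start every
``step`` bases (500 b), so consecutive windows overlap; each window is
assigned the single class that covers it entirely, or ``mixed`` (and is then
excluded from class-stratified statistics, slightly under-representing domain
edges).  PcG windows containing a PRE-binding-protein peak summit are flagged
separately.  Genes are reduced to the largest interval shared by all their
isoforms and classified with precedence PcG > active > inactive.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

CLASSES = ("active", "inactive", "PcG", "Hp1")
MIXED = "mixed"

#: collapse of the nine-state chromatin model onto four classes:
#: states 1-5 are flavours of active chromatin, 6 is the Polycomb
#: compartment, 7-8 are Hp1 heterochromatin, 9 is generally inactive.
NINE_TO_FOUR = {
    1: "active",
    2: "active",
    3: "active",
    4: "active",
    5: "active",
    6: "PcG",
    7: "Hp1",
    8: "Hp1",
    9: "inactive",
}


@dataclass(frozen=True)
class DomainSegment:
    """A genomic interval labeled with one chromatin class."""

    chrom: str
    start: int
    end: int
    cls: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid segment interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.cls not in CLASSES:
            raise ValueError(f"unknown chromatin class {self.cls!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomicBin:
    """A fixed-width, stepped window carrying at most one chromatin class.

    ``cls`` is one of the four classes, ``mixed``, or ``None`` before
    annotation.  ``pre_flag`` marks PcG bins containing a PRE summit and is
    never set on other classes.
    """

    chrom: str
    start: int
    end: int
    cls: str | None = None
    pre_flag: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class GeneModel:
    """A gene with isoforms collapsed to their shared interval.

    ``isoforms`` are (chrom, start, end) spans.  ``collapsed`` is the largest
    region shared by all isoforms, or ``None`` when their intersection is
    empty (such genes are excluded from class-stratified analyses).
    """

    gene_id: str
    isoforms: list[tuple[str, int, int]]
    collapsed: tuple[str, int, int] | None = None
    cls: str | None = None
    length_for_tpm: int = 0
    strand: str = "+"


@dataclass
class ExclusionMask:
    """Named interval sets removed from binning (blacklisted chromosomes,
    pericentric heterochromatin, hyper-amplified loci such as the chorion
    gene clusters)."""

    chromosomes: set[str] = field(default_factory=set)
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            for s, e in ivs:
                if s < 0 or e <= s:
                    raise ValueError(f"invalid mask interval {chrom}:{s}-{e}")
            self.intervals[chrom] = sorted(ivs)

    def excludes(self, chrom: str, start: int, end: int) -> bool:
        """True if the query overlaps any masked region by >= 1 base."""
        if chrom in self.chromosomes:
            return True
        for s, e in self.intervals.get(chrom, ()):
            if s >= end:
                break
            if e > start:
                return True
        return False


def simplify_states(segments_9state: Iterable) -> list[DomainSegment]:
    """Collapse a nine-state segmentation onto the four-class model.

    Accepts an iterable of ``(chrom, start, end, state)`` tuples (or objects
    with those attributes), with integer states 1-9, sorted within each
    chromosome.  Adjacent (touching) segments mapping to the same class are
    merged.
    """
    out: list[DomainSegment] = []
    for seg in segments_9state:
        if isinstance(seg, tuple):
            chrom, start, end, state = seg
        else:
            chrom, start, end, state = seg.chrom, seg.start, seg.end, seg.cls
        try:
            cls = NINE_TO_FOUR[int(state)]
        except (KeyError, ValueError, TypeError):
            raise ValueError(f"unknown chromatin state label {state!r}") from None
        if (
            out
            and out[-1].chrom == chrom
            and out[-1].cls == cls
            and out[-1].end == start
        ):
            out[-1] = DomainSegment(chrom, out[-1].start, end, cls)
        else:
            out.append(DomainSegment(chrom, start, end, cls))
    return out


def merge_adjacent(segments: Sequence[DomainSegment]) -> list[DomainSegment]:
    """Merge touching same-class segments (input sorted per chromosome)."""
    out: list[DomainSegment] = []
    for seg in segments:
        if (
            out
            and out[-1].chrom == seg.chrom
            and out[-1].cls == seg.cls
            and out[-1].end == seg.start
        ):
            out[-1] = DomainSegment(seg.chrom, out[-1].start, seg.end, seg.cls)
        else:
            out.append(seg)
    return out


def make_bins(
    chrom_sizes: dict[str, int],
    width: int = 5000,
    step: int = 500,
    mask: ExclusionMask | None = None,
) -> list[GenomicBin]:
    """Tile each chromosome with overlapping fixed-width windows.

    Windows start at 0, step, 2*step, ...; a window extending past the
    chromosome end is dropped, as is any window on a blacklisted chromosome
    or overlapping a masked interval (dropped entirely even on partial
    overlap).  On an unmasked chromosome of length L >= width this yields
    ``floor((L - width)/step) + 1`` windows.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    bins: list[GenomicBin] = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        if mask is not None and chrom in mask.chromosomes:
            continue
        for start in range(0, length - width + 1, step):
            if mask is not None and mask.excludes(chrom, start, start + width):
                continue
            bins.append(GenomicBin(chrom, start, start + width))
    return bins


def _segments_by_chrom(
    segments: Iterable[DomainSegment],
) -> dict[str, list[DomainSegment]]:
    by: dict[str, list[DomainSegment]] = {}
    for seg in segments:
        by.setdefault(seg.chrom, []).append(seg)
    for segs in by.values():
        segs.sort(key=lambda s: s.start)
    return by


def assign_bin_class(
    bin: GenomicBin, segments: Sequence[DomainSegment]
) -> str:
    """Return the unique class fully covering the bin, else ``mixed``.

    A bin overlapping two classes, or containing sequence not covered by any
    segment, is ``mixed``.  Segment input order is irrelevant.
    """
    segs = sorted(
        (s for s in segments if s.chrom == bin.chrom and s.end > bin.start and s.start < bin.end),
        key=lambda s: s.start,
    )
    classes: set[str] = set()
    pos = bin.start
    for seg in segs:
        if seg.start > pos:
            return MIXED  # uncovered gap
        classes.add(seg.cls)
        if len(classes) > 1:
            return MIXED
        pos = max(pos, seg.end)
        if pos >= bin.end:
            break
    if pos < bin.end or not classes:
        return MIXED
    return classes.pop()


def annotate_bins(
    bins: Sequence[GenomicBin], segments: Sequence[DomainSegment]
) -> list[GenomicBin]:
    """Assign a class to every bin (vectorized over sorted segments).

    Equivalent to calling :func:`assign_bin_class` per bin, but walks each
    chromosome's sorted segment list once.
    """
    by_chrom = _segments_by_chrom(segments)
    out = []
    for b in bins:
        segs = by_chrom.get(b.chrom, [])
        starts = [s.start for s in segs]
        # first segment that could overlap: last with start <= b.start
        i = bisect_right(starts, b.start) - 1
        if i < 0:
            i = 0
        cls = MIXED
        classes: set[str] = set()
        pos = b.start
        ok = True
        j = i
        while j < len(segs) and pos < b.end:
            seg = segs[j]
            if seg.end <= pos:
                j += 1
                continue
            if seg.start > pos:
                ok = False
                break
            classes.add(seg.cls)
            if len(classes) > 1:
                ok = False
                break
            pos = seg.end
            j += 1
        if ok and pos >= b.end and len(classes) == 1:
            cls = classes.pop()
        out.append(GenomicBin(b.chrom, b.start, b.end, cls, False))
    return out


def flag_pre_bins(
    bins: Sequence[GenomicBin], summits: Iterable[tuple[str, int]]
) -> list[GenomicBin]:
    """Flag PcG bins containing >= 1 peak summit position.

    ``summits`` is a composite list of (chrom, position) summit calls
    (deduplicated by position); half-open containment: a summit at
    ``bin.end`` does not flag the bin.  Non-PcG bins are never flagged.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in set(summits):
        by_chrom.setdefault(chrom, []).append(pos)
    for positions in by_chrom.values():
        positions.sort()
    out = []
    for b in bins:
        flag = False
        if b.cls == "PcG":
            positions = by_chrom.get(b.chrom, [])
            lo = bisect_left(positions, b.start)
            hi = bisect_left(positions, b.end)
            flag = hi > lo
        out.append(GenomicBin(b.chrom, b.start, b.end, b.cls, flag))
    return out


def collapse_isoforms(gene: GeneModel) -> tuple[str, int, int] | None:
    """Largest region shared by all isoforms of a gene (span intersection).

    Returns ``None`` when the isoform spans are disjoint.  Raises if
    isoforms sit on different chromosomes.
    """
    if not gene.isoforms:
        raise ValueError(f"gene {gene.gene_id} has no isoforms")
    chroms = {c for c, _, _ in gene.isoforms}
    if len(chroms) > 1:
        raise ValueError(
            f"gene {gene.gene_id} has isoforms on multiple chromosomes: {sorted(chroms)}"
        )
    chrom = chroms.pop()
    start = max(s for _, s, _ in gene.isoforms)
    end = min(e for _, _, e in gene.isoforms)
    if start >= end:
        return None
    return (chrom, start, end)


def classify_gene(
    collapsed: tuple[str, int, int], segments: Sequence[DomainSegment]
) -> str:
    """Classify a gene interval with precedence PcG > active > inactive.

    Any overlap (>= 1 base) with a PcG segment makes the gene PcG; otherwise
    any overlap with an active segment makes it active; otherwise it is
    inactive.  (Hp1 genes fall through to inactive; Hp1-specific analyses are
    out of scope here.)
    """
    chrom, start, end = collapsed
    if start >= end:
        raise ValueError("empty gene interval")
    hit: set[str] = set()
    for seg in segments:
        if seg.chrom == chrom and seg.start < end and seg.end > start:
            hit.add(seg.cls)
    if "PcG" in hit:
        return "PcG"
    if "active" in hit:
        return "active"
    return "inactive"


_SPAN_RE = re.compile(r"^([^:\s]+):(\d+)\.\.(\d+)$")


def domain_span_kb(coordinate_string: str) -> float:
    """Span of an ``ARM:START..END`` coordinate string, in kilobases.

    ``(END - START) / 1000``, the convention used for printed domain lengths.
    """
    m = _SPAN_RE.match(coordinate_string.strip())
    if not m:
        raise ValueError(f"malformed coordinate string {coordinate_string!r}")
    start, end = int(m.group(2)), int(m.group(3))
    if end <= start:
        raise ValueError(f"END must exceed START in {coordinate_string!r}")
    return (end - start) / 1000.0
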