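"""Core genomic data types and interval algebra.

Coordinates are 0-based, half-open throughout the package; GFF3/GTF I/O
converts to and from 1-based closed at the boundary (see :mod:`ltrscape.io`).
Every annotation carries one of three provenance tags — ``homology``,
``structural`` or ``secondary`` — naming the pipeline stage that produced it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

SOURCES = ("homology", "structural", "secondary")

#: Sentinel distance for elements on contigs without any annotated feature.
ND = None


class BoundsError(ValueError):
    """An interval extends beyond its chromosome."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic span: ``chrom``, 0-based inclusive ``start``, exclusive ``end``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to(self, other: "Interval") -> int:
        """Edge-to-edge gap in bp; 0 when overlapping; requires same chrom."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def overlap_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeIndex:
    """Ordered chromosome-name -> length map, with optional assembly gaps."""

    chromosomes: dict[str, int]
    assembly_gaps: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for gap in self.assembly_gaps:
            if gap.chrom not in self.chromosomes:
                raise BoundsError(f"gap on unknown chromosome {gap.chrom}")
            if gap.end > self.chromosomes[gap.chrom]:
                raise BoundsError(f"gap {gap} beyond chromosome end")

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    @property
    def assembled_length(self) -> int:
        """Total length minus assembly-gap bases."""
        gap = sum(len(g) for g in self.assembly_gaps)
        return self.total_length - gap

    def check(self, iv: Interval) -> None:
        if iv.chrom not in self.chromosomes:
            raise BoundsError(f"unknown chromosome in {iv}")
        if iv.end > self.chromosomes[iv.chrom]:
            raise BoundsError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chromosomes[iv.chrom]}"
            )


@dataclass
class Annotation:
    """An interval with pipeline provenance, a score and a free-text label."""

    interval: Interval
    source: str
    score: float | None = None
    label: str = ""
    id: str | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(
                f"source must be one of {SOURCES}, got {self.source!r}"
            )


class AnnotationSet:
    """A list of :class:`Annotation` records with lazy coordinate sorting."""

    def __init__(self, records: Iterable[Annotation] = ()) -> None:
        self.records: list[Annotation] = list(records)
        self._sorted = False

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def add(self, rec: Annotation) -> None:
        self.records.append(rec)
        self._sorted = False

    def sort(self) -> "AnnotationSet":
        self.records.sort(
            key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end)
        )
        self._sorted = True
        return self

    def intervals(self) -> list[Interval]:
        return [r.interval for r in self.records]

    def validate(self, genome: GenomeIndex) -> None:
        for rec in self.records:
            genome.check(rec.interval)

    def by_chrom(self) -> dict[str, list[Annotation]]:
        out: dict[str, list[Annotation]] = defaultdict(list)
        for rec in self.records:
            out[rec.interval.chrom].append(rec)
        return dict(out)

    def total_span(self) -> int:
        """Total bp covered (union, multiply-covered bases counted once)."""
        return sum(length for _, length in _union_segments(self.intervals()))


def _union_segments(ivs: Sequence[Interval]) -> list[tuple[str, int]]:
    """(chrom, length) for each maximal merged run of the input intervals."""
    by_chrom: dict[str, list[Interval]] = defaultdict(list)
    for iv in ivs:
        by_chrom[iv.chrom].append(iv)
    out = []
    for chrom, items in by_chrom.items():
        items.sort(key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = items[0].start, items[0].end
        for iv in items[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append((chrom, cur_e - cur_s))
                cur_s, cur_e = iv.start, iv.end
        out.append((chrom, cur_e - cur_s))
    return out


def merge_intervals(
    records: AnnotationSet,
    max_gap: int = 10,
    genome: GenomeIndex | None = None,
) -> AnnotationSet:
    """Merge annotations that overlap or lie within ``max_gap`` bp of each other.

    The default ``max_gap=10`` merges records fewer than 11 bp apart, the
    convention used when combining homology evidence tracks. Merging is
    strand-agnostic and transitive: chains of nearby records collapse into
    one. Each merged record keeps the provenance tag covering the most bases
    of the merged span and lists all contributing tags in
    ``attrs['sources']``.

    Parameters
    ----------
    records : AnnotationSet
    max_gap : int
        Largest inter-record gap (bp) that still merges; must be >= 0.
    genome : GenomeIndex, optional
        When given, every record is bounds-checked first.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if genome is not None:
        records.validate(genome)
    out = AnnotationSet()
    for chrom, items in sorted(records.by_chrom().items()):
        items = sorted(items, key=lambda r: (r.interval.start, r.interval.end))
        group: list[Annotation] = []
        cur_end = -1
        for rec in items:
            if group and rec.interval.start - cur_end > max_gap:
                out.add(_merge_group(chrom, group))
                group = []
            group.append(rec)
            cur_end = max(cur_end, rec.interval.end)
        if group:
            out.add(_merge_group(chrom, group))
    return out.sort()


def _merge_group(chrom: str, group: list[Annotation]) -> Annotation:
    if len(group) == 1:
        rec = group[0]
        return replace(rec, attrs=dict(rec.attrs, sources=(rec.source,)))
    start = min(r.interval.start for r in group)
    end = max(r.interval.end for r in group)
    # dominant source = most covered bases within the merged span
    cov: dict[str, int] = defaultdict(int)
    for r in group:
        cov[r.source] += len(r.interval)
    dominant = max(cov, key=lambda s: (cov[s], -SOURCES.index(s)))
    sources = tuple(sorted({r.source for r in group}, key=SOURCES.index))
    scores = [r.score for r in group if r.score is not None]
    return Annotation(
        interval=Interval(chrom, start, end),
        source=dominant,
        score=min(scores) if scores else None,
        label=";".join(sorted({r.label for r in group if r.label})),
        attrs={"sources": sources, "n_merged": len(group)},
    )


def strand_intersect(
    elements: AnnotationSet,
    features: AnnotationSet,
    mode: str = "any",
) -> list[tuple[Annotation, Annotation]]:
    """Report every (element, feature) pair sharing >= 1 bp.

    In ``same-orientation`` mode both records must carry equal, defined
    strands; unstranded records never match (conservative reading of
    orientation-restricted intersection).
    """
    if mode not in ("any", "same-orientation"):
        raise ValueError(f"unknown mode {mode!r}")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for feat in features:
        trees[feat.interval.chrom].addi(
            feat.interval.start, feat.interval.end, feat
        )
    pairs = []
    for el in elements:
        for hit in sorted(trees[el.interval.chrom].overlap(
            el.interval.start, el.interval.end
        )):
            feat = hit.data
            if mode == "same-orientation":
                if el.interval.strand == "." or feat.interval.strand == ".":
                    continue
                if el.interval.strand != feat.interval.strand:
                    continue
            pairs.append((el, feat))
    return pairs


def nearest_distance(
    element: Interval, features: AnnotationSet
) -> int | None:
    """Shortest edge-to-edge distance (bp) from ``element`` to any feature.

    Returns 0 when overlapping, and the non-defined marker ``None`` when the
    element's chromosome/contig carries no feature at all.
    """
    best: int | None = None
    for feat in features:
        if feat.interval.chrom != element.chrom:
            continue
        d = element.distance_to(feat.interval)
        if best is None or d < best:
            best = d
        if best == 0:
            break
    return best


def coverage_summary(
    sets: Mapping[str, AnnotationSet]
) -> dict:
    """Per-source, exclusive-category and union coverage in bp.

    Returns a dict with keys:

    ``per_source``
        source -> union bp covered by that source alone-or-shared.
    ``categories``
        frozenset of sources -> bp covered by exactly that combination.
        The exclusive categories partition the union.
    ``pairwise``
        (source_a, source_b) -> bp covered by both (regardless of others).
    ``union``
        total bp covered by any source.
    """
    # event sweep per chromosome with a per-source active counter
    events: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for source, aset in sets.items():
        for iv in aset.intervals():
            events[iv.chrom].append((iv.start, +1, source))
            events[iv.chrom].append((iv.end, -1, source))
    per_source: dict[str, int] = {s: 0 for s in sets}
    categories: dict[frozenset, int] = defaultdict(int)
    pairwise: dict[tuple[str, str], int] = defaultdict(int)
    union = 0
    names = sorted(sets)
    for chrom, evs in events.items():
        evs.sort(key=lambda e: (e[0], -e[1]))
        active: dict[str, int] = defaultdict(int)
        prev = None
        for pos, delta, source in evs:
            if prev is not None and pos > prev:
                live = frozenset(s for s, c in active.items() if c > 0)
                if live:
                    seg = pos - prev
                    union += seg
                    categories[live] += seg
                    for s in live:
                        per_source[s] += seg
                    for i, a in enumerate(names):
                        for b in names[i + 1:]:
                            if a in live and b in live:
                                pairwise[(a, b)] += seg
            active[source] += delta
            prev = pos
    return {
        "per_source": per_source,
        "categories": dict(categories),
        "pairwise": dict(pairwise),
        "union": union,
    }
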