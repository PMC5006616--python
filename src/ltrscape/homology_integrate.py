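"""Homology-evidence filtering, validation, merging and provenance accounting.

This stage turns raw homology evidence (BLAST-style hit tables, RepeatMasker
annotations) into a clean ``source=homology`` track, removes records whose
span is dominated by other repeat classes (e.g. CR1 LINEs picked up through
their reverse transcriptase), validates records against the reference LTR
retrotransposon library, expands the annotation with fragments related to
structurally intact elements (the secondary stage), and merges the three
provenance tracks into the final annotation with a coverage breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_model import (
    Annotation,
    AnnotationSet,
    Interval,
    coverage_summary,
    merge_intervals,
)

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "evalue",
    "bitscore", "sstart", "send", "sstrand",
]


@dataclass
class HomologyHit:
    query_id: str
    target: Interval
    e_value: float
    pct_identity: float  # fraction in [0, 1]
    aln_len: int
    tool: str = "blastn"
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value on hit {self.query_id}")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0 <= self.pct_identity <= 1:
            raise ValueError("pct_identity must be a fraction in [0, 1]")


@dataclass
class RepeatRecord:
    target: Interval
    repeat_name: str
    repeat_class: str
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not self.repeat_class:
            raise ValueError("repeat class must be non-empty")


@dataclass
class FilterParams:
    """Homology thresholds; boundaries are inclusive (E <= e_max passes)."""

    e_max: float = 1e-10
    min_hit_len: int = 100
    merge_gap: int = 10
    conflict_cov: float = 0.5
    dirs_rt_e: float = 1e-15
    dirs_aux_e: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("e_max", "min_hit_len", "dirs_rt_e", "dirs_aux_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.conflict_cov <= 1:
            raise ValueError("conflict_cov must be in (0, 1]")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


# ---------------------------------------------------------------- parsers

def read_blast_tsv(path) -> list[HomologyHit]:
    """BLAST tabular (outfmt 6 style) with subject coordinates.

    Expected columns: qseqid sseqid pident length evalue bitscore sstart
    send sstrand. Subject coordinates are 1-based closed and may be
    reversed for minus-strand hits.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS,
                     comment="#", dtype={"sseqid": str})
    hits = []
    for row in df.itertuples(index=False):
        s, e = int(row.sstart), int(row.send)
        strand = "+" if s <= e else "-"
        if str(row.sstrand) in ("+", "-"):
            strand = str(row.sstrand)
        lo, hi = min(s, e), max(s, e)
        hits.append(
            HomologyHit(
                query_id=str(row.qseqid),
                target=Interval(str(row.sseqid), lo - 1, hi, strand),
                e_value=float(row.evalue),
                pct_identity=float(row.pident) / 100.0,
                aln_len=int(row.length),
                bitscore=float(row.bitscore),
            )
        )
    return hits


def import_repeatmasker(path) -> tuple[AnnotationSet, AnnotationSet]:
    """Partition a RepeatMasker ``.out`` file into LTR-class vs other-class.

    Both partitions are returned: LTR-class records feed the homology track,
    the rest feed the conflict filter.
    """
    ltr, other = AnnotationSet(), AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            first = stripped.split()[0]
            if first in ("SW", "score") or stripped.startswith("There were"):
                continue  # header / footer lines
            cols = stripped.split()
            if len(cols) < 11:
                raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line")
            try:
                chrom = cols[4]
                start = int(cols[5]) - 1
                end = int(cols[6])
                strand = "-" if cols[8] in ("C", "-") else "+"
                name = cols[9]
                rclass = cols[10]
                divergence = float(cols[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed RepeatMasker line"
                ) from exc
            rec = Annotation(
                Interval(chrom, start, end, strand),
                source="homology",
                score=divergence,
                label=rclass,
                id=name,
            )
            (ltr if rclass.split("/")[0].upper() == "LTR" else other).add(rec)
    return ltr.sort(), other.sort()


# ---------------------------------------------------------------- filters

def filter_homology_hits(
    hits: list[HomologyHit], params: FilterParams | None = None
) -> AnnotationSet:
    """Keep hits with E <= e_max and alignment length >= min_hit_len."""
    params = params or FilterParams()
    out = AnnotationSet()
    for hit in hits:
        if hit.e_value <= params.e_max and hit.aln_len >= params.min_hit_len:
            out.add(
                Annotation(
                    hit.target,
                    source="homology",
                    score=hit.e_value,
                    label=hit.tool,
                    id=hit.query_id,
                )
            )
    return out.sort()


def apply_conflict_filter(
    elements: AnnotationSet,
    other_repeats: AnnotationSet,
    params: FilterParams | None = None,
) -> tuple[AnnotationSet, list[dict]]:
    """Drop elements whose span is mostly covered by non-LTR repeat classes.

    An element is removed when >= ``conflict_cov`` of its bases are covered
    by other-class records; removals are logged with the dominating class.
    """
    params = params or FilterParams()
    by_chrom: dict[str, list[Annotation]] = other_repeats.by_chrom()
    kept, removed = AnnotationSet(), []
    for el in elements:
        others = by_chrom.get(el.interval.chrom, [])
        # per-base coverage of the element span by other-class records
        cov_by_class: dict[str, int] = {}
        segs: list[tuple[int, int]] = []
        for o in others:
            ol = el.interval.overlap_length(o.interval)
            if ol:
                cov_by_class[o.label] = cov_by_class.get(o.label, 0) + ol
                segs.append(
                    (
                        max(el.interval.start, o.interval.start),
                        min(el.interval.end, o.interval.end),
                    )
                )
        covered = 0
        if segs:
            segs.sort()
            cs, ce = segs[0]
            for s, e in segs[1:]:
                if s <= ce:
                    ce = max(ce, e)
                else:
                    covered += ce - cs
                    cs, ce = s, e
            covered += ce - cs
        frac = covered / len(el.interval)
        if frac >= params.conflict_cov:
            removed.append(
                {
                    "id": el.id,
                    "interval": el.interval,
                    "coverage": frac,
                    "dominating_class": max(cov_by_class, key=cov_by_class.get),
                }
            )
        else:
            kept.add(el)
    return kept.sort(), removed


def reciprocal_validate(
    elements: AnnotationSet,
    library_hits: dict[str, HomologyHit],
    params: FilterParams | None = None,
) -> AnnotationSet:
    """Flag each element validated/unvalidated by its best reciprocal hit.

    Best hit = highest bitscore (ties: lowest E, then longest alignment);
    validated iff that hit passes ``e_max``. Unvalidated elements stay in
    the set but are retained at finalization only with structural support.
    """
    params = params or FilterParams()
    out = AnnotationSet()
    for el in elements:
        hit = library_hits.get(el.id) if el.id else None
        validated = hit is not None and hit.e_value <= params.e_max
        el.attrs = dict(el.attrs, validated=validated)
        out.add(el)
    return out.sort()


def best_reciprocal_hits(
    hits_by_element: dict[str, list[HomologyHit]]
) -> dict[str, HomologyHit]:
    """Reduce per-element reciprocal hit lists to the single best hit."""
    best = {}
    for el_id, hits in hits_by_element.items():
        if hits:
            best[el_id] = sorted(
                hits, key=lambda h: (-h.bitscore, h.e_value, -h.aln_len)
            )[0]
    return best


def call_dirs(domain_hits: list, params: FilterParams | None = None) -> bool:
    """DIRS acceptance: RT at E <= 1e-15 plus MT or YR at E <= 1e-12."""
    params = params or FilterParams()
    has_rt = any(
        h.domain == "RT" and h.e_value <= params.dirs_rt_e for h in domain_hits
    )
    has_aux = any(
        h.domain in ("MT", "YR") and h.e_value <= params.dirs_aux_e
        for h in domain_hits
    )
    return has_rt and has_aux


# ---------------------------------------------------------------- secondary stage

def secondary_expand(
    genome_hits: list[HomologyHit],
    existing: AnnotationSet,
    params: FilterParams | None = None,
) -> AnnotationSet:
    """Turn SIE-vs-genome hits into ``source=secondary`` records.

    Hits inherit the primary E-value/length filters; a hit entirely inside
    an already-annotated region is absorbed (no new record). Each new record
    carries its query SIE id.
    """
    params = params or FilterParams()
    existing_by_chrom = existing.by_chrom()
    out = AnnotationSet()
    for hit in genome_hits:
        if hit.e_value > params.e_max or hit.aln_len < params.min_hit_len:
            continue
        absorbed = any(
            rec.interval.contains(hit.target)
            for rec in existing_by_chrom.get(hit.target.chrom, [])
        )
        if absorbed:
            continue
        out.add(
            Annotation(
                hit.target,
                source="secondary",
                score=hit.e_value,
                label="secondary",
                id=None,
                attrs={"query_sie": hit.query_id},
            )
        )
    return out.sort()


# ---------------------------------------------------------------- finalize

@dataclass
class ProvenanceReport:
    """Fig.-2-style accounting: bp per provenance combination."""

    per_source: dict
    categories: dict
    union: int
    dropped_unvalidated: list = field(default_factory=list)


def finalize_annotation(
    homology: AnnotationSet,
    structural: AnnotationSet,
    secondary: AnnotationSet,
    params: FilterParams | None = None,
) -> tuple[AnnotationSet, ProvenanceReport]:
    """Merge the three provenance tracks into the final annotation.

    Homology records flagged unvalidated by the reciprocal search are
    dropped (and logged) unless they overlap structural evidence; the
    survivors are unioned with ``merge_intervals`` and the coverage table is
    computed over the three input tracks.
    """
    params = params or FilterParams()
    structural_by_chrom = structural.by_chrom()
    kept_homology = AnnotationSet()
    dropped = []
    for rec in homology:
        if rec.attrs.get("validated", True):
            kept_homology.add(rec)
            continue
        supported = any(
            rec.interval.overlaps(s.interval)
            for s in structural_by_chrom.get(rec.interval.chrom, [])
        )
        if supported:
            kept_homology.add(rec)
        else:
            dropped.append({"id": rec.id, "interval": rec.interval})
    combined = AnnotationSet(
        list(kept_homology) + list(structural) + list(secondary)
    )
    final = merge_intervals(combined, max_gap=params.merge_gap)
    cov = coverage_summary(
        {
            "homology": kept_homology,
            "structural": structural,
            "secondary": secondary,
        }
    )
    report = ProvenanceReport(
        per_source=cov["per_source"],
        categories=cov["categories"],
        union=cov["union"],
        dropped_unvalidated=dropped,
    )
    return final, report
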