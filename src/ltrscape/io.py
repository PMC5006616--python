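"""Readers and writers for the standard text formats at the package boundary.

Internally everything is 0-based half-open. BED is native; GFF3/GTF columns 4-5
are converted to/from 1-based closed here and nowhere else.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import Annotation, AnnotationSet, GenomeIndex, Interval


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    try:
        return {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
    except OSError as exc:
        raise IOError(f"cannot read FASTA {path}: {exc}") from exc


def write_fasta(path: str | os.PathLike, seqs: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def genome_index_from_fasta(path: str | os.PathLike) -> GenomeIndex:
    return GenomeIndex(
        {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


# ---------------------------------------------------------------- BED6

def write_bed6(path: str | os.PathLike, records: AnnotationSet) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            name = rec.id or rec.label or f"rec{i}"
            score = 0 if rec.score is None else rec.score
            fh.write(
                f"{rec.interval.chrom}\t{rec.interval.start}\t{rec.interval.end}"
                f"\t{name}\t{score}\t{rec.interval.strand}\n"
            )


def read_bed6(path: str | os.PathLike, source: str = "homology") -> AnnotationSet:
    out = AnnotationSet()
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in ("+", "-") else "."
        out.add(
            Annotation(
                Interval(str(row.chrom), int(row.start), int(row.end), strand),
                source=source,
                score=float(row.score),
                id=str(row.name),
            )
        )
    return out


# ---------------------------------------------------------------- GFF3

def _fmt_attrs(rec: Annotation, i: int) -> str:
    parts = [f"ID={rec.id or f'rec{i}'}"]
    if rec.label:
        parts.append(f"label={rec.label}")
    for key, val in sorted(rec.attrs.items()):
        if isinstance(val, (tuple, list)):
            val = ",".join(str(v) for v in val)
        parts.append(f"{key}={val}")
    return ";".join(parts)


def write_gff3(
    path: str | os.PathLike,
    records: AnnotationSet,
    feature_type: str = "LTR_retrotransposon",
) -> None:
    """Write annotations with their provenance tag in GFF3 column 2."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, rec in enumerate(records):
            score = "." if rec.score is None else f"{rec.score:g}"
            fh.write(
                "\t".join(
                    [
                        rec.interval.chrom,
                        rec.source,
                        feature_type,
                        str(rec.interval.start + 1),
                        str(rec.interval.end),
                        score,
                        rec.interval.strand if rec.interval.strand != "." else ".",
                        ".",
                        _fmt_attrs(rec, i),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    """Read a flat annotation GFF3 written by this package (or compatible)."""
    out = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            chrom, source, _ftype, start, end, score, strand, _, attrs = cols
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = v
            out.add(
                Annotation(
                    Interval(
                        chrom,
                        int(start) - 1,
                        int(end),
                        strand if strand in ("+", "-") else ".",
                    ),
                    source=source if source in ("homology", "structural", "secondary") else "homology",
                    score=None if score == "." else float(score),
                    label=attr_map.get("label", ""),
                    id=attr_map.get("ID"),
                    attrs={
                        k: v for k, v in attr_map.items() if k not in ("ID", "label")
                    },
                )
            )
    return out


# ---------------------------------------------------------------- GTF transcripts

def write_transcript_gtf(
    path: str | os.PathLike,
    transcripts: Iterable[tuple[str, str, Interval]],
) -> None:
    """Write (tissue, transcript_id, span) triples as single-exon GTF models."""
    with open(path, "w") as fh:
        for tissue, tid, iv in transcripts:
            attrs = (
                f'gene_id "{tid}"; transcript_id "{tid}"; tissue "{tissue}";'
            )
            for ftype in ("transcript", "exon"):
                fh.write(
                    f"{iv.chrom}\tltrscape\t{ftype}\t{iv.start + 1}\t{iv.end}\t."
                    f"\t{iv.strand}\t.\t{attrs}\n"
                )


def read_transcript_gtf(
    path: str | os.PathLike,
) -> dict[str, AnnotationSet]:
    """Transcript spans grouped by tissue (from the ``tissue`` GTF attribute).

    Transcripts with no tissue attribute land under tissue ``"all"``.
    """
    by_tissue: dict[str, AnnotationSet] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[2] != "transcript":
                continue
            attrs = _parse_gtf_attrs(cols[8])
            tissue = attrs.get("tissue", "all")
            strand = cols[6] if cols[6] in ("+", "-") else "."
            by_tissue.setdefault(tissue, AnnotationSet()).add(
                Annotation(
                    Interval(cols[0], int(cols[3]) - 1, int(cols[4]), strand),
                    source="homology",
                    id=attrs.get("transcript_id"),
                    label="transcript",
                )
            )
    return by_tissue


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if " " in item:
            k, v = item.split(" ", 1)
            out[k] = v.strip().strip('"')
    return out


# ---------------------------------------------------------------- recombination map

def write_recomb_map(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_recomb_map(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with columns chrom, start, end, rate (cM/Mb)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = {"chrom", "start", "end", "rate"}
    if not expected.issubset(df.columns):
        raise ValueError(f"recombination map needs columns {sorted(expected)}")
    if (df["rate"] < 0).any():
        raise ValueError("negative recombination rate")
    return df
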