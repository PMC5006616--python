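"""Synthetic genomes with planted truth for exercising the whole pipeline.

The generator emulates the inputs an annotation run consumes — a
multi-chromosome genome with planted intact elements (controlled LTR
divergence, TG...CA termini, TSDs, PBS/PPT motifs, lineage-tagged internal
domain placeholders), planted fragments derived from those elements,
BLAST-style hit tables with synthetic E-values, gene models with exon/UTR
structure, stranded transcripts, a binned recombination map and a tRNA set —
together with a truth table for recovery testing. Background sequence is
i.i.d. with configurable GC; divergence between the two planted LTR copies is
split symmetrically (each copy mutated at d/2) so the pair diverges by ~d,
matching the dating model's assumption of independent post-insertion
lineages.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import Annotation, AnnotationSet, GenomeIndex, Interval
from .distribution_stats import TUModel
from .homology_integrate import HomologyHit

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate(b"ACGT")}

POLYA_MOTIF = b"AATAAA"
PPT_RUN = b"AGGAGGGGGAGGG"  # 13 bp, 13 purines

DOMAIN_LENGTHS = {"gag": 240, "pro": 120, "RT": 330, "RNaseH": 150, "IN": 210}

DEFAULT_LINEAGES = (
    "alpharetrovirus",
    "betaretrovirus",
    "gammaretrovirus",
    "Ty3/Gypsy",
)


def _rng_for(label: str, seed: int) -> np.random.Generator:
    """Deterministic child generator keyed by a stable string label."""
    return np.random.default_rng((zlib.crc32(label.encode()) + seed) % 2**31)


def _random_seq_arr(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _BASES[rng.choice(4, size=n, p=p)]


def _arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        lut[a] = b
    return lut[arr][::-1]


def mutate_sequence(
    seq: str,
    d: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    indel_rate: float = 0.0,
) -> str:
    """Mutate a copy of ``seq``: per-site substitution probability ``d``.

    Substituted sites take one of the three alternative bases uniformly.
    ``indel_rate`` adds per-site single-base insertions/deletions (half
    each). Seeded and deterministic.
    """
    if not 0 <= d <= 1:
        raise ValueError("divergence d must be in [0, 1]")
    if indel_rate < 0:
        raise ValueError("indel_rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = _arr(seq)
    sites = np.flatnonzero(rng.random(len(arr)) < d)
    if sites.size:
        idx = np.array([_BASE_INDEX.get(b, 0) for b in arr[sites]])
        arr[sites] = _BASES[(idx + rng.integers(1, 4, size=sites.size)) % 4]
    if indel_rate > 0:
        out = bytearray()
        events = rng.random(len(arr))
        kinds = rng.random(len(arr))
        inserts = _BASES[rng.integers(0, 4, size=len(arr))]
        for i, b in enumerate(arr):
            if events[i] < indel_rate:
                if kinds[i] < 0.5:
                    continue  # deletion
                out.append(inserts[i])
            out.append(b)
        return out.decode()
    return _to_str(arr)


def domain_template(lineage: str, domain: str, seed: int = 7) -> str:
    """Deterministic placeholder sequence for a (lineage, domain) pair."""
    length = DOMAIN_LENGTHS.get(domain, 200)
    rng = _rng_for(f"domain:{lineage}:{domain}", seed)
    return _to_str(_random_seq_arr(length, 0.45, rng))


# ---------------------------------------------------------------- config & truth

@dataclass
class SimulationConfig:
    """Desk-scale study conditions: a 2 Mb two-chromosome genome with 10
    intact elements, 50 fragments and 40 genes by default."""

    chromosome_lengths: tuple = (1_200_000, 800_000)
    gc: float = 0.42
    n_sie: int = 10
    divergences: tuple | None = None  # cycled over elements; None -> default grid
    ltr_len_range: tuple = (250, 400)
    internal_len_range: tuple = (2000, 5000)
    n_fragments: int = 50
    fragment_divergence: float = 0.15
    fragment_len_range: tuple = (80, 800)
    n_genes: int = 40
    gene_len_range: tuple = (3000, 15000)
    exon_count_range: tuple = (2, 8)
    n_trna: int = 5
    lineages: tuple = DEFAULT_LINEAGES
    cluster_plantings: list | None = None  # [(chrom, (start, end), count), ...]
    recomb_bin: int = 500_000
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("n_sie", "n_fragments", "n_genes", "n_trna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.divergences is not None and any(
            not 0 <= d <= 1 for d in self.divergences
        ):
            raise ValueError("divergences must lie in [0, 1]")

    @property
    def divergence_grid(self) -> tuple:
        if self.divergences is not None:
            return tuple(self.divergences)
        return (0.0, 0.02, 0.05, 0.08, 0.10, 0.12, 0.15)


@dataclass
class TruthRecord:
    id: str
    type: str  # "SIE" | "fragment" | "gene" | "tRNA"
    chrom: str
    start: int
    end: int
    strand: str
    divergence: float | None = None
    lineage: str | None = None
    tsd: str | None = None
    ltr5: tuple | None = None  # genomic (start, end) of the left LTR
    ltr3: tuple | None = None
    internal: tuple | None = None
    source_id: str | None = None  # for fragments: the template SIE
    expression: str | None = None  # planted expression status for SIEs


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: dict[str, str]
    index: GenomeIndex
    truth: list[TruthRecord]
    tus: list[TUModel]
    transcripts: dict[str, AnnotationSet]
    recomb_map: pd.DataFrame
    blast_hits: list[HomologyHit]
    trnas: dict[str, str]
    reference_library: dict[str, str]
    lineage_map: dict[str, str]

    def truth_of_type(self, kind: str) -> list[TruthRecord]:
        return [t for t in self.truth if t.type == kind]


def synthetic_evalue(identity: float, length: int) -> float:
    """Declining function of identity x length standing in for a real E-value.

    Synthetic: only its ordering and threshold behaviour matter downstream.
    """
    exponent = identity * length / 5.0
    return max(10.0 ** -min(exponent, 180.0), 1e-180)


# ---------------------------------------------------------------- planting

class _Placer:
    """Non-overlapping placement with a safety margin per chromosome."""

    def __init__(self, lengths: dict[str, int], rng, margin: int = 200):
        self.lengths = lengths
        self.rng = rng
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in lengths
        }

    def place(
        self, size: int, chrom: str | None = None,
        span: tuple[int, int] | None = None, tries: int = 2000,
    ) -> tuple[str, int]:
        chroms = list(self.lengths)
        weights = np.array([self.lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(tries):
            c = chrom or chroms[self.rng.choice(len(chroms), p=weights)]
            lo, hi = self.margin, self.lengths[c] - size - self.margin
            if span is not None:
                lo, hi = max(lo, span[0]), min(hi, span[1] - size)
            if hi <= lo:
                continue
            pos = int(self.rng.integers(lo, hi))
            a, b = pos - self.margin, pos + size + self.margin
            if all(b <= s or a >= e for s, e in self.occupied[c]):
                self.occupied[c].append((a, b))
                return c, pos
        raise RuntimeError(
            f"infeasible planting density on chromosome {chrom or 'any'}"
        )


def build_element_template(
    lineage: str, ltr_len: int, internal_len: int, trna: str, seed: int,
    instance: str = "canonical",
) -> tuple[str, str]:
    """(LTR template, internal template) for one element family.

    The LTR starts TG, ends CA and carries an AATAAA motif; the internal
    region opens with a PBS (reverse complement of the tRNA 3' 18-mer),
    closes with a polypurine run, and embeds the lineage's domain
    placeholder sequences. The LTR and domain blocks are shared across the
    family; the internal filler is unique per ``instance`` so distinct
    insertions of one family do not share their whole internal region.
    """
    ltr_rng = _rng_for(f"ltr:{lineage}:{seed}", seed)
    rng = _rng_for(f"template:{lineage}:{instance}:{seed}", seed)
    ltr = _random_seq_arr(ltr_len, 0.45, ltr_rng)
    ltr[:2] = np.frombuffer(b"TG", dtype=np.uint8)
    ltr[-2:] = np.frombuffer(b"CA", dtype=np.uint8)
    mid = ltr_len // 2
    ltr[mid:mid + 6] = np.frombuffer(POLYA_MOTIF, dtype=np.uint8)
    from .structural_detect import revcomp

    pbs = _arr(revcomp(trna[-18:]))
    domains = b"".join(
        domain_template(lineage, dom, seed).encode() for dom in DOMAIN_LENGTHS
    )
    fixed = 2 + len(pbs) + len(domains) + len(PPT_RUN)
    filler_len = max(internal_len - fixed, 50)
    filler = _random_seq_arr(filler_len, 0.45, rng)
    internal = np.concatenate(
        [
            _arr("TT"),
            pbs,
            filler[: filler_len // 2],
            np.frombuffer(domains, dtype=np.uint8),
            filler[filler_len // 2:],
            np.frombuffer(PPT_RUN, dtype=np.uint8),
        ]
    )
    return _to_str(ltr), _to_str(internal)


def plant_element(
    chrom_arr: np.ndarray,
    pos: int,
    ltr_template: str,
    internal_template: str,
    d: float,
    rng: np.random.Generator,
    strand: str = "+",
) -> dict:
    """Write one element (LTR + internal + LTR, TSD outside) into the draft.

    Each LTR copy is independently mutated at d/2; the internal region at
    d/2. Returns the element geometry for the truth table.
    """
    ltr5 = mutate_sequence(ltr_template, d / 2, rng=rng)
    ltr3 = mutate_sequence(ltr_template, d / 2, rng=rng)
    internal = mutate_sequence(internal_template, d / 2, rng=rng)
    element = _arr(ltr5 + internal + ltr3)
    if strand == "-":
        element = _revcomp_arr(element)
    total = len(element)
    if pos < 6 or pos + total + 6 > len(chrom_arr):
        raise ValueError("position does not admit the full element plus TSD")
    tsd_len = int(rng.integers(4, 7))
    tsd = _random_seq_arr(tsd_len, 0.5, rng)
    chrom_arr[pos:pos + total] = element
    chrom_arr[pos - tsd_len:pos] = tsd
    chrom_arr[pos + total:pos + total + tsd_len] = tsd
    n_ltr, n_int = len(ltr_template), len(internal)
    if strand == "-":
        # genomic left LTR is the element's 3' LTR after reverse complement
        left_len, right_len = len(ltr3), len(ltr5)
    else:
        left_len, right_len = len(ltr5), len(ltr3)
    return {
        "start": pos,
        "end": pos + total,
        "ltr5": (pos, pos + left_len),
        "ltr3": (pos + total - right_len, pos + total),
        "internal": (pos + left_len, pos + total - right_len),
        "tsd": tsd.tobytes().decode(),
        "element_seq": _to_str(element),
    }


# ---------------------------------------------------------------- gene models

def _make_gene(
    gene_id: str, chrom: str, pos: int, length: int, strand: str,
    n_exons: int, rng,
) -> TUModel:
    span = Interval(chrom, pos, pos + length, strand)
    # exon boundaries: alternate exon/intron blocks spanning the gene
    cuts = np.sort(rng.choice(
        np.arange(100, length - 100), size=2 * n_exons - 2, replace=False
    ))
    bounds = [0, *cuts.tolist(), length]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = pos + bounds[i], pos + bounds[i + 1]
        if e > s:
            exons.append(Interval(chrom, s, e, strand))
    first, last = exons[0], exons[-1]
    utr_a = Interval(chrom, first.start, first.start + max(len(first) // 3, 1), strand)
    utr_b = Interval(chrom, last.end - max(len(last) // 3, 1), last.end, strand)
    utr5, utr3 = (utr_a, utr_b) if strand == "+" else (utr_b, utr_a)
    return TUModel(
        gene_id=gene_id,
        biotype="protein_coding" if rng.random() < 0.85 else "RNA",
        span=span, exons=exons, utr5=utr5, utr3=utr3,
    )


def write_gene_gff3(path, tus: list[TUModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tu in tus:
            s = tu.span
            fh.write(
                f"{s.chrom}\tltrscape\tgene\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand}\t.\tID={tu.gene_id};biotype={tu.biotype}\n"
            )
            for i, ex in enumerate(tu.exons):
                fh.write(
                    f"{ex.chrom}\tltrscape\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={tu.gene_id}.e{i};Parent={tu.gene_id}\n"
                )
            for name, utr in (("five_prime_UTR", tu.utr5), ("three_prime_UTR", tu.utr3)):
                if utr is not None:
                    fh.write(
                        f"{utr.chrom}\tltrscape\t{name}\t{utr.start + 1}\t{utr.end}"
                        f"\t.\t{utr.strand}\t.\tID={tu.gene_id}.{name};Parent={tu.gene_id}\n"
                    )


# ---------------------------------------------------------------- main generator

def simulate_genome(
    config: SimulationConfig, outdir: str | os.PathLike | None = None
) -> SimulationResult:
    """Generate a genome plus every companion file the pipeline consumes.

    Deterministic under ``config.seed``: the same config produces
    byte-identical outputs. When ``outdir`` is given, writes genome.fa,
    trna.fa, genes.gff3, transcripts.gtf, recomb.tsv, hits.tsv, refs.fa,
    lineage_map.tsv and truth.json there.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chromosome_lengths))]
    lengths = dict(zip(chrom_names, config.chromosome_lengths))
    arrays = {
        c: _random_seq_arr(lengths[c], config.gc, rng) for c in chrom_names
    }
    placer = _Placer(lengths, rng)
    truth: list[TruthRecord] = []

    trnas = {
        f"tRNA{i + 1}": _to_str(_random_seq_arr(76, 0.5, _rng_for(f"trna{i}", config.seed)))
        for i in range(config.n_trna)
    }

    # one template family per lineage; reference library carries lineage labels
    grid = config.divergence_grid
    lineage_cycle = config.lineages
    templates = {}
    reference_library: dict[str, str] = {}
    lineage_map: dict[str, str] = {}
    trna_names = list(trnas)
    for li, lineage in enumerate(lineage_cycle):
        ltr_len = int(rng.integers(*config.ltr_len_range))
        internal_len = int(rng.integers(*config.internal_len_range))
        trna = trnas[trna_names[li % len(trna_names)]] if trnas else "A" * 76
        ltr_t, int_t = build_element_template(
            lineage, ltr_len, internal_len, trna, config.seed
        )
        templates[lineage] = (ltr_t, int_t)
        ref_id = f"ref_{lineage.replace('/', '_')}"
        reference_library[ref_id] = ltr_t + int_t + ltr_t
        lineage_map[ref_id] = lineage

    # --- intact elements (plus optional forced cluster plantings)
    plant_specs: list[tuple[str | None, tuple | None]] = [
        (None, None)
    ] * config.n_sie
    for chrom, span, count in config.cluster_plantings or []:
        plant_specs.extend([(chrom, tuple(span))] * count)
    expression_cycle = ("complete", "partial", "none")
    trna_by_lineage = {
        lineage: trnas[trna_names[li % len(trna_names)]] if trnas else "A" * 76
        for li, lineage in enumerate(lineage_cycle)
    }
    for i, (chrom_req, span_req) in enumerate(plant_specs):
        lineage = lineage_cycle[i % len(lineage_cycle)]
        d = grid[i % len(grid)]
        ltr_t, canonical_int = templates[lineage]
        _, int_t = build_element_template(
            lineage, len(ltr_t), len(canonical_int),
            trna_by_lineage[lineage], config.seed, instance=f"sie{i}",
        )
        total = 2 * len(ltr_t) + len(int_t)
        chrom, pos = placer.place(total + 12, chrom=chrom_req, span=span_req)
        strand = "+" if i % 3 else "-"
        geom = plant_element(
            arrays[chrom], pos + 6, ltr_t, int_t, d, rng, strand=strand
        )
        truth.append(
            TruthRecord(
                id=f"sie{i + 1:03d}", type="SIE", chrom=chrom,
                start=geom["start"], end=geom["end"], strand=strand,
                divergence=d, lineage=lineage, tsd=geom["tsd"],
                ltr5=geom["ltr5"], ltr3=geom["ltr3"],
                internal=geom["internal"],
                expression=expression_cycle[i % len(expression_cycle)],
            )
        )

    # --- fragments derived from the element templates
    blast_hits: list[HomologyHit] = []
    sies = [t for t in truth if t.type == "SIE"]
    for j in range(config.n_fragments):
        src = sies[j % len(sies)] if sies else None
        lineage = src.lineage if src else lineage_cycle[j % len(lineage_cycle)]
        ltr_t, int_t = templates[lineage]
        template_seq = ltr_t + int_t + ltr_t
        flen = int(rng.integers(*config.fragment_len_range))
        flen = min(flen, len(template_seq))
        off = int(rng.integers(0, len(template_seq) - flen + 1))
        d_frag = float(rng.uniform(0, config.fragment_divergence))
        frag = mutate_sequence(template_seq[off:off + flen], d_frag, rng=rng)
        chrom, pos = placer.place(flen)
        arrays[chrom][pos:pos + flen] = _arr(frag)
        identity = 1.0 - d_frag
        truth.append(
            TruthRecord(
                id=f"frag{j + 1:03d}", type="fragment", chrom=chrom,
                start=pos, end=pos + flen, strand="+",
                divergence=d_frag, lineage=lineage,
                source_id=src.id if src else None,
            )
        )
        blast_hits.append(
            HomologyHit(
                query_id=src.id if src else f"ref_{lineage.replace('/', '_')}",
                target=Interval(chrom, pos, pos + flen, "+"),
                e_value=synthetic_evalue(identity, flen),
                pct_identity=identity,
                aln_len=flen,
                tool="blastn",
                bitscore=identity * flen,
            )
        )

    # --- gene models
    tus: list[TUModel] = []
    for g in range(config.n_genes):
        glen = int(rng.integers(*config.gene_len_range))
        n_exons = int(rng.integers(*config.exon_count_range))
        chrom, pos = placer.place(glen)
        strand = "+" if rng.random() < 0.5 else "-"
        tu = _make_gene(f"gene{g + 1:03d}", chrom, pos, glen, strand, n_exons, rng)
        tus.append(tu)
        truth.append(
            TruthRecord(
                id=tu.gene_id, type="gene", chrom=chrom,
                start=pos, end=pos + glen, strand=strand,
            )
        )

    # --- transcripts matching each SIE's planted expression status
    tissues = ("embryo", "ovary", "pancreas")
    transcripts: dict[str, AnnotationSet] = {t: AnnotationSet() for t in tissues}
    for t in sies:
        tissue = tissues[int(rng.integers(0, len(tissues)))]
        a, b = t.internal
        if t.expression == "complete":
            iv = Interval(t.chrom, max(0, a - 50), b + 50, t.strand)
        elif t.expression == "partial":
            iv = Interval(t.chrom, a, a + max((b - a) // 2, 1), t.strand)
        else:
            continue
        transcripts[tissue].add(
            Annotation(iv, source="homology", id=f"tx_{t.id}", label="transcript")
        )
    # background transcripts from genes
    for tu in tus[: max(len(tus) // 2, 1)]:
        tissue = tissues[int(rng.integers(0, len(tissues)))]
        transcripts[tissue].add(
            Annotation(
                Interval(tu.span.chrom, tu.span.start, tu.span.end, tu.span.strand),
                source="homology", id=f"tx_{tu.gene_id}", label="transcript",
            )
        )

    # --- recombination map: 500 kb bins, lognormal rates
    rows = []
    for chrom in chrom_names:
        for s in range(0, lengths[chrom], config.recomb_bin):
            e = min(s + config.recomb_bin, lengths[chrom])
            rows.append(
                {
                    "chrom": chrom, "start": s, "end": e,
                    "rate": float(rng.lognormal(mean=0.5, sigma=0.6)),
                }
            )
    recomb_map = pd.DataFrame(rows)

    genome = {c: _to_str(arrays[c]) for c in chrom_names}
    result = SimulationResult(
        config=config,
        genome=genome,
        index=GenomeIndex(dict(lengths)),
        truth=truth,
        tus=tus,
        transcripts=transcripts,
        recomb_map=recomb_map,
        blast_hits=blast_hits,
        trnas=trnas,
        reference_library=reference_library,
        lineage_map=lineage_map,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: SimulationResult, outdir) -> None:
    from . import io as lio

    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    lio.write_fasta(j("genome.fa"), result.genome)
    lio.write_fasta(j("trna.fa"), result.trnas)
    lio.write_fasta(j("refs.fa"), result.reference_library)
    with open(j("lineage_map.tsv"), "w") as fh:
        for ref, lineage in result.lineage_map.items():
            fh.write(f"{ref}\t{lineage}\n")
    write_gene_gff3(j("genes.gff3"), result.tus)
    triples = [
        (tissue, rec.id, rec.interval)
        for tissue, aset in sorted(result.transcripts.items())
        for rec in aset
    ]
    lio.write_transcript_gtf(j("transcripts.gtf"), triples)
    lio.write_recomb_map(j("recomb.tsv"), result.recomb_map)
    with open(j("hits.tsv"), "w") as fh:
        for h in result.blast_hits:
            fh.write(
                f"{h.query_id}\t{h.target.chrom}\t{h.pct_identity * 100:.2f}\t"
                f"{h.aln_len}\t{h.e_value:.3e}\t{h.bitscore:.1f}\t"
                f"{h.target.start + 1}\t{h.target.end}\t{h.target.strand}\n"
            )
    with open(j("truth.json"), "w") as fh:
        json.dump(
            [dataclasses.asdict(t) for t in result.truth],
            fh, indent=1, default=str,
        )


# ---------------------------------------------------------------- chicken-scale index

def galliform_chromosome_index() -> GenomeIndex:
    """A chicken-genome-scale chromosome partition (synthetic stand-in).

    Named chromosome lengths follow the public galGal4 assembly's macro/micro
    structure; the unplaced remainder is modelled as 30 kb scaffolds so the
    total is exactly 1,046,932,099 bp of assembled sequence.
    """
    named = {
        "chr1": 195276750, "chr2": 148809762, "chr3": 110447801,
        "chr4": 90216835, "chr5": 59580361, "chr6": 34951654,
        "chr7": 36245040, "chr8": 28767244, "chr9": 23441680,
        "chr10": 19911089, "chr11": 19401079, "chr12": 19897011,
        "chr13": 17760035, "chr14": 15161805, "chr15": 12656803,
        "chr16": 535270, "chr17": 10454150, "chr18": 11219875,
        "chr19": 9983394, "chr20": 14302601, "chr21": 6802778,
        "chr22": 4081097, "chr23": 5723239, "chr24": 6323281,
        "chr25": 2191139, "chr26": 5329985, "chr27": 5209285,
        "chr28": 4742627, "chr32": 78254, "chrW": 1248174,
        "chrZ": 82363669, "chrLGE22": 965146, "chrLGE64": 799899,
    }
    total = 1_046_932_099
    remainder = total - sum(named.values())
    scaffold = 30_000
    n_scaffolds, tail = divmod(remainder, scaffold)
    chroms = dict(named)
    for i in range(n_scaffolds):
        chroms[f"scaffold{i + 1}"] = scaffold
    if tail:
        chroms["scaffold_tail"] = tail
    index = GenomeIndex(chroms)
    assert index.total_length == total
    return index
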