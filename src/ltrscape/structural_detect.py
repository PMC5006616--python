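"""Reference structural detector for LTR retrotransposons.

Intact elements retain two long terminal repeats (LTRs) — direct repeats that
were identical at insertion — flanking an internal region. The detector finds
candidate LTR pairs from exact k-mer seed matches at admissible spacing,
extends each seed cluster to a full pairwise LTR alignment, and then confirms
candidates with internal and terminal sequence evidence: TG...CA termini, a
target-site duplication (TSD), a primer binding site (PBS) complementary to a
host tRNA 3' end, a polypurine tract (PPT), a polyadenylation motif, and any
supplied protein/nucleotide domain hits.

The distance and similarity constraints (LTR length 80-2000 bp, pair
similarity >= 0.75) follow standard vertebrate LTR retrotransposon structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .genome_model import Annotation, AnnotationSet, Interval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DetectorParams:
    """Distance/similarity constraints and evidence requirement.

    Defaults: LTR length within [80, 2000] bp, pair similarity >= 0.75,
    element span within [1000, 25000] bp, 12-mer seeds, and at least two of
    the five structural evidence flags (or one passing domain hit) for
    acceptance.
    """

    min_ltr_len: int = 80
    max_ltr_len: int = 2000
    min_ltr_similarity: float = 0.75
    min_element_span: int = 1000
    max_element_span: int = 25000
    seed_kmer: int = 12
    evidence_min: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_ltr_len <= self.max_ltr_len):
            raise ValueError("require 0 < min_ltr_len <= max_ltr_len")
        if not (0 < self.min_ltr_similarity <= 1):
            raise ValueError("min_ltr_similarity must be in (0, 1]")
        if not (self.min_element_span < self.max_element_span):
            raise ValueError("require min_element_span < max_element_span")


@dataclass
class LTRPairCandidate:
    left_ltr: Interval
    right_ltr: Interval
    similarity: float
    element_span: Interval
    strand: str = "+"

    @property
    def internal(self) -> Interval:
        """Region between the two LTRs."""
        return Interval(
            self.left_ltr.chrom, self.left_ltr.end, self.right_ltr.start
        )


@dataclass
class EvidenceFlags:
    tg_ca: bool = False
    tsd: bool = False
    pbs: bool = False
    ppt: bool = False
    polya: bool = False
    tsd_seq: str | None = None

    @property
    def count(self) -> int:
        return sum((self.tg_ca, self.tsd, self.pbs, self.ppt, self.polya))


@dataclass
class StructuralElement:
    id: str
    candidate: LTRPairCandidate
    evidence: EvidenceFlags
    domain_hits: list = field(default_factory=list)
    accepted: bool = False
    nested_parent: str | None = None

    @property
    def span(self) -> Interval:
        return self.candidate.element_span


# ------------------------------------------------------------ seed matching

def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit k-mer codes per position; -1 where the window has a non-ACGT base."""
    lut = np.full(256, -1, dtype=np.int64)
    for i, base in enumerate("ACGT"):
        lut[ord(base)] = i
    b = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = b[j:j + n]
        codes = codes * 4 + np.where(col < 0, 0, col)
        bad |= col < 0
    codes[bad] = -1
    return codes


def _seed_pairs(seq: str, params: DetectorParams, max_occ: int = 64):
    """(left_pos, offset) seed pairs at admissible LTR-pair spacing."""
    k = params.seed_kmer
    codes = _encode_kmers(seq, k)
    if codes.size == 0:
        return {}
    d_min = max(params.min_ltr_len, params.min_element_span - params.max_ltr_len)
    d_max = params.max_element_span - params.min_ltr_len
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [codes.size]))
    by_offset: dict[int, list[int]] = {}
    for s, e in zip(starts, ends):
        if sorted_codes[s] < 0 or not (2 <= e - s <= max_occ):
            continue
        positions = np.sort(order[s:e])
        for ii in range(len(positions)):
            for jj in range(ii + 1, len(positions)):
                d = int(positions[jj] - positions[ii])
                if d > d_max:
                    break
                if d >= d_min:
                    by_offset.setdefault(d, []).append(int(positions[ii]))
    return by_offset


def _clusters(positions: list[int], params: DetectorParams, max_seed_gap: int = 500):
    """Split sorted seed positions into putative-LTR clusters."""
    positions = sorted(positions)
    span_cap = params.max_ltr_len - params.seed_kmer
    clusters = []
    start = prev = positions[0]
    for pos in positions[1:]:
        if pos - prev > max_seed_gap or pos - start > span_cap:
            clusters.append((start, prev))
            start = pos
        prev = pos
    clusters.append((start, prev))
    return clusters


# ------------------------------------------------------------ alignment

def _alignment_columns(query: str, target: str):
    """Per-column (match, query_pos, target_pos) from a global edlib alignment."""
    res = edlib.align(query, target, task="path")
    ops = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    match, qpos, tpos = [], [], []
    qi = ti = 0
    for count, op in ops:
        for _ in range(count):
            if op == "=" or op == "X":
                match.append(op == "=")
                qpos.append(qi)
                tpos.append(ti)
                qi += 1
                ti += 1
            elif op == "I":  # consumes query only (edlib extended cigar)
                match.append(False)
                qpos.append(qi)
                tpos.append(-1)
                qi += 1
            elif op == "D":  # consumes target only
                match.append(False)
                qpos.append(-1)
                tpos.append(ti)
                ti += 1
    if qi != len(query) or ti != len(target):
        # edlib I/D orientation differs between releases; swap and redo
        match, qpos, tpos = [], [], []
        qi = ti = 0
        for count, op in ops:
            for _ in range(count):
                if op == "=" or op == "X":
                    match.append(op == "=")
                    qpos.append(qi)
                    tpos.append(ti)
                    qi += 1
                    ti += 1
                elif op == "D":
                    match.append(False)
                    qpos.append(qi)
                    tpos.append(-1)
                    qi += 1
                else:
                    match.append(False)
                    qpos.append(-1)
                    tpos.append(ti)
                    ti += 1
    return np.asarray(match, bool), np.asarray(qpos), np.asarray(tpos)


def _trim_to_repeat(match: np.ndarray, gap: np.ndarray | None = None):
    """Max-scoring run of alignment columns (match +1, mismatch -1.5, gap -3).

    The padded alignment windows include random flanking sequence whose
    expected column score is negative under these weights (an edit-distance
    alignment of unrelated sequence trades mismatches for gap columns, so
    gaps must cost more than mismatches), while a true repeat at similarity
    >= 0.75 scores positive per column — the maximum-sum subarray therefore
    recovers the repeat boundaries. Ties prefer the shortest, leftmost run,
    which keeps the rule symmetric under reverse complementation up to
    score ties.
    """
    w = np.where(match, 1.0, -1.5)
    if gap is not None:
        w = np.where(gap, -3.0, w)
    prefix = np.concatenate(([0], np.cumsum(w)))
    best_sum, best = -1, None
    min_val, min_idx = 0, 0
    for j in range(1, len(prefix)):
        cand = prefix[j] - min_val
        if cand > best_sum or (
            cand == best_sum and best is not None and j - min_idx < best[1] - best[0]
        ):
            best_sum, best = cand, (min_idx, j)
        if prefix[j] <= min_val:
            min_val, min_idx = prefix[j], j
    if best is None or best_sum <= 0:
        return None
    lo, hi = best
    return lo, hi - 1


def _refine_candidate(
    seq: str, chrom: str, lo: int, hi: int, offset: int, params: DetectorParams
) -> LTRPairCandidate | None:
    pad = 60
    a = max(0, lo - pad)
    b = min(len(seq) - offset, hi + params.seed_kmer + pad)
    b = min(b, a + params.max_ltr_len + 2 * pad)
    if b - a < params.min_ltr_len:
        return None
    left_seq = seq[a:b]
    right_seq = seq[a + offset:b + offset]
    match, qpos, tpos = _alignment_columns(left_seq, right_seq)
    gap_cols = (qpos < 0) | (tpos < 0)
    trimmed = _trim_to_repeat(match, gap_cols)
    if trimmed is None:
        return None
    c0, c1 = trimmed
    sub = slice(c0, c1 + 1)
    similarity = float(np.mean(match[sub]))
    # the max-subarray similarity is selection-biased upward; gate instead on
    # the seed-cluster core, an unbiased sample of the repeat's interior
    core = (qpos >= lo - a) & (qpos <= hi + params.seed_kmer - 1 - a)
    if core.any() and float(np.mean(match[core])) < params.min_ltr_similarity:
        return None
    q = qpos[sub]
    t = tpos[sub]
    q = q[q >= 0]
    t = t[t >= 0]
    left = Interval(chrom, a + int(q[0]), a + int(q[-1]) + 1)
    right = Interval(chrom, a + offset + int(t[0]), a + offset + int(t[-1]) + 1)
    for ltr in (left, right):
        if not (params.min_ltr_len <= len(ltr) <= params.max_ltr_len):
            return None
    if left.end > right.start:
        return None
    span = right.end - left.start
    if not (params.min_element_span <= span <= params.max_element_span):
        return None
    if similarity < params.min_ltr_similarity:
        return None
    left, right = _polish_boundaries(seq, left, right, params)
    return LTRPairCandidate(
        left_ltr=left,
        right_ltr=right,
        similarity=similarity,
        element_span=Interval(chrom, left.start, right.end),
    )


def _polish_boundaries(
    seq: str, left: Interval, right: Interval, params: DetectorParams,
    max_shift: int = 5,
) -> tuple[Interval, Interval]:
    """Snap alignment-derived boundaries to element motifs.

    Outer boundaries (element start/end) are shifted by up to ``max_shift``
    bp onto a TG start / CA end, preferring shifts that also expose a 4-6 bp
    flanking target-site duplication; inner boundaries are snapped onto a
    CA end of the left LTR and a TG start of the right LTR. Alignment
    boundaries are typically within a few bp of the true termini; motif
    snapping recovers the exact ones when the motifs survive.
    """
    n = len(seq)
    best = None
    for s1 in range(-max_shift, max_shift + 1):
        ls = left.start + s1
        if ls < 0 or seq[ls:ls + 2] != "TG":
            continue
        for s2 in range(-max_shift, max_shift + 1):
            re = right.end + s2
            if re > n or seq[re - 2:re] != "CA":
                continue
            tsd_len = 0
            for k in TSD_LENGTHS:
                if ls - k >= 0 and re + k <= n and seq[ls - k:ls] == seq[re:re + k]:
                    tsd_len = k
                    break
            key = (-tsd_len, abs(s1) + abs(s2), s1, s2)
            if best is None or key < best[0]:
                best = (key, ls, re)
    ls, re = (best[1], best[2]) if best else (left.start, right.end)

    def _snap(pos: int, motif_at) -> int:
        for delta in sorted(range(-max_shift, max_shift + 1), key=lambda d: (abs(d), d)):
            if motif_at(pos + delta):
                return pos + delta
        return pos

    le = _snap(left.end, lambda p: 2 <= p <= n and seq[p - 2:p] == "CA")
    rs = _snap(right.start, lambda p: 0 <= p <= n - 2 and seq[p:p + 2] == "TG")
    if not (ls < le <= rs < re):
        return left, right
    new_left = Interval(left.chrom, ls, le)
    new_right = Interval(right.chrom, rs, re)
    for ltr in (new_left, new_right):
        if not (params.min_ltr_len <= len(ltr) <= params.max_ltr_len):
            return left, right
    return new_left, new_right


def find_ltr_pair_candidates(
    sequence: str, params: DetectorParams | None = None, chrom: str = "seq"
) -> list[LTRPairCandidate]:
    """Find LTR-pair candidates satisfying all detector constraints.

    Direct repeats read as direct repeats on both strands, so a single
    forward scan covers elements of either orientation; strand is assigned
    later from the internal evidence.
    """
    params = params or DetectorParams()
    if len(sequence) < params.min_element_span:
        return []
    sequence = sequence.upper()
    out: list[LTRPairCandidate] = []
    seen: set[tuple[int, int, int, int]] = set()
    for offset, positions in sorted(_seed_pairs(sequence, params).items()):
        for lo, hi in _clusters(positions, params):
            if hi + params.seed_kmer - lo < max(
                params.seed_kmer + 1, params.min_ltr_len // 2
            ):
                continue
            cand = _refine_candidate(sequence, chrom, lo, hi, offset, params)
            if cand is None:
                continue
            key = (
                cand.left_ltr.start,
                cand.left_ltr.end,
                cand.right_ltr.start,
                cand.right_ltr.end,
            )
            if key not in seen:
                seen.add(key)
                out.append(cand)
    out.sort(key=lambda c: (c.element_span.start, c.element_span.end))
    return out


# ------------------------------------------------------------ evidence

PBS_TAIL_LEN = 18          # 3'-terminal tRNA bases matched by the PBS
PBS_MIN_MATCH = 16         # of PBS_TAIL_LEN
PBS_SEARCH_WINDOW = 20     # bp downstream of the left LTR
PPT_WINDOW = 11            # purine-window length
PPT_MIN_PURINES = 9
PPT_SEARCH_WINDOW = 20     # bp upstream of the right LTR
TSD_LENGTHS = (6, 5, 4)    # preferred longest first
POLYA_MOTIF = "AATAAA"


def collect_internal_evidence(
    candidate: LTRPairCandidate,
    sequence: str,
    trna_set: dict[str, str] | list[str] | None = None,
) -> EvidenceFlags:
    """Evaluate the five structural evidence flags on the given orientation.

    tg_ca
        both LTRs start ``TG`` and end ``CA`` exactly.
    tsd
        identical 4-6 bp duplication immediately flanking the element.
    pbs
        >= 16/18 complementarity to the 3' 18-mer of any supplied tRNA
        within 20 bp downstream of the left LTR.
    ppt
        an 11 bp window with >= 9 purines within 20 bp upstream of the
        right LTR.
    polya
        ``AATAAA`` inside either LTR.
    """
    left, right = candidate.left_ltr, candidate.right_ltr
    if right.end > len(sequence) or left.start < 0:
        raise ValueError(
            f"candidate {left.chrom}:{left.start}-{right.end} outside sequence"
        )
    flags = EvidenceFlags()
    ltr5 = sequence[left.start:left.end]
    ltr3 = sequence[right.start:right.end]
    flags.tg_ca = all(
        s.startswith("TG") and s.endswith("CA") for s in (ltr5, ltr3)
    )
    for k in TSD_LENGTHS:
        if left.start - k < 0 or right.end + k > len(sequence):
            continue
        up = sequence[left.start - k:left.start]
        down = sequence[right.end:right.end + k]
        if up == down and set(up) <= set("ACGT"):
            flags.tsd = True
            flags.tsd_seq = up
            break
    if trna_set:
        trnas = trna_set.values() if isinstance(trna_set, dict) else trna_set
        targets = [revcomp(t[-PBS_TAIL_LEN:]) for t in trnas if len(t) >= PBS_TAIL_LEN]
        region = sequence[left.end:left.end + PBS_SEARCH_WINDOW + PBS_TAIL_LEN]
        flags.pbs = any(
            sum(a == b for a, b in zip(region[o:o + PBS_TAIL_LEN], tgt))
            >= PBS_MIN_MATCH
            for tgt in targets
            for o in range(0, min(PBS_SEARCH_WINDOW, len(region) - PBS_TAIL_LEN) + 1)
        )
    ppt_region = sequence[max(0, right.start - PPT_SEARCH_WINDOW):right.start]
    flags.ppt = any(
        sum(c in "AG" for c in ppt_region[i:i + PPT_WINDOW]) >= PPT_MIN_PURINES
        for i in range(0, max(0, len(ppt_region) - PPT_WINDOW) + 1)
    )
    flags.polya = POLYA_MOTIF in ltr5 or POLYA_MOTIF in ltr3
    return flags


def _mirror_candidate(cand: LTRPairCandidate, n: int) -> LTRPairCandidate:
    def mirror(iv: Interval) -> Interval:
        return Interval(iv.chrom, n - iv.end, n - iv.start)

    return LTRPairCandidate(
        left_ltr=mirror(cand.right_ltr),
        right_ltr=mirror(cand.left_ltr),
        similarity=cand.similarity,
        element_span=mirror(cand.element_span),
    )


def _oriented_evidence(
    cand: LTRPairCandidate, seq: str, rc_seq: str, trna_set
) -> tuple[EvidenceFlags, str]:
    fwd = collect_internal_evidence(cand, seq, trna_set)
    rev = collect_internal_evidence(
        _mirror_candidate(cand, len(seq)), rc_seq, trna_set
    )
    if rev.count > fwd.count:
        return rev, "-"
    return fwd, "+"


# ------------------------------------------------------------ element calling

def _resolve_overlaps(scored: list) -> list[StructuralElement]:
    """Resolve overlapping accepted candidates on one chromosome.

    Chooses the mutually non-overlapping subset maximizing total
    similarity x evidence-count score (weighted interval scheduling).
    Maximizing the total, rather than keeping candidates greedily, prevents
    a chimeric pairing of two neighbouring elements' outer LTRs — which
    individually outscores either true element — from displacing both. A
    rejected candidate lying wholly inside a chosen element's internal
    region is then re-admitted as a nested element.
    """
    if not scored:
        return []
    scored = sorted(scored, key=lambda x: (x[1].element_span.end, x[1].element_span.start))
    ends = [x[1].element_span.end for x in scored]
    n = len(scored)
    import bisect

    prev = [
        bisect.bisect_right(ends, scored[i][1].element_span.start) - 1
        for i in range(n)
    ]
    dp = [0.0] * (n + 1)
    take = [False] * n
    for i in range(n):
        with_i = dp[prev[i] + 1] + scored[i][0]
        if with_i > dp[i]:
            dp[i + 1] = with_i
            take[i] = True
        else:
            dp[i + 1] = dp[i]
    chosen: list[int] = []
    i = n - 1
    while i >= 0:
        if take[i] and dp[i + 1] != dp[i]:
            chosen.append(i)
            i = prev[i]
        else:
            i -= 1
    chosen.reverse()
    kept: list[StructuralElement] = []
    for idx in chosen:
        score, cand, flags, hits = scored[idx]
        kept.append(
            StructuralElement(
                id=f"tmp{len(kept)}", candidate=cand, evidence=flags,
                domain_hits=hits, accepted=True,
            )
        )
    rejected = sorted(
        (scored[i] for i in range(n) if i not in set(chosen)),
        key=lambda x: -x[0],
    )
    for score, cand, flags, hits in rejected:
        parent = next(
            (el for el in kept if el.candidate.internal.contains(cand.element_span)),
            None,
        )
        if parent is not None:
            if any(
                el.nested_parent is not None and el.span.overlaps(cand.element_span)
                for el in kept
            ):
                continue
            kept.append(
                StructuralElement(
                    id=f"tmp{len(kept)}", candidate=cand, evidence=flags,
                    domain_hits=hits, accepted=True, nested_parent=parent.id,
                )
            )
            continue
        # the converse: a rejected outer candidate whose internal region
        # wholly contains kept elements (and conflicts with nothing else)
        # is re-admitted as their parent
        inside = [
            el for el in kept if cand.internal.contains(el.span)
        ]
        conflicts = [
            el for el in kept
            if el.span.overlaps(cand.element_span) and el not in inside
        ]
        if inside and not conflicts:
            outer = StructuralElement(
                id=f"tmp{len(kept)}", candidate=cand, evidence=flags,
                domain_hits=hits, accepted=True,
            )
            kept.append(outer)
            for el in inside:
                if el.nested_parent is None:
                    el.nested_parent = outer.id
    return kept


def call_structural_elements(
    genome: dict[str, str],
    params: DetectorParams | None = None,
    trna_set: dict[str, str] | list[str] | None = None,
    domain_hits: list | None = None,
    thresholds=None,
) -> list[StructuralElement]:
    """Candidate finding + evidence collection + acceptance over a genome.

    A candidate is accepted when at least ``params.evidence_min`` of the five
    structural flags are set, or when at least one supplied domain hit passes
    its E-value threshold and overlaps the candidate's internal region.
    Overlapping accepted candidates are resolved by keeping the highest
    similarity x evidence-count score (ties: longer, then leftmost); an
    accepted element lying wholly inside another's internal region is kept
    and flagged as nested.
    """
    from .evidence_classify import EvidenceThresholds

    params = params or DetectorParams()
    thresholds = thresholds or EvidenceThresholds()
    domain_hits = domain_hits or []
    elements: list[StructuralElement] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        rc_seq = revcomp(seq)
        candidates = find_ltr_pair_candidates(seq, params, chrom=chrom)
        scored = []
        for cand in candidates:
            flags, strand = _oriented_evidence(cand, seq, rc_seq, trna_set)
            cand.strand = strand
            hits = [
                h
                for h in domain_hits
                if h.span is not None
                and h.span.chrom == chrom
                and h.span.overlaps(cand.internal)
                and h.e_value
                <= (
                    thresholds.prot_e_max
                    if h.kind == "protein"
                    else thresholds.nt_e_max
                )
            ]
            accepted = flags.count >= params.evidence_min or len(hits) >= 1
            if not accepted:
                continue
            score = cand.similarity * (flags.count + len(hits))
            scored.append((score, cand, flags, hits))
        elements.extend(_resolve_overlaps(scored))
    elements.sort(key=lambda e: (e.span.chrom, e.span.start, e.span.end))
    renames: dict[str, str] = {}
    for i, el in enumerate(elements, 1):
        renames[el.id] = f"SIE{i:04d}"
        el.id = renames[el.id]
    for el in elements:
        if el.nested_parent is not None:
            el.nested_parent = renames.get(el.nested_parent, el.nested_parent)
    return elements


def elements_to_annotations(elements: list[StructuralElement]) -> AnnotationSet:
    """Accepted elements as a ``source=structural`` annotation set."""
    out = AnnotationSet()
    for el in elements:
        if not el.accepted:
            continue
        iv = el.span
        out.add(
            Annotation(
                Interval(iv.chrom, iv.start, iv.end, el.candidate.strand),
                source="structural",
                score=el.candidate.similarity,
                label="SIE",
                id=el.id,
                attrs={
                    "ltr5": f"{el.candidate.left_ltr.start}-{el.candidate.left_ltr.end}",
                    "ltr3": f"{el.candidate.right_ltr.start}-{el.candidate.right_ltr.end}",
                    "evidence": el.evidence.count,
                },
            )
        )
    return out.sort()
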