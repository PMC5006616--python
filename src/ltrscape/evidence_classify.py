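"""Domain-evidence filtering and lineage classification.

Elements are assigned to a retroviral genus or LTR retrotransposon family
from the lineages of their best-matching reference hits, with protein
evidence taking precedence over nucleotide evidence and reverse
transcriptase (RT) outranking all other protein domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import Interval

DOMAINS = ("gag", "pro", "RT", "RNaseH", "IN", "env", "MT", "YR", "other")

LINEAGES = (
    "alpharetrovirus",
    "betaretrovirus",
    "gammaretrovirus",
    "epsilonretrovirus",
    "spumavirus",
    "lentivirus",
    "deltaretrovirus",
    "Ty1/Copia",
    "Ty3/Gypsy",
    "Bel/Pao",
    "DIRS",
    "unclassified",
)


@dataclass
class DomainHit:
    """A nucleotide-motif or protein-domain hit attributed to one element.

    ``span`` is a genomic interval (attribution to elements is by id or by
    overlap with the element's internal region); ``lineage`` is the lineage
    label of the best-matching reference, carried from the reference library
    sidecar map.
    """

    element_id: str | None
    domain: str
    kind: str  # "nucleotide" | "protein"
    e_value: float
    frame: int | None = None
    span: Interval | None = None
    lineage: str | None = None
    aln_len: int = 0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("E-value must be >= 0")
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"unknown hit kind {self.kind!r}")
        if self.kind == "protein" and self.frame is not None:
            if self.frame == 0 or not -3 <= self.frame <= 3:
                raise ValueError("protein frame must be in -3..+3, non-zero")


@dataclass
class EvidenceThresholds:
    """E-value ceilings: 1e-5 for nucleotide motif hits, 1e-10 for protein."""

    nt_e_max: float = 1e-5
    prot_e_max: float = 1e-10

    def __post_init__(self) -> None:
        if self.nt_e_max <= 0 or self.prot_e_max <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class EvidenceBundle:
    element_id: str
    nt_hits: list[DomainHit] = field(default_factory=list)
    prot_hits: list[DomainHit] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.nt_hits and not self.prot_hits


@dataclass
class LineageCall:
    element_id: str
    label: str
    evidence_level: str  # "protein" | "nucleotide" | "none"
    best_hit: DomainHit | None = None
    tie_logged: bool = False

    def __post_init__(self) -> None:
        if (self.evidence_level == "none") != (self.label == "unclassified"):
            raise ValueError("evidence_level none <=> label unclassified")


def evaluate_candidate_evidence(
    element_id: str,
    nt_hits: list[DomainHit],
    prot_hits: list[DomainHit],
    thresholds: EvidenceThresholds | None = None,
) -> EvidenceBundle:
    """Retain hits passing their kind's E-value ceiling (inclusive)."""
    thresholds = thresholds or EvidenceThresholds()
    return EvidenceBundle(
        element_id=element_id,
        nt_hits=[h for h in nt_hits if h.e_value <= thresholds.nt_e_max],
        prot_hits=[h for h in prot_hits if h.e_value <= thresholds.prot_e_max],
    )


def _best(hits: list[DomainHit]) -> tuple[DomainHit, bool]:
    """Lowest E-value; ties by longer span, then input order (logged)."""
    best = hits[0]
    tie = False
    for h in hits[1:]:
        if h.e_value < best.e_value:
            best, tie = h, False
        elif h.e_value == best.e_value:
            if h.aln_len > best.aln_len:
                best, tie = h, True
            else:
                tie = True
    return best, tie


def classify_lineage(bundle: EvidenceBundle) -> LineageCall:
    """Assign a lineage with protein-over-nucleotide and RT-first precedence.

    The call is the lineage of the best protein hit, where RT hits outrank
    all other protein domains; failing protein evidence, the best nucleotide
    hit decides; an empty bundle is unclassified. Hits without a lineage
    label are ignored for labelling.
    """
    prot = [h for h in bundle.prot_hits if h.lineage]
    nt = [h for h in bundle.nt_hits if h.lineage]
    if prot:
        rt = [h for h in prot if h.domain == "RT"]
        best, tie = _best(rt if rt else prot)
        return LineageCall(bundle.element_id, best.lineage, "protein", best, tie)
    if nt:
        best, tie = _best(nt)
        return LineageCall(
            bundle.element_id, best.lineage, "nucleotide", best, tie
        )
    return LineageCall(bundle.element_id, "unclassified", "none")


def classify_elements(
    bundles: list[EvidenceBundle],
) -> dict[str, LineageCall]:
    return {b.element_id: classify_lineage(b) for b in bundles}
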