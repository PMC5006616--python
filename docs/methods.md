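# Methods

This note documents the models, algorithms and numerical choices behind
`ltrscape`, and what the synthetic-data tests do and do not establish about
real genomes.

## Coordinate conventions and interval algebra

All coordinates are 0-based, half-open internally; GFF3/GTF I/O converts to
1-based closed at the boundary, BED is native. "Fewer than 11 bp apart" is
read literally as inter-interval gap ≤ 10 bp in half-open coordinates, the
default for merging homology evidence. Merging is strand-agnostic —
annotation is of loci, and repeat-masking tools report fragments of one
locus on either strand — with contributing strands and provenance tags kept
as record metadata. Unstranded records are excluded from same-orientation
intersection (conservative). Distances are edge-to-edge, matching
bedtools-style "shortest distance" semantics. Coverage accounting sweeps
chromosome-sorted boundary events with a per-source active counter, so the
exclusive provenance categories partition the union exactly; this identity
is asserted in tests against a per-base bitmap oracle.

## Structural detector

The detector finds candidate LTR pairs and confirms them with sequence
evidence. Parameters (defaults in brackets):

| parameter | default | meaning |
|---|---|---|
| `min_ltr_len` / `max_ltr_len` | 80 / 2000 bp | admissible LTR lengths |
| `min_ltr_similarity` | 0.75 | minimum LTR-pair identity |
| `min_element_span` / `max_element_span` | 1000 / 25000 bp | whole-element span bounds |
| `seed_kmer` | 12 | exact seed length |
| `evidence_min` | 2 | structural flags required for acceptance |

LTR lengths and the similarity floor follow known vertebrate LTR
retrotransposon structure; the span bounds bracket observed intact-element
lengths (means around 8–9 kb, with long nested elements) and are
configurable.

**Candidate generation.** Exact 12-mer matches between genome positions at
admissible spacing are grouped by offset (substitution-divergent LTR copies
share one offset) and clustered along the sequence (split at seed gaps
> 500 bp or when a cluster would exceed the LTR length cap). Each cluster
is padded by 60 bp and the left/right windows globally aligned (edlib).
Because direct repeats read as direct repeats on both strands, one forward
scan covers both orientations; strand is assigned afterwards from the
evidence motifs evaluated in both orientations.

**Boundary estimation.** Repeat boundaries are the maximum-scoring run of
alignment columns with weights match +1, mismatch −1.5, gap −3. The weights
make unrelated flanking sequence score negative even under an edit-distance
alignment (which otherwise trades mismatch runs for gap columns and keeps
~50 % match columns in random sequence), while a true repeat at ≥ 0.75
identity scores positive per column. Boundaries are then snapped (≤ 5 bp)
onto element motifs: a `TG` start / `CA` end, preferring shifts that expose
an exact 4–6 bp flanking TSD, and inner `CA`/`TG` boundaries likewise.
Candidate acceptance is gated on the identity of the seed-cluster core — an
unbiased sample of the repeat interior — because the max-subarray identity
is selection-biased upward near the threshold.

**Evidence flags.** `tg_ca` (both LTRs exactly TG…CA), `tsd` (identical
4–6 bp duplication immediately outside both LTRs, exact match, longest
first), `pbs` (≥ 16/18 complementarity to the 3′-terminal 18-mer of any
supplied tRNA within 20 bp downstream of the left LTR), `ppt` (an 11 bp
window with ≥ 9 purines within 20 bp upstream of the right LTR), `polya`
(`AATAAA` inside either LTR). The PBS/PPT scans replace profile-HMM
searches with motif rules whose thresholds are explicit and configurable.
An element is accepted with ≥ 2 flags, or with ≥ 1 internal domain hit
passing the evidence thresholds — a reproducible stand-in for manual
review of feature tests.

**Overlap resolution.** Among accepted candidates on one chromosome the
kept set is the mutually non-overlapping subset maximizing total
similarity × evidence-count score (weighted interval scheduling). A greedy
keep-best rule was rejected because two neighbouring same-family elements
offer a chimeric "outer" pairing (left element's LTR with right element's
LTR) that individually outscores either true element; maximizing the total
keeps both true elements instead. Rejected candidates wholly inside a kept
element's internal region are re-admitted as nested elements, and a
rejected outer candidate whose internal region wholly contains kept
elements is re-admitted as their parent.

**Known limitations.** A fragment that retains LTR + PBS sequence and lies
within the element-span bounds of a true element can still form a
convincing chimeric pair (it carries genuine motifs); boundary estimates at
pair divergence near 0.3 can truncate into locally conserved cores. Both
are failure modes shared with seed-and-extend structural detectors
generally, not artifacts of the synthetic data.

## Homology integration

Thresholds are inclusive (E ≤ 10⁻¹⁰ passes, length ≥ 100 bp passes),
consistent with "or better" phrasing in the DIRS rule. The conflict filter
removes an element when ≥ 50 % of its span (configurable) is covered by
non-LTR repeat records — a reproducible criterion standing in for manual
case review — and logs the dominating class. Reciprocal validation reduces
each element's hit list to the best hit (highest bitscore, ties by lower E
then longer alignment); unvalidated records survive finalization only with
overlapping structural support. The secondary stage inherits the primary
E-value/length filters (its own thresholds are not independently
specified); hits wholly inside existing annotation are absorbed, partial
overlaps merge downstream. tBLASTx-style hits are treated as nucleotide
subject intervals; frame is discarded after filtering.

## Lineage classification

Hits are filtered at E ≤ 10⁻⁵ (nucleotide) and E ≤ 10⁻¹⁰ (protein). The
lineage call is the lineage of the best protein hit, with reverse
transcriptase outranking all other protein domains; failing protein
evidence, the best nucleotide hit decides; otherwise unclassified. "Best"
is lowest E, ties broken by longer alignment span then input order, with
ties flagged on the call. Reference lineage labels travel with the
user-supplied library (sidecar TSV); no proprietary repeat-library content
ships with the package.

## Insertion dating

LTR pair identity is computed from a global alignment
(`Bio.Align.PairwiseAligner`, match +1, mismatch −1, gap open −2, extend
−0.5); terminal gap columns are excluded from the denominator, internal
gap columns count as mismatches. Affine gap penalties matter here: a pure
edit-distance alignment inflates identity by ~2 points at 10 % divergence
(it converts mismatch runs into gap pairs), which would bias ages low by
~18 %.

The clock is **T = d / (2 r)** with *d* = 1 − identity and *r* the
per-lineage substitution rate; the default *r* = 3.7×10⁻⁹ /site/year is
chosen so that 10 % divergence maps to 13.5 million years, the standard
Galliformes calibration, and is a configuration value. Divergence is linear
by default (the 10 % → 13.5 MYA and 20 % → 27 MYA pairing is linear); an
optional Jukes–Cantor correction (−¾ ln(1 − 4d/3)) is available for older
elements. Rate uncertainty is not estimated — a user-supplied rate range
can be propagated externally.

The age-randomization operation permutes ages across elements. Over the
full element set a permutation preserves category proportions identically
(this degenerate identity is asserted in tests); the informative use passes
a member subset — for example the elements inside clusters — whose permuted
category proportions are averaged over replicates, giving the null for
age-relatedness of that group. The permutation generator is seeded and
bit-reproducible.

## Distribution statistics

**Density and correlates.** Densities (elements/Mb) and their correlates
are log₁₀-transformed; pairwise Pearson correlations and a Gaussian
identity-link GLM (ordinary least squares via statsmodels) of log density
on log length and log recombination rate, with caller-specified chromosome
exclusions. Non-positive values before the log, or zero-variance columns,
raise errors naming the offending chromosome/variable.

**Clusters.** A cluster requires ≥ 5 element midpoints per 1 Mb window.
Windows are anchored at element midpoints — the continuous limit of a
finely stepped sliding window — so any 5 consecutive sorted midpoints
spanning ≤ 1 Mb qualify, and overlapping qualifying windows are unioned.
This is deterministic and needs no step-size parameter; against a 1 kb
stepped scan the difference on the integration null is below 0.1
percentage points. Cluster density is reported as members per Mb of the
member span; for a union of chained windows this can in principle dip
below the per-window criterion, which is why the defining rule is the
windowing, not the reported density.

**Random-integration null.** Each replicate draws *n* point integrations
uniformly over assembled (non-gap) bases — chromosomes are hit
proportionally to assembled length — and computes either the clustered
fraction or the distance-to-TU category profile. Element length is ignored
(point integrations). Simulations are seeded, bit-reproducible, and
vectorized (~1 ms per replicate at n ≈ 1000 on a 1 Gb partition). The
package ships a chicken-genome-scale partition (named chromosome lengths
following the public galGal4 assembly; the ~42 Mb unplaced remainder
modelled as 30 kb scaffolds; total exactly 1,046,932,099 bp) as the
reference configuration for the cluster null; on it, 1,073 integrations
put ≈ 6.8 % of elements in clusters.

**Distance profiles and tests.** A transcriptional unit (TU) is a gene
span — exons, introns, UTRs — plus 5 kb flanks, clipped to the chromosome;
overlapping TU extents are merged for distance computation but kept
per-gene for subfeature assignment. Elements overlapping a TU extent are
the TU category; others are binned by shortest edge-to-edge distance in
10 kb bins to 100 kb, then > 100 kb; elements on contigs without any TU are
non-defined (ND) and excluded from distances. Category counts always sum
to the element count (asserted on every construction). Per-category
two-sided exact binomial tests take their expected proportions from the
null-simulation means (matching the Monte-Carlo procedure rather than
analytic coverage); the Kolmogorov–Smirnov test is two-sample between
observed per-element distances and pooled null distances (capped,
deterministically, at 50 000 pooled values). Subfeature assignment uses
precedence exon > 5′UTR > 3′UTR > intron > flank; expected subfeature
fractions are the precedence-classified base composition of the merged TU
extents, the analytic limit of the uniform null. The χ² representation
test is Pearson's, df = 1, no continuity correction, with a warning flag
when an expected cell is below 1.

**Expression.** Per element and tissue, same-strand transcripts are
evaluated against the internal region (between the LTRs): complete iff a
single transcript covers it entirely, partial on any same-strand overlap,
none otherwise; unstranded transcripts are excluded and tallied.

## Synthetic data

The generator's defaults define the desk-scale study conditions: a 2 Mb
two-chromosome genome at GC 0.42, 10 intact elements with divergences
cycling through {0, 0.02, 0.05, 0.08, 0.10, 0.12, 0.15}, LTRs of 250–400 bp,
internal regions of 2–5 kb, 50 fragments (≤ 0.15 divergence, 80–800 bp),
40 genes (3–15 kb, 2–8 exons with UTRs), 5 tRNAs, four element families
(three retroviral genera and Ty3/Gypsy), a 500 kb-binned lognormal
recombination map, and stranded transcripts realising a planted
complete/partial/none expression status per element.

Element templates share an LTR and a domain block within a family but get
per-insertion internal filler, so two insertions of one family do not share
their entire internal sequence. Each LTR copy is mutated independently at
*d*/2 (substitutions uniform over the three alternatives), so the pair
diverges by ≈ *d* under the same independence assumption the dating model
makes. TSDs are duplicated outside both LTRs; PBS/PPT/polyA/TG…CA motifs
are planted where the detector expects them. Synthetic E-values for hit
tables decline with identity × alignment length (10^(−identity·len/5));
only their ordering and threshold behaviour carry information, and they
are labelled synthetic. Background sequence is i.i.d. with configurable
GC — no higher-order composition, no transposition-history model
(bursts, selection), no read-level RNA-seq simulation.

Everything is deterministic under the config seed (child generators are
derived from stable string labels), and the same config yields
byte-identical output files.

**What passing tests show — and don't.** Recovery of planted elements
shows the detector implements its stated constraints correctly on
sequence whose repeats are unambiguous by construction; it does not bound
sensitivity on real genomes, where segmental duplications, satellite
arrays, degraded elements and compositional heterogeneity all depress it.
Likewise the dating recovery shows estimator correctness under the
substitution model the clock assumes, not robustness to rate variation or
gene conversion between LTRs (which rejuvenates real elements).

## Problem sizes

Default test and reference runs use 2 Mb genomes for detection (about a
second per genome), 10³ Monte-Carlo replicates in test nulls and a few
thousand in the reference script (~1 ms per replicate at genome scale),
and 25 fixed-seed 500 bp LTR pairs per divergence level for dating
recovery — at 500 bp the per-pair binomial noise at d = 0.02 is ~30 %
relative, so the median over 25 pairs isolates estimator error from
sampling noise.
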