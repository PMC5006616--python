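"""Genomic distribution statistics for annotated LTR retrotransposons.

Covers per-chromosome density and its correlates (length, gene density,
recombination rate), cluster calling under the >=5-elements-per-Mb rule, a
Monte-Carlo null of uniform random point integrations, distance-to-gene
profiles with exact binomial and Kolmogorov-Smirnov enrichment tests,
subfeature (exon/UTR/intron/flank) overlap accounting, and the
expression-completeness classification of intact elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    Annotation,
    AnnotationSet,
    GenomeIndex,
    Interval,
    merge_intervals,
)

MB = 1_000_000

DISTANCE_BIN_EDGES_KB = tuple(range(0, 101, 10))  # (0,10], ... (90,100] kb


def distance_categories() -> list[str]:
    cats = ["TU"]
    cats += [
        f"{DISTANCE_BIN_EDGES_KB[i]}-{DISTANCE_BIN_EDGES_KB[i + 1]}kb"
        for i in range(len(DISTANCE_BIN_EDGES_KB) - 1)
    ]
    cats += [">100kb", "ND"]
    return cats


# ---------------------------------------------------------------- TU model

@dataclass
class TUModel:
    """A transcriptional unit: gene span, exon/UTR structure and 5 kb flanks."""

    gene_id: str
    biotype: str  # "protein_coding" | "RNA"
    span: Interval
    exons: list[Interval] = field(default_factory=list)
    utr5: Interval | None = None
    utr3: Interval | None = None
    flank: int = 5000

    def __post_init__(self) -> None:
        for ex in self.exons:
            if not self.span.contains(ex):
                raise ValueError(f"exon {ex} outside gene span of {self.gene_id}")

    def extent(self, genome: GenomeIndex | None = None) -> Interval:
        """Gene span plus flanks, clipped to the chromosome."""
        start = max(0, self.span.start - self.flank)
        end = self.span.end + self.flank
        if genome is not None:
            end = min(end, genome.chromosomes[self.span.chrom])
        return Interval(self.span.chrom, start, end, self.span.strand)


def read_gene_models(path, flank: int = 5000) -> list[TUModel]:
    """Read gene models (gene/exon/UTR features) from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    tus = []
    for gene in db.features_of_type("gene"):
        span = Interval(
            gene.seqid, gene.start - 1, gene.end,
            gene.strand if gene.strand in ("+", "-") else ".",
        )
        exons, utr5, utr3 = [], None, None
        for child in db.children(gene.id):
            iv = Interval(child.seqid, child.start - 1, child.end, span.strand)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5 = iv
            elif child.featuretype == "three_prime_UTR":
                utr3 = iv
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        tus.append(
            TUModel(
                gene_id=gene.id, biotype=biotype, span=span,
                exons=exons, utr5=utr5, utr3=utr3, flank=flank,
            )
        )
    return tus


def merged_tu_extents(
    tus: list[TUModel], genome: GenomeIndex | None = None
) -> AnnotationSet:
    """TU extents (span +/- flank) merged where overlapping."""
    aset = AnnotationSet(
        Annotation(tu.extent(genome), source="homology", label="TU")
        for tu in tus
    )
    return merge_intervals(aset, max_gap=0)


# ---------------------------------------------------------------- density

def chromosome_density_table(
    elements: AnnotationSet, genome: GenomeIndex
) -> pd.DataFrame:
    """Elements per Mb for every chromosome of the genome index."""
    elements.validate(genome)
    counts: dict[str, int] = {c: 0 for c in genome.chromosomes}
    for rec in elements:
        counts[rec.interval.chrom] += 1
    rows = [
        {
            "chrom": chrom,
            "length": length,
            "n_elements": counts[chrom],
            "density_per_mb": counts[chrom] / (length / MB),
        }
        for chrom, length in genome.chromosomes.items()
    ]
    return pd.DataFrame(rows)


@dataclass
class DensityCorrelates:
    pearson: dict          # (var_a, var_b) -> (r, p) on log10 scale
    glm_params: pd.Series
    glm_pvalues: pd.Series
    glm_conf_int: pd.DataFrame
    excluded: list[str]
    n_chromosomes: int


def density_correlates(
    table: pd.DataFrame,
    exclusions: list[str] | None = None,
) -> DensityCorrelates:
    """Pairwise Pearson correlations and a Gaussian GLM on log10 variables.

    ``table`` needs columns chrom, density_per_mb, length, gene_density and
    recomb_rate; listed chromosomes are excluded before fitting. The GLM
    regresses log10 density on log10 length and log10 recombination rate
    (Gaussian family, identity link — ordinary least squares).
    """
    import statsmodels.api as sm

    exclusions = exclusions or []
    df = table[~table["chrom"].isin(exclusions)].copy()
    if len(df) < 3:
        raise ValueError("need >= 3 non-excluded chromosomes")
    variables = ["density_per_mb", "length", "gene_density", "recomb_rate"]
    for var in variables:
        bad = df[df[var] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive {var} before log on chromosome "
                f"{bad['chrom'].iloc[0]}"
            )
        df[f"log_{var}"] = np.log10(df[var])
        if np.ptp(df[f"log_{var}"]) == 0:
            raise ValueError(f"correlation undefined: {var} has zero variance")
    pearson = {}
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r, p = stats.pearsonr(df[f"log_{a}"], df[f"log_{b}"])
            pearson[(a, b)] = (float(r), float(p))
    X = sm.add_constant(df[["log_length", "log_recomb_rate"]])
    fit = sm.GLM(
        df["log_density_per_mb"], X, family=sm.families.Gaussian()
    ).fit()
    return DensityCorrelates(
        pearson=pearson,
        glm_params=fit.params,
        glm_pvalues=fit.pvalues,
        glm_conf_int=fit.conf_int(),
        excluded=list(exclusions),
        n_chromosomes=len(df),
    )


# ---------------------------------------------------------------- clusters

@dataclass
class ClusterCall:
    span: Interval
    member_ids: list
    density_per_mb: float


def _marked_runs(midpoints: np.ndarray, window: float, cluster_min: int):
    """Boolean mask of midpoints lying in some <=window run of >=cluster_min."""
    n = len(midpoints)
    mark = np.zeros(n, dtype=bool)
    if n < cluster_min:
        return mark
    m = cluster_min
    ok = midpoints[m - 1:] - midpoints[: n - m + 1] <= window
    diff = np.zeros(n + 1, dtype=int)
    idx = np.flatnonzero(ok)
    np.add.at(diff, idx, 1)
    np.add.at(diff, idx + m, -1)
    return np.cumsum(diff[:-1]) > 0


def call_clusters(
    elements: AnnotationSet,
    window: int = MB,
    cluster_min: int = 5,
) -> list[ClusterCall]:
    """Call element clusters under the >= cluster_min per window density rule.

    A window of ``window`` bp containing >= ``cluster_min`` element midpoints
    qualifies (windows are anchored at midpoints — the continuous limit of a
    fine-stepped sliding window); overlapping qualifying windows are unioned
    into one cluster. Cluster density is members per Mb of the member span.
    """
    clusters: list[ClusterCall] = []
    for chrom, recs in sorted(elements.by_chrom().items()):
        recs = sorted(recs, key=lambda r: r.interval.midpoint)
        mids = np.array([r.interval.midpoint for r in recs])
        mark = _marked_runs(mids, window, cluster_min)
        i = 0
        while i < len(recs):
            if not mark[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(recs) and mark[j + 1]:
                j += 1
            members = recs[i:j + 1]
            start = min(r.interval.start for r in members)
            end = max(r.interval.end for r in members)
            clusters.append(
                ClusterCall(
                    span=Interval(chrom, start, end),
                    member_ids=[
                        r.id if r.id else f"{chrom}:{r.interval.start}"
                        for r in members
                    ],
                    density_per_mb=len(members) / ((end - start) / MB),
                )
            )
            i = j + 1
    return clusters


def clustered_fraction(
    elements: AnnotationSet, window: int = MB, cluster_min: int = 5
) -> float:
    """Fraction of elements belonging to any called cluster."""
    if len(elements) == 0:
        return 0.0
    n_in = sum(len(c.member_ids) for c in call_clusters(elements, window, cluster_min))
    return n_in / len(elements)


# ---------------------------------------------------------------- random-integration null

@dataclass
class NullSummary:
    """Monte-Carlo summary of a statistic under uniform point integrations."""

    statistic: str
    reps: int
    n: int
    seed: int
    categories: list[str] | None = None
    mean: np.ndarray | float = 0.0
    sd: np.ndarray | float = 0.0
    q025: np.ndarray | float = 0.0
    q975: np.ndarray | float = 0.0
    values: np.ndarray | None = None          # per-replicate scalar statistic
    pooled_distances: np.ndarray | None = None  # subsample for KS tests


def _assembled_segments(genome: GenomeIndex):
    """(chrom, seg_start, seg_end) for non-gap stretches, with global offsets."""
    gaps_by_chrom: dict[str, list[Interval]] = {}
    for gap in genome.assembly_gaps:
        gaps_by_chrom.setdefault(gap.chrom, []).append(gap)
    segs = []
    for chrom, length in genome.chromosomes.items():
        pos = 0
        for gap in sorted(gaps_by_chrom.get(chrom, []), key=lambda g: g.start):
            if gap.start > pos:
                segs.append((chrom, pos, gap.start))
            pos = max(pos, gap.end)
        if pos < length:
            segs.append((chrom, pos, length))
    return segs


def _draw_positions(genome: GenomeIndex, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """n uniform positions over assembled bases -> (chrom index, position)."""
    segs = _assembled_segments(genome)
    chrom_ids = {c: i for i, c in enumerate(genome.chromosomes)}
    seg_chrom = np.array([chrom_ids[c] for c, _, _ in segs])
    seg_start = np.array([s for _, s, _ in segs], dtype=float)
    seg_len = np.array([e - s for _, s, e in segs], dtype=float)
    cum = np.cumsum(seg_len)
    u = rng.uniform(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right")
    offset = u - (cum[idx] - seg_len[idx])
    return seg_chrom[idx], seg_start[idx] + offset


def _cluster_fraction_of_points(
    chrom_idx: np.ndarray,
    pos: np.ndarray,
    chrom_offsets: np.ndarray,
    window: float,
    cluster_min: int,
) -> float:
    g = chrom_offsets[chrom_idx] + pos
    order = np.argsort(g)
    g = g[order]
    cid = chrom_idx[order]
    n, m = len(g), cluster_min
    if n < m:
        return 0.0
    ok = (cid[m - 1:] == cid[: n - m + 1]) & (g[m - 1:] - g[: n - m + 1] <= window)
    diff = np.zeros(n + 1, dtype=int)
    idx = np.flatnonzero(ok)
    np.add.at(diff, idx, 1)
    np.add.at(diff, idx + m, -1)
    return float(np.mean(np.cumsum(diff[:-1]) > 0))


def _point_distances(
    chrom_idx: np.ndarray,
    pos: np.ndarray,
    extent_arrays: dict[int, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Distance (bp) from each point to the nearest TU extent; -1 marks ND."""
    out = np.empty(len(pos))
    for ci in np.unique(chrom_idx):
        sel = chrom_idx == ci
        if ci not in extent_arrays:
            out[sel] = -1
            continue
        starts, ends = extent_arrays[ci]
        p = pos[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        d_prev = np.where(idx >= 0, p - ends[np.clip(idx, 0, len(ends) - 1)], np.inf)
        nxt = np.clip(idx + 1, 0, len(starts) - 1)
        d_next = np.where(idx + 1 < len(starts), starts[nxt] - p, np.inf)
        d = np.minimum(np.maximum(d_prev, 0), np.maximum(d_next, 0))
        d[inside] = 0.0
        out[sel] = d
    return out


def _bin_distances(d: np.ndarray, overlap: np.ndarray | None = None) -> np.ndarray:
    """Counts per distance category (see :func:`distance_categories`)."""
    cats = distance_categories()
    counts = np.zeros(len(cats), dtype=float)
    nd = d < 0
    counts[-1] = nd.sum()
    dd = d[~nd]
    if overlap is None:
        in_tu = dd == 0
    else:
        in_tu = overlap[~nd]
    counts[0] = in_tu.sum()
    rest = dd[~in_tu]
    edges_bp = [e * 1000 for e in DISTANCE_BIN_EDGES_KB]
    for i in range(len(edges_bp) - 1):
        counts[1 + i] = np.sum((rest > edges_bp[i]) & (rest <= edges_bp[i + 1]))
    counts[len(edges_bp)] = np.sum(rest > edges_bp[-1])
    return counts


def simulate_random_integrations(
    n: int,
    genome: GenomeIndex,
    reps: int = 1000,
    seed: int = 0,
    statistic: str = "cluster_fraction",
    tus: list[TUModel] | None = None,
    window: int = MB,
    cluster_min: int = 5,
    pooled_cap: int = 50_000,
) -> NullSummary:
    """Monte-Carlo null: ``n`` uniform point integrations per replicate.

    Positions fall uniformly over assembled (non-gap) bases, which picks
    chromosomes proportionally to assembled length. ``statistic`` is either
    ``cluster_fraction`` (fraction of points inside >=cluster_min/window
    clusters) or ``distance_profile`` (distance-to-TU category counts;
    requires ``tus``). Seeded and bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_list = list(genome.chromosomes)
    if statistic == "cluster_fraction":
        offsets = np.concatenate(
            ([0], np.cumsum([genome.chromosomes[c] for c in chrom_list])))[:-1].astype(float)
        # separate chromosomes by more than the window so runs never span them
        offsets += window * 2 * np.arange(len(chrom_list))
        values = np.empty(reps)
        for r in range(reps):
            ci, pos = _draw_positions(genome, n, rng)
            values[r] = _cluster_fraction_of_points(
                ci, pos, offsets, window, cluster_min
            )
        return NullSummary(
            statistic=statistic, reps=reps, n=n, seed=seed,
            mean=float(values.mean()), sd=float(values.std(ddof=1)) if reps > 1 else 0.0,
            q025=float(np.quantile(values, 0.025)),
            q975=float(np.quantile(values, 0.975)),
            values=values,
        )
    if statistic == "distance_profile":
        if tus is None:
            raise ValueError("distance_profile statistic requires tus")
        chrom_ids = {c: i for i, c in enumerate(chrom_list)}
        extents = merged_tu_extents(tus, genome)
        extent_arrays: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, recs in extents.by_chrom().items():
            starts = np.array(sorted(r.interval.start for r in recs), dtype=float)
            ends = np.array(sorted(r.interval.end for r in recs), dtype=float)
            extent_arrays[chrom_ids[chrom]] = (starts, ends)
        cats = distance_categories()
        counts = np.empty((reps, len(cats)))
        pooled: list[np.ndarray] = []
        pooled_total = 0
        for r in range(reps):
            ci, pos = _draw_positions(genome, n, rng)
            d = _point_distances(ci, pos, extent_arrays)
            counts[r] = _bin_distances(d)
            if pooled_total < pooled_cap:
                keep = d[d >= 0]
                pooled.append(keep)
                pooled_total += len(keep)
        props = counts / n
        return NullSummary(
            statistic=statistic, reps=reps, n=n, seed=seed, categories=cats,
            mean=props.mean(axis=0),
            sd=props.std(axis=0, ddof=1) if reps > 1 else np.zeros(len(cats)),
            q025=np.quantile(props, 0.025, axis=0),
            q975=np.quantile(props, 0.975, axis=0),
            pooled_distances=np.concatenate(pooled)[:pooled_cap] if pooled else None,
        )
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------- distance profile

@dataclass
class DistanceProfile:
    categories: list[str]
    counts: np.ndarray
    total: int
    distances: np.ndarray | None = None  # per-element, TU-overlaps as 0, ND dropped

    def __post_init__(self) -> None:
        if int(np.sum(self.counts)) != self.total:
            raise AssertionError("distance-profile counts do not sum to total")

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / max(self.total, 1)


def tu_distance_profile(
    elements: AnnotationSet,
    tus: list[TUModel],
    genome: GenomeIndex,
) -> DistanceProfile:
    """Bin each element by overlap with / distance to the nearest TU extent.

    Elements overlapping a TU extent (gene span plus 5 kb flanks) fall in
    the TU category; others are binned by shortest edge-to-edge distance in
    10 kb bins up to 100 kb, then >100 kb; elements on contigs without any
    TU are non-defined (ND).
    """
    extents = merged_tu_extents(tus, genome)
    by_chrom = extents.by_chrom()
    cats = distance_categories()
    counts = np.zeros(len(cats))
    dists = []
    edges_bp = [e * 1000 for e in DISTANCE_BIN_EDGES_KB]
    for rec in elements:
        chrom_extents = by_chrom.get(rec.interval.chrom)
        if not chrom_extents:
            counts[-1] += 1
            continue
        d = min(rec.interval.distance_to(x.interval) for x in chrom_extents)
        dists.append(d)
        if d == 0:
            counts[0] += 1
        elif d > edges_bp[-1]:
            counts[len(edges_bp)] += 1
        else:
            for i in range(len(edges_bp) - 1):
                if edges_bp[i] < d <= edges_bp[i + 1]:
                    counts[1 + i] += 1
                    break
    return DistanceProfile(
        categories=cats,
        counts=counts,
        total=len(elements),
        distances=np.array(dists, dtype=float),
    )


# ---------------------------------------------------------------- enrichment tests

@dataclass
class EnrichmentResult:
    category: str
    observed: int
    expected_proportion: float
    p_binomial: float
    direction: str  # "enriched" | "depleted" | "none"

    def __post_init__(self) -> None:
        if not 0 <= self.p_binomial <= 1:
            raise ValueError("p out of [0, 1]")


def category_enrichment_tests(
    observed: DistanceProfile,
    null: NullSummary,
) -> tuple[list[EnrichmentResult], tuple[float, float] | None]:
    """Two-sided exact binomial test per category plus a two-sample KS test.

    Expected proportions are the null-simulation category means. ND counts
    are compared like any other category when present in both. The KS test
    compares per-element observed distances with pooled null distances and
    is returned as (D, p), or None when either side lacks distances.
    """
    if observed.total < 1:
        raise ValueError("observed profile is empty")
    if null.categories != observed.categories:
        raise ValueError("category mismatch between observed and null")
    n_tested = observed.total
    results = []
    for i, cat in enumerate(observed.categories):
        k = int(observed.counts[i])
        p_exp = float(null.mean[i])
        p_exp = min(max(p_exp, 0.0), 1.0)
        test = stats.binomtest(k, n_tested, p_exp, alternative="two-sided")
        obs_prop = k / n_tested
        if obs_prop > p_exp:
            direction = "enriched"
        elif obs_prop < p_exp:
            direction = "depleted"
        else:
            direction = "none"
        results.append(
            EnrichmentResult(
                category=cat,
                observed=k,
                expected_proportion=p_exp,
                p_binomial=float(test.pvalue),
                direction=direction,
            )
        )
    ks = None
    if (
        observed.distances is not None
        and len(observed.distances)
        and null.pooled_distances is not None
        and len(null.pooled_distances)
    ):
        res = stats.ks_2samp(observed.distances, null.pooled_distances)
        ks = (float(res.statistic), float(res.pvalue))
    return results, ks


# ---------------------------------------------------------------- subfeatures

SUBFEATURE_PRECEDENCE = ("exon", "utr5", "utr3", "intron", "flank")


def _subfeature_intervals(tus: list[TUModel], genome: GenomeIndex | None):
    classes: dict[str, list[Interval]] = {c: [] for c in SUBFEATURE_PRECEDENCE}
    for tu in tus:
        classes["exon"].extend(tu.exons)
        if tu.utr5 is not None:
            classes["utr5"].append(tu.utr5)
        if tu.utr3 is not None:
            classes["utr3"].append(tu.utr3)
        classes["intron"].append(tu.span)
        classes["flank"].append(tu.extent(genome))
    return classes


def subfeature_overlap_profile(
    elements: AnnotationSet,
    tus: list[TUModel],
    genome: GenomeIndex | None = None,
) -> dict:
    """Assign TU-overlapping elements one subfeature by precedence.

    Precedence: exon > 5'UTR > 3'UTR > intron > flank — an element touching
    an exon anywhere counts as exonic. Expected fractions are the
    precedence-classified base composition of the merged TU extents (the
    analytic limit of a uniform point-integration null).
    """
    classes = _subfeature_intervals(tus, genome)
    by_chrom: dict[str, dict[str, list[Interval]]] = {}
    for cls, ivs in classes.items():
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, {c: [] for c in SUBFEATURE_PRECEDENCE})[
                cls
            ].append(iv)
    observed = {c: 0 for c in SUBFEATURE_PRECEDENCE}
    n_overlapping = 0
    extents = merged_tu_extents(tus, genome)
    extents_by_chrom = extents.by_chrom()
    for rec in elements:
        chrom_ext = extents_by_chrom.get(rec.interval.chrom, [])
        if not any(rec.interval.overlaps(x.interval) for x in chrom_ext):
            continue
        n_overlapping += 1
        chrom_classes = by_chrom.get(rec.interval.chrom, {})
        for cls in SUBFEATURE_PRECEDENCE:
            if any(rec.interval.overlaps(iv) for iv in chrom_classes.get(cls, [])):
                observed[cls] += 1
                break
    expected = _expected_subfeature_fractions(tus, genome)
    return {
        "n_overlapping": n_overlapping,
        "observed_counts": observed,
        "observed_fractions": {
            c: observed[c] / n_overlapping if n_overlapping else 0.0
            for c in SUBFEATURE_PRECEDENCE
        },
        "expected_fractions": expected,
    }


def _expected_subfeature_fractions(
    tus: list[TUModel], genome: GenomeIndex | None
) -> dict[str, float]:
    """Per-base precedence classification of merged TU-extent bases."""
    classes = _subfeature_intervals(tus, genome)
    extents = merged_tu_extents(tus, genome)
    totals = {c: 0 for c in SUBFEATURE_PRECEDENCE}
    grand = 0
    for rec in extents:
        seg = rec.interval
        points = {seg.start, seg.end}
        for cls in SUBFEATURE_PRECEDENCE:
            for iv in classes[cls]:
                if iv.chrom != seg.chrom:
                    continue
                if iv.start > seg.start and iv.start < seg.end:
                    points.add(iv.start)
                if iv.end > seg.start and iv.end < seg.end:
                    points.add(iv.end)
        cuts = sorted(points)
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            grand += hi - lo
            mid = (lo + hi) / 2
            for cls in SUBFEATURE_PRECEDENCE:
                if any(
                    iv.chrom == seg.chrom and iv.start <= mid < iv.end
                    for iv in classes[cls]
                ):
                    totals[cls] += hi - lo
                    break
    return {
        c: totals[c] / grand if grand else 0.0 for c in SUBFEATURE_PRECEDENCE
    }


# ---------------------------------------------------------------- chi-square

def chi_square_representation(table) -> dict:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = row @ col / total
    warning = bool((expected < 1).any())
    if (expected == 0).any():
        chi2 = 0.0
    else:
        chi2 = float(np.sum((obs - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return {"chi2": chi2, "p": p, "df": 1, "low_expected_warning": warning}


# ---------------------------------------------------------------- expression

@dataclass
class ExpressionCall:
    element_id: str
    status: str  # "none" | "partial" | "complete"
    supporting_tissues: list[str] = field(default_factory=list)


def classify_expression_support(
    elements: list[tuple[str, Interval]],
    transcripts_by_tissue: dict[str, AnnotationSet],
) -> tuple[list[ExpressionCall], int]:
    """Classify each element's transcriptional support across tissues.

    ``elements`` are (id, internal-region interval with the element strand)
    pairs — the internal region is the span between the two LTRs. Complete
    expression requires a single same-strand transcript covering the whole
    internal region in at least one tissue; any same-strand overlap short of
    that is partial. Unstranded transcripts are excluded (their count is
    returned as a warning tally).
    """
    calls = []
    n_unstranded = 0
    for el_id, internal in elements:
        status = "none"
        tissues: list[str] = []
        for tissue, tset in transcripts_by_tissue.items():
            tissue_status = None
            for tr in tset:
                if tr.interval.strand == ".":
                    n_unstranded += 1
                    continue
                if internal.strand == "." or tr.interval.strand != internal.strand:
                    continue
                if not tr.interval.overlaps(internal):
                    continue
                if tr.interval.contains(internal):
                    tissue_status = "complete"
                    break
                tissue_status = tissue_status or "partial"
            if tissue_status is not None:
                tissues.append(tissue)
                if tissue_status == "complete":
                    status = "complete"
                elif status != "complete":
                    status = "partial"
        calls.append(ExpressionCall(el_id, status, tissues))
    return calls, n_unstranded
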