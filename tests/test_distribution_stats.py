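"""Density, clusters, the random-integration null, TU profiles and tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ltrscape.distribution_stats import (
    DistanceProfile,
    TUModel,
    call_clusters,
    category_enrichment_tests,
    chi_square_representation,
    chromosome_density_table,
    classify_expression_support,
    clustered_fraction,
    density_correlates,
    distance_categories,
    merged_tu_extents,
    simulate_random_integrations,
    subfeature_overlap_profile,
    tu_distance_profile,
)
from ltrscape.genome_model import Annotation, AnnotationSet, GenomeIndex, Interval


def _elements(positions, chrom="c", length=100, source="structural"):
    return AnnotationSet(
        Annotation(Interval(chrom, p, p + length), source, id=f"e{i}")
        for i, p in enumerate(positions)
    ).sort()


class TestDensity:
    def test_ten_elements_on_ten_mb(self):
        genome = GenomeIndex({"c": 10_000_000})
        table = chromosome_density_table(
            _elements(range(0, 1_000_000, 100_000)), genome
        )
        assert table.loc[0, "density_per_mb"] == pytest.approx(1.0)

    def test_empty_chromosome_zero(self):
        genome = GenomeIndex({"c": 10_000_000, "empty": 2_000_000})
        table = chromosome_density_table(_elements([5]), genome)
        assert table.set_index("chrom").loc["empty", "density_per_mb"] == 0.0

    def test_random_placements_match_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        genome = GenomeIndex({"a": 3_000_000, "b": 7_000_000})
        pos_a = rng.integers(0, 2_999_000, 13)
        pos_b = rng.integers(0, 6_999_000, 29)
        els = AnnotationSet(
            [Annotation(Interval("a", int(p), int(p) + 50), "homology") for p in pos_a]
            + [Annotation(Interval("b", int(p), int(p) + 50), "homology") for p in pos_b]
        )
        table = chromosome_density_table(els, genome).set_index("chrom")
        assert table.loc["a", "density_per_mb"] == pytest.approx(13 / 3.0)
        assert table.loc["b", "density_per_mb"] == pytest.approx(29 / 7.0)


class TestDensityCorrelates:
    def _table(self, rng, n=30, b=1.2, c=-0.8, noise=0.05):
        import pandas as pd

        length = rng.uniform(5e6, 2e8, n)
        recomb = rng.uniform(0.5, 10.0, n)
        log_density = (
            0.5 + b * np.log10(length) + c * np.log10(recomb)
            + rng.normal(0, noise, n)
        )
        return pd.DataFrame(
            {
                "chrom": [f"chr{i}" for i in range(n)],
                "density_per_mb": 10.0 ** log_density,
                "length": length,
                "gene_density": rng.uniform(1, 50, n),
                "recomb_rate": recomb,
            }
        )

    def test_recovers_planted_coefficients(self):
        rng = np.random.default_rng(8)
        res = density_correlates(self._table(rng))
        lo, hi = res.glm_conf_int.loc["log_length"]
        assert lo <= 1.2 <= hi
        lo, hi = res.glm_conf_int.loc["log_recomb_rate"]
        assert lo <= -0.8 <= hi

    def test_density_proportional_to_length_gives_r_one(self):
        rng = np.random.default_rng(9)
        table = self._table(rng, c=0.0, noise=0.0, b=1.0)
        res = density_correlates(table)
        r, _ = res.pearson[("density_per_mb", "length")]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_exclusions_are_applied(self):
        rng = np.random.default_rng(10)
        table = self._table(rng, n=10)
        res = density_correlates(table, exclusions=["chr0", "chr1"])
        assert res.n_chromosomes == 8 and res.excluded == ["chr0", "chr1"]

    def test_constant_density_is_error(self):
        rng = np.random.default_rng(11)
        table = self._table(rng, n=5)
        table["density_per_mb"] = 2.0
        with pytest.raises(ValueError, match="zero variance"):
            density_correlates(table)

    def test_nonpositive_value_names_chromosome(self):
        rng = np.random.default_rng(12)
        table = self._table(rng, n=5)
        table.loc[2, "recomb_rate"] = 0.0
        with pytest.raises(ValueError, match="chr2"):
            density_correlates(table)


class TestCallClusters:
    def test_five_elements_within_window_form_cluster(self):
        els = _elements(range(0, 800_000, 160_000))
        clusters = call_clusters(els)
        assert len(clusters) == 1 and len(clusters[0].member_ids) == 5

    def test_four_elements_insufficient(self):
        els = _elements(range(0, 500_000, 125_000))
        assert call_clusters(els) == []

    def test_five_elements_spread_past_window_no_cluster(self):
        els = _elements(range(0, 2_000_000, 400_000))
        assert call_clusters(els) == []

    def test_fifty_six_elements_one_window_union(self):
        rng = np.random.default_rng(1)
        positions = np.sort(rng.integers(0, 1_200_000, 56))
        clusters = call_clusters(_elements(positions))
        assert len(clusters) == 1
        assert len(clusters[0].member_ids) == 56
        assert clusters[0].density_per_mb >= 5

    def test_clustered_fraction_counts_members(self):
        els = _elements(list(range(0, 800_000, 160_000)) + [5_000_000])
        assert clustered_fraction(els) == pytest.approx(5 / 6)


class TestRandomIntegrationNull:
    def test_single_point_never_clusters(self):
        s = simulate_random_integrations(
            1, GenomeIndex({"c": 10_000_000}), reps=20, seed=0
        )
        assert s.mean == 0.0 and s.values.max() == 0.0

    def test_five_points_on_one_mb_always_cluster(self):
        s = simulate_random_integrations(
            5, GenomeIndex({"c": 1_000_000}), reps=20, seed=0
        )
        assert s.mean == 1.0 and s.values.min() == 1.0

    def test_seeded_and_bit_reproducible(self):
        g = GenomeIndex({"a": 5_000_000, "b": 2_000_000})
        a = simulate_random_integrations(50, g, reps=30, seed=3)
        b = simulate_random_integrations(50, g, reps=30, seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_random_integrations(50, g, reps=30, seed=4)
        assert not np.array_equal(a.values, c.values)

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_random_integrations(0, GenomeIndex({"c": 100}), reps=1)
        with pytest.raises(ValueError):
            simulate_random_integrations(1, GenomeIndex({"c": 100}), reps=0)

    def test_gap_bases_never_sampled(self):
        g = GenomeIndex(
            {"c": 1_000_000},
            assembly_gaps=[Interval("c", 0, 990_000)],
        )
        # all mass in the last 10 kb -> every draw clusters with n >= 5
        s = simulate_random_integrations(5, g, reps=10, seed=1)
        assert s.mean == 1.0

    def test_monte_carlo_error_shrinks_with_replicates(self):
        g = GenomeIndex({"c": 50_000_000})
        means_small = [
            simulate_random_integrations(60, g, reps=25, seed=s).mean
            for s in range(12)
        ]
        means_large = [
            simulate_random_integrations(60, g, reps=100, seed=100 + s).mean
            for s in range(12)
        ]
        ratio = np.std(means_small) / max(np.std(means_large), 1e-12)
        assert ratio > 1.2  # ~2 expected for 4x replicates


def _tu(chrom, start, end, strand="+", gene_id="g", exons=None, utr5=None, utr3=None):
    return TUModel(
        gene_id=gene_id,
        biotype="protein_coding",
        span=Interval(chrom, start, end, strand),
        exons=exons or [],
        utr5=utr5,
        utr3=utr3,
    )


class TestTuDistanceProfile:
    def _genome(self):
        return GenomeIndex({"c": 1_000_000, "bare": 100_000})

    def test_element_within_flank_is_tu_category(self):
        tus = [_tu("c", 50_000, 60_000)]
        els = _elements([45_900])  # 4 kb from the gene span, inside the flank
        profile = tu_distance_profile(els, tus, self._genome())
        assert profile.counts[0] == 1

    def test_ninety_five_kb_bins_to_90_100(self):
        tus = [_tu("c", 500_000, 510_000)]
        els = _elements([399_900])  # ends 95 kb before the 5 kb flank start
        profile = tu_distance_profile(els, tus, self._genome())
        cats = distance_categories()
        assert profile.counts[cats.index("90-100kb")] == 1

    def test_beyond_100kb_category(self):
        tus = [_tu("c", 500_000, 510_000)]
        els = _elements([344_000])
        profile = tu_distance_profile(els, tus, self._genome())
        assert profile.counts[distance_categories().index(">100kb")] == 1

    def test_contig_without_annotation_is_nd(self):
        tus = [_tu("c", 500_000, 510_000)]
        els = _elements([5_000], chrom="bare")
        profile = tu_distance_profile(els, tus, self._genome())
        assert profile.counts[-1] == 1

    def test_counts_always_sum_to_total(self):
        rng = np.random.default_rng(2)
        tus = [_tu("c", int(s), int(s) + 5000, gene_id=f"g{i}")
               for i, s in enumerate(rng.integers(0, 900_000, 15))]
        els = _elements(sorted(rng.integers(0, 999_000, 200)))
        profile = tu_distance_profile(els, tus, self._genome())
        assert int(profile.counts.sum()) == profile.total == 200

    def test_conservation_violation_is_asserted(self):
        with pytest.raises(AssertionError):
            DistanceProfile(
                categories=distance_categories(),
                counts=np.zeros(13),
                total=5,
            )

    def test_null_tu_proportion_converges_to_base_fraction(self):
        """Null TU-category mass approaches the TU-extent base fraction."""
        genome = GenomeIndex({"c": 1_000_000})
        tus = [_tu("c", s, s + 40_000, gene_id=f"g{s}")
               for s in range(100_000, 900_000, 200_000)]
        extents = merged_tu_extents(tus, genome)
        q = extents.total_span() / genome.total_length
        null = simulate_random_integrations(
            200, genome, reps=300, seed=5, statistic="distance_profile", tus=tus
        )
        se = null.sd[0] / np.sqrt(null.reps)
        assert abs(null.mean[0] - q) <= max(3 * se, 0.01)


class TestEnrichmentTests:
    def _profile_and_null(self, seed=0, n=120):
        genome = GenomeIndex({"c": 2_000_000})
        tus = [_tu("c", s, s + 30_000, gene_id=f"g{s}")
               for s in range(100_000, 1_900_000, 400_000)]
        rng = np.random.default_rng(seed)
        els = _elements(sorted(rng.integers(0, 1_999_000, n)))
        profile = tu_distance_profile(els, tus, genome)
        null = simulate_random_integrations(
            n, genome, reps=200, seed=seed, statistic="distance_profile", tus=tus
        )
        return profile, null

    def test_random_elements_show_no_strong_enrichment(self):
        profile, null = self._profile_and_null()
        results, ks = category_enrichment_tests(profile, null)
        assert min(r.p_binomial for r in results) > 1e-4
        assert ks is not None and ks[0] < 0.2

    def test_binomial_matches_closed_form(self):
        profile, null = self._profile_and_null()
        for r, k in zip(
            category_enrichment_tests(profile, null)[0], profile.counts
        ):
            expected = stats.binomtest(
                int(k), profile.total, r.expected_proportion
            ).pvalue
            assert r.p_binomial == pytest.approx(expected)

    def test_category_mismatch_is_error(self):
        profile, null = self._profile_and_null()
        null.categories = list(null.categories[:-1])
        with pytest.raises(ValueError):
            category_enrichment_tests(profile, null)

    def test_ks_statistic_matches_brute_force_sup_difference(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 100_000, 300)
        b = rng.uniform(0, 120_000, 500)
        d_scipy = stats.ks_2samp(a, b).statistic
        grid = np.concatenate([a, b])
        cdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        cdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert d_scipy == pytest.approx(np.max(np.abs(cdf_a - cdf_b)))


class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = chi_square_representation([[25, 25], [25, 25]])
        assert res["chi2"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        res = chi_square_representation([[10, 20], [20, 10]])
        assert res["chi2"] == pytest.approx(20 / 3)

    def test_matches_brute_force_on_small_tables(self):
        """Exhaustive agreement with sum((O-E)^2/E) for all tables n <= 12."""
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if a + b + c + d == 0 or (a + b) == 0 or (c + d) == 0:
                continue
            if (a + c) == 0 or (b + d) == 0:
                continue
            obs = np.array([[a, b], [c, d]], float)
            n = obs.sum()
            exp = np.outer(obs.sum(1), obs.sum(0)) / n
            brute = np.sum((obs - exp) ** 2 / exp)
            res = chi_square_representation(obs)
            assert res["chi2"] == pytest.approx(brute)

    def test_low_expected_cell_warns(self):
        res = chi_square_representation([[1, 0], [0, 1]])
        assert res["low_expected_warning"]


class TestSubfeatureOverlap:
    def _tus(self):
        exons = [Interval("c", 10_000, 11_000, "+"), Interval("c", 15_000, 16_000, "+")]
        return [
            _tu(
                "c", 10_000, 20_000,
                exons=exons,
                utr5=Interval("c", 9_000, 10_000, "+"),
                utr3=Interval("c", 20_000, 20_500, "+"),
            )
        ]

    def test_element_inside_intron(self):
        tus = [_tu("c", 10_000, 20_000, exons=[Interval("c", 10_000, 11_000, "+")])]
        prof = subfeature_overlap_profile(_elements([13_000]), tus)
        assert prof["observed_counts"]["intron"] == 1

    def test_exon_precedence_over_intron(self):
        tus = [_tu("c", 10_000, 20_000, exons=[Interval("c", 10_000, 11_000, "+")])]
        prof = subfeature_overlap_profile(_elements([10_950]), tus)
        assert prof["observed_counts"]["exon"] == 1

    def test_expected_fractions_match_per_base_oracle(self):
        genome = GenomeIndex({"c": 1_000_000})
        tus = self._tus()
        prof = subfeature_overlap_profile(AnnotationSet(), tus, genome)
        # per-base bitmap with precedence exon > utr5 > utr3 > intron > flank
        extent = tus[0].extent(genome)
        classes = np.full(len(extent), 4)  # flank
        off = extent.start
        span = tus[0].span
        classes[span.start - off:span.end - off] = 3
        if tus[0].utr3:
            classes[tus[0].utr3.start - off:tus[0].utr3.end - off] = 2
        if tus[0].utr5:
            classes[tus[0].utr5.start - off:tus[0].utr5.end - off] = 1
        for ex in tus[0].exons:
            classes[ex.start - off:ex.end - off] = 0
        expected = prof["expected_fractions"]
        for i, name in enumerate(("exon", "utr5", "utr3", "intron", "flank")):
            assert expected[name] == pytest.approx(
                np.mean(classes == i), abs=1e-9
            )


class TestExpression:
    def _transcripts(self, iv):
        return {"ovary": AnnotationSet([Annotation(iv, "homology", id="t1")])}

    def test_full_cover_same_strand_is_complete(self):
        internal = Interval("c", 1000, 3000, "+")
        calls, _ = classify_expression_support(
            [("e1", internal)], self._transcripts(Interval("c", 900, 3100, "+"))
        )
        assert calls[0].status == "complete"
        assert calls[0].supporting_tissues == ["ovary"]

    def test_half_cover_is_partial(self):
        internal = Interval("c", 1000, 3000, "+")
        calls, _ = classify_expression_support(
            [("e1", internal)], self._transcripts(Interval("c", 1000, 2000, "+"))
        )
        assert calls[0].status == "partial"

    def test_antisense_only_is_none(self):
        internal = Interval("c", 1000, 3000, "+")
        calls, _ = classify_expression_support(
            [("e1", internal)], self._transcripts(Interval("c", 900, 3100, "-"))
        )
        assert calls[0].status == "none"

    def test_unstranded_transcript_excluded_with_warning(self):
        internal = Interval("c", 1000, 3000, "+")
        calls, n_unstranded = classify_expression_support(
            [("e1", internal)], self._transcripts(Interval("c", 900, 3100, "."))
        )
        assert calls[0].status == "none" and n_unstranded == 1

    def test_planted_expression_recovered_from_simulation(self, sim):
        internals = [
            (t.id, Interval(t.chrom, t.internal[0], t.internal[1], t.strand))
            for t in sim.truth_of_type("SIE")
        ]
        calls, _ = classify_expression_support(internals, sim.transcripts)
        by_id = {c.element_id: c.status for c in calls}
        for t in sim.truth_of_type("SIE"):
            assert by_id[t.id] == t.expression
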