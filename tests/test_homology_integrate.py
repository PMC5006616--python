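"""Homology filtering, conflict removal, DIRS rule, secondary stage, finalize."""

import numpy as np
import pytest

from ltrscape.evidence_classify import DomainHit
from ltrscape.genome_model import (
    Annotation,
    AnnotationSet,
    Interval,
)
from ltrscape.homology_integrate import (
    FilterParams,
    HomologyHit,
    apply_conflict_filter,
    best_reciprocal_hits,
    call_dirs,
    filter_homology_hits,
    finalize_annotation,
    import_repeatmasker,
    reciprocal_validate,
    secondary_expand,
)
from ltrscape.structural_detect import elements_to_annotations


def _hit(e, length, start=0, chrom="chr1", qid="q"):
    return HomologyHit(
        query_id=qid,
        target=Interval(chrom, start, start + length),
        e_value=e,
        pct_identity=0.9,
        aln_len=length,
    )


class TestFilterHomologyHits:
    @pytest.mark.parametrize(
        "e,length,kept",
        [
            (1e-9, 500, False),   # E too weak
            (1e-12, 99, False),   # too short
            (1e-10, 100, True),   # both boundaries inclusive
            (1e-20, 5000, True),
        ],
    )
    def test_threshold_boundaries(self, e, length, kept):
        out = filter_homology_hits([_hit(e, length)])
        assert (len(out) == 1) == kept

    def test_negative_evalue_rejected_at_construction(self):
        with pytest.raises(ValueError):
            _hit(-1e-5, 200)

    def test_order_invariance_of_filter_then_merge(self):
        from ltrscape.genome_model import merge_intervals

        rng = np.random.default_rng(2)
        hits = [
            _hit(10.0 ** -float(rng.integers(5, 30)), int(l), start=int(s))
            for s, l in zip(rng.integers(0, 20000, 40), rng.integers(50, 400, 40))
        ]
        def run(h):
            return [
                (r.interval.chrom, r.interval.start, r.interval.end)
                for r in merge_intervals(filter_homology_hits(h), max_gap=10)
            ]
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert run(hits) == run(shuffled)


RM_OUT = """\
   SW   perc perc perc  query     position in query            matching repeat
score   div. del. ins.  sequence  begin end (left)  repeat  class/family  begin end (left) ID

  463   11.5  0.0  0.0  chr1      1001  1200 (5000) + ERV1-x  LTR/ERVL       1  200  (0)   1
  220   20.1  1.0  0.0  chr1      3001  3500 (2700) C CR1-y   LINE/CR1       1  500  (0)   2
"""


class TestImportRepeatmasker:
    def test_partition_by_class(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(RM_OUT)
        ltr, other = import_repeatmasker(path)
        assert len(ltr) == 1 and ltr[0].label == "LTR/ERVL"
        assert ltr[0].interval.start == 1000 and ltr[0].interval.end == 1200
        assert len(other) == 1 and other[0].label == "LINE/CR1"
        assert other[0].interval.strand == "-"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text("")
        ltr, other = import_repeatmasker(path)
        assert len(ltr) == 0 and len(other) == 0

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text("garbage line with words only here now ok\n")
        with pytest.raises(ValueError, match=":1"):
            import_repeatmasker(path)


class TestConflictFilter:
    def _element(self, start=0, end=1000):
        return AnnotationSet(
            [Annotation(Interval("chr1", start, end), "homology", id="el1")]
        )

    def _cr1(self, start, end):
        return AnnotationSet(
            [Annotation(Interval("chr1", start, end), "homology", label="LINE/CR1")]
        )

    def test_majority_covered_removed(self):
        kept, removed = apply_conflict_filter(self._element(), self._cr1(0, 600))
        assert len(kept) == 0 and removed[0]["dominating_class"] == "LINE/CR1"

    def test_zero_overlap_retained(self):
        kept, removed = apply_conflict_filter(self._element(), self._cr1(5000, 6000))
        assert len(kept) == 1 and removed == []

    def test_minor_overlap_retained(self):
        kept, _ = apply_conflict_filter(self._element(), self._cr1(0, 300))
        assert len(kept) == 1


class TestReciprocalValidate:
    def _element(self):
        return AnnotationSet(
            [Annotation(Interval("chr1", 0, 500), "homology", id="el1")]
        )

    def test_strong_hit_validates(self):
        out = reciprocal_validate(self._element(), {"el1": _hit(1e-20, 300)})
        assert out[0].attrs["validated"] is True

    def test_no_hit_flags_unvalidated(self):
        out = reciprocal_validate(self._element(), {})
        assert out[0].attrs["validated"] is False

    def test_weak_hit_flags_unvalidated(self):
        out = reciprocal_validate(self._element(), {"el1": _hit(1e-8, 300)})
        assert out[0].attrs["validated"] is False

    def test_best_hit_selection(self):
        hits = [
            HomologyHit("el1", Interval("c", 0, 100), 1e-8, 0.9, 100, bitscore=50),
            HomologyHit("el1", Interval("c", 0, 100), 1e-20, 0.9, 100, bitscore=90),
        ]
        best = best_reciprocal_hits({"el1": hits})
        assert best["el1"].e_value == 1e-20


class TestCallDirs:
    def _hit(self, domain, e):
        return DomainHit(None, domain, "protein", e, frame=1)

    def test_rt_plus_yr_passes(self):
        assert call_dirs([self._hit("RT", 1e-16), self._hit("YR", 1e-13)])

    def test_rt_alone_fails(self):
        assert not call_dirs([self._hit("RT", 1e-16)])

    def test_rt_boundary_fails(self):
        assert not call_dirs([self._hit("RT", 1e-14), self._hit("MT", 1e-13)])

    def test_exact_boundaries_pass(self):
        assert call_dirs([self._hit("RT", 1e-15), self._hit("MT", 1e-12)])


class TestSecondaryExpand:
    def _existing(self):
        return AnnotationSet(
            [Annotation(Interval("chr1", 1000, 2000), "homology")]
        )

    def test_disjoint_hit_becomes_secondary(self):
        out = secondary_expand([_hit(1e-12, 150, start=5000)], self._existing())
        assert len(out) == 1 and out[0].source == "secondary"

    def test_contained_hit_absorbed(self):
        out = secondary_expand([_hit(1e-12, 150, start=1200)], self._existing())
        assert len(out) == 0

    def test_short_hit_rejected(self):
        out = secondary_expand([_hit(1e-12, 80, start=5000)], self._existing())
        assert len(out) == 0

    def test_partial_overlap_kept_for_downstream_merge(self):
        out = secondary_expand([_hit(1e-12, 150, start=1900)], self._existing())
        assert len(out) == 1

    def test_recovers_planted_fragments(self, sim, detected):
        """Planted fragments >= 100 bp come back as secondary records."""
        structural = elements_to_annotations(detected)
        secondary = secondary_expand(sim.blast_hits, structural)
        spans = {
            (r.interval.chrom, r.interval.start, r.interval.end) for r in secondary
        }
        eligible = [
            t for t in sim.truth_of_type("fragment")
            if t.end - t.start >= 100 and t.divergence <= 0.2
        ]
        recovered = sum((t.chrom, t.start, t.end) in spans for t in eligible)
        assert recovered / len(eligible) >= 0.9


class TestFinalize:
    def test_worked_arithmetic(self):
        homology = AnnotationSet(
            [Annotation(Interval("chr1", 0, 10000), "homology")]
        )
        structural = AnnotationSet(
            [Annotation(Interval("chr1", 8000, 13000), "structural")]
        )
        secondary = AnnotationSet(
            [Annotation(Interval("chr1", 20000, 21000), "secondary")]
        )
        final, report = finalize_annotation(homology, structural, secondary)
        assert report.union == 14000
        assert report.categories[frozenset({"homology"})] == 8000
        assert report.categories[frozenset({"homology", "structural"})] == 2000
        assert report.categories[frozenset({"structural"})] == 3000
        assert report.categories[frozenset({"secondary"})] == 1000
        assert final.total_span() == 14000

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        def spans(source):
            return AnnotationSet(
                Annotation(Interval("c", int(s), int(s) + int(l)), source)
                for s, l in zip(rng.integers(0, 50000, 20), rng.integers(1, 800, 20))
            )
        sets = [spans(src) for src in ("homology", "structural", "secondary")]
        final1, _ = finalize_annotation(*sets)
        final2, _ = finalize_annotation(*sets)
        assert [
            (r.interval.start, r.interval.end) for r in final1
        ] == [(r.interval.start, r.interval.end) for r in final2]

    def test_union_matches_bitmap_oracle_and_conserves(self):
        rng = np.random.default_rng(11)
        L = 30000
        bitmap = np.zeros(L, bool)
        sets = []
        for source in ("homology", "structural", "secondary"):
            records = AnnotationSet()
            for s, l in zip(rng.integers(0, L - 900, 25), rng.integers(1, 800, 25)):
                records.add(Annotation(Interval("c", int(s), int(s) + int(l)), source))
                bitmap[int(s):int(s) + int(l)] = True
            sets.append(records)
        final, report = finalize_annotation(*sets)
        assert report.union == int(bitmap.sum())
        assert sum(report.categories.values()) == report.union

    def test_unvalidated_without_structural_support_dropped(self):
        homology = AnnotationSet(
            [
                Annotation(Interval("chr1", 0, 1000), "homology", id="bad",
                           attrs={"validated": False}),
                Annotation(Interval("chr1", 5000, 6000), "homology", id="ok",
                           attrs={"validated": False}),
            ]
        )
        structural = AnnotationSet(
            [Annotation(Interval("chr1", 5500, 9000), "structural")]
        )
        final, report = finalize_annotation(homology, structural, AnnotationSet())
        assert [d["id"] for d in report.dropped_unvalidated] == ["bad"]
        assert final.total_span() == 4000  # 5000-9000 merged
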