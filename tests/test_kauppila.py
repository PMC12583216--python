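"""Kauppila grading rules, severity tiers, segment geometry, mask scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aacscore import kauppila
from aacscore.kauppila import (
    SEGMENT_KEYS,
    KauppilaScore,
    SegmentKey,
    Severity,
    classify_severity,
    grade_segment,
    score_from_masks,
    segment_spans,
    total_score,
)


class TestGradeSegment:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.0, 0),
            (0.01, 1), (0.2, 1), (0.33, 1),
            (1 / 3, 2), (0.5, 2), (2 / 3, 2),
            (0.67, 3), (0.8, 3), (1.0, 3),
        ],
    )
    def test_grading_rules(self, fraction, expected):
        assert grade_segment(fraction) == expected

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan"), float("inf")])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            grade_segment(bad)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_with_full_image(self, f):
        g = grade_segment(f)
        assert g in (0, 1, 2, 3)
        # monotone: a slightly larger fraction never grades lower
        if f < 1.0:
            assert grade_segment(min(1.0, f + 1e-3)) >= g


class TestTotalsAndSeverity:
    def test_total_sums_eight_grades(self):
        grades = dict(zip(SEGMENT_KEYS, [1, 0, 2, 0, 3, 0, 0, 0]))
        assert total_score(grades) == 6
        assert total_score({k: 0 for k in SEGMENT_KEYS}) == 0
        assert total_score({k: 3 for k in SEGMENT_KEYS}) == 24

    def test_total_rejects_missing_or_bad_grades(self):
        grades = {k: 1 for k in SEGMENT_KEYS}
        del grades[SegmentKey("L3", "posterior")]
        with pytest.raises(ValueError, match="missing"):
            total_score(grades)
        grades = {k: 1 for k in SEGMENT_KEYS}
        grades[SegmentKey("L1", "anterior")] = 4
        with pytest.raises(ValueError):
            total_score(grades)

    def test_severity_partition_has_no_gaps_or_overlaps(self):
        expected = [Severity.no_mild] * 5 + [Severity.moderate] * 11 + [Severity.severe] * 9
        assert [classify_severity(t) for t in range(25)] == expected

    @pytest.mark.parametrize("bad", [-1, 25])
    def test_severity_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            classify_severity(bad)

    def test_score_record_consistency_enforced(self):
        grades = {k: 1 for k in SEGMENT_KEYS}
        s = KauppilaScore.from_grades(grades)
        assert s.total == 8 and s.category is Severity.moderate
        with pytest.raises(ValueError):
            KauppilaScore(grades=grades, total=9)


def _mask_from_rows(row_spans, shape=(400, 60), cols=(20, 50)):
    m = np.zeros(shape, dtype=np.uint8)
    for lab, (r0, r1) in enumerate(row_spans, start=1):
        m[r0:r1, cols[0]:cols[1]] = lab
    return m


class TestSegmentSpans:
    def test_midpoint_boundary(self):
        m = _mask_from_rows([(100, 200), (220, 320), (330, 350), (360, 380), (390, 399)])
        spans = segment_spans(m)
        assert spans["L1"] == (100, 210)  # midpoint of [200, 220)
        assert spans["L2"][0] == 210

    def test_l4_ends_at_midpoint_of_l4_l5_gap(self):
        m = _mask_from_rows([(10, 40), (50, 80), (90, 120), (130, 160), (170, 200)])
        spans = segment_spans(m)
        assert spans["L4"] == ((120 + 130) // 2, (160 + 170) // 2)

    def test_missing_label_reported_by_name(self):
        m = _mask_from_rows([(10, 40), (50, 80), (90, 120), (130, 160), (170, 200)])
        m[m == 3] = 0
        with pytest.raises(ValueError, match="L3"):
            segment_spans(m)

    def test_fragmented_label_reported(self):
        m = _mask_from_rows([(10, 40), (50, 80), (90, 120), (130, 160), (170, 200)])
        m[60:65] = 0  # split L2
        with pytest.raises(ValueError, match="L2"):
            segment_spans(m)

    def test_phantom_spans_match_generator_geometry(self, default_spec):
        from aacscore import phantom

        s = phantom.make_phantom(default_spec, seed=0)
        spans = segment_spans(s.vertebra_mask)
        # analytic: vertebrae 36 rows, gaps 10, top margin (256-220)//2 = 18
        starts = [18 + i * 46 for i in range(5)]
        assert spans["L1"] == (18, 36 + 18 + 5)  # L1 sup .. midpoint of first gap
        for i, level in enumerate(("L2", "L3")):
            assert spans[level][0] == starts[i] + 36 + 5
        assert spans["L4"][1] == starts[3] + 36 + 5


class TestScoreFromMasks:
    def test_empty_calcification_scores_zero(self, default_spec):
        from aacscore import phantom

        s = phantom.make_phantom(default_spec, seed=0)
        score = score_from_masks(np.zeros_like(s.calcification_mask), s.vertebra_mask)
        assert score.total == 0 and score.category is Severity.no_mild

    def test_known_fractions_recovered(self, sample_with_calc):
        from aacscore.phantom import score_sample

        score = score_sample(sample_with_calc)
        assert score.grades[SegmentKey("L1", "anterior")] == 2
        assert score.grades[SegmentKey("L3", "posterior")] == 3
        assert score.total == 5

    def test_full_segment_strip_grades_three(self):
        from aacscore import phantom
        from aacscore.kauppila import SegmentKey

        spec = phantom.PhantomSpec(calcified_fractions={SegmentKey("L2", "anterior"): 1.0})
        s = phantom.make_phantom(spec, seed=1)
        assert phantom.score_sample(s).grades[SegmentKey("L2", "anterior")] == 3

    def test_shape_mismatch_rejected(self, default_spec):
        from aacscore import phantom

        s = phantom.make_phantom(default_spec, seed=0)
        with pytest.raises(ValueError, match="shape"):
            score_from_masks(np.zeros((10, 10)), s.vertebra_mask)

    def test_mirror_symmetry(self):
        """Flipping the image left-right and the anterior side preserves scores."""
        from aacscore import phantom
        from dataclasses import replace

        spec = phantom.PhantomSpec(
            calcified_fractions={SegmentKey("L1", "anterior"): 0.5,
                                 SegmentKey("L4", "posterior"): 0.2}
        )
        left = phantom.make_phantom(spec, seed=3)
        right = phantom.make_phantom(replace(spec, anterior_side="right"), seed=3)
        assert np.array_equal(left.calcification_mask[:, ::-1], right.calcification_mask)
        s_left = phantom.score_sample(left)
        s_right = phantom.score_sample(right)
        assert s_left.grades == s_right.grades
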