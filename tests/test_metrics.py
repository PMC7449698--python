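import numpy as np
import pytest

from readthrough_kit import (
    GenomicInterval,
    StrandedCoverageTrack,
    TranscriptAnnotation,
    class_fold_change,
    downstream_window,
    flag_readthrough,
    qpcr_occupancy,
    region_rank_test,
    region_set_signal,
    region_signal,
    replicate_correlation,
    three_prime_extension_index,
)
from readthrough_kit.metrics import ExtensionIndexRecord

from _oracles import naive_region_sum, rank_sum_pvalue_enumeration

SIZES = {"chrI": 3000}


def _feat(start, end, strand="+", name="snR1", cls="snoRNA"):
    return TranscriptAnnotation(name, GenomicInterval("chrI", start, end, strand), cls)


def _track(plus=0.0, minus=0.0):
    t = StrandedCoverageTrack.zeros(SIZES)
    t.depths["chrI"][0][:] = plus
    t.depths["chrI"][1][:] = minus
    return t


class TestExtensionIndex:
    def test_identical_tracks_give_unity(self):
        t = _track(plus=30.0)
        records, _ = three_prime_extension_index(t, _track(plus=30.0),
                                                 [_feat(100, 200)])
        assert records[0].ei3 == 1.0

    def test_pseudocount_arithmetic(self):
        # window signals 29 and 9 with eps 1 -> 30/10
        mut = _track()
        wt = _track()
        mut.depths["chrI"][0][200:350] = 29 / 150
        wt.depths["chrI"][0][200:350] = 9 / 150
        records, _ = three_prime_extension_index(mut, wt, [_feat(100, 200)])
        assert records[0].ei3 == pytest.approx(3.0)

    def test_empty_clamped_window_excluded_and_reported(self):
        feat_edge = _feat(2900, 3000, "+", name="edge")
        records, excluded = three_prime_extension_index(
            _track(plus=1.0), _track(plus=1.0), [feat_edge, _feat(100, 200)])
        assert excluded == ["edge"]
        assert [r.feature_id for r in records] == ["snR1"]

    def test_records_sorted_by_feature_id(self):
        feats = [_feat(500, 600, name="b"), _feat(100, 200, name="a")]
        records, _ = three_prime_extension_index(_track(plus=1.0),
                                                 _track(plus=1.0), feats)
        assert [r.feature_id for r in records] == ["a", "b"]

    def test_zero_eps_with_silent_wt_errors(self):
        with pytest.raises(ZeroDivisionError):
            three_prime_extension_index(_track(plus=1.0), _track(),
                                        [_feat(100, 200)], eps=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_recomputation(self, seed):
        from conftest import random_track
        rng = np.random.default_rng(300 + seed)
        mut = random_track(rng, SIZES)
        wt = random_track(rng, SIZES)
        feats = [_feat(300, 450, "+", "a"), _feat(900, 1000, "-", "b"),
                 _feat(1500, 1800, "+", "c")]
        records, _ = three_prime_extension_index(mut, wt, feats, window=150)
        for rec in records:
            feat = next(f for f in feats if f.id == rec.feature_id)
            win = downstream_window(feat, 150, SIZES)
            idx = 0 if feat.strand == "+" else 1
            m = naive_region_sum(*mut.depths["chrI"], win.start, win.end, feat.strand)
            w = naive_region_sum(*wt.depths["chrI"], win.start, win.end, feat.strand)
            assert rec.ei3 == pytest.approx((m + 1) / (w + 1), rel=1e-12)


class TestFlagReadthrough:
    def _rec(self, ei3, name="f"):
        return ExtensionIndexRecord(name, GenomicInterval("chrI", 0, 150, "+"),
                                    0.0, 0.0, ei3)

    def test_threshold_inclusive(self):
        flagged, frac = flag_readthrough([self._rec(1.5), self._rec(1.49)])
        assert len(flagged) == 1 and frac == 0.5

    def test_no_readthrough_fraction_zero(self):
        _, frac = flag_readthrough([self._rec(1.0)] * 5)
        assert frac == 0.0

    def test_fraction_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        recs = [self._rec(float(x)) for x in rng.uniform(0.5, 3.0, size=50)]
        fracs = [flag_readthrough(recs, threshold=t)[1]
                 for t in (1.0, 1.25, 1.5, 2.0, 2.5)]
        assert fracs == sorted(fracs, reverse=True)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            flag_readthrough([])


class TestClassFoldChange:
    def test_identity(self):
        t = _track(plus=10.0)
        feats = [_feat(100, 200, cls="NUT"), _feat(400, 600, cls="NUT")]
        assert class_fold_change(t, _track(plus=10.0), feats) == 1.0

    def test_doubled_signal(self):
        feats = [_feat(100, 300, cls="NUT"), _feat(500, 900, cls="NUT")]
        fold = class_fold_change(_track(plus=200.0), _track(plus=100.0), feats)
        assert fold == pytest.approx(2.0, rel=1e-4)

    def test_mixed_classes_rejected(self):
        feats = [_feat(100, 200, cls="NUT"), _feat(400, 600, cls="CUT")]
        with pytest.raises(ValueError, match="mixed"):
            class_fold_change(_track(), _track(), feats)

    def test_invariant_to_order_and_splitting(self):
        from conftest import random_track
        rng = np.random.default_rng(2)
        mut, wt = random_track(rng, SIZES), random_track(rng, SIZES)
        whole = [_feat(100, 400, cls="NUT", name="a"),
                 _feat(800, 1200, cls="NUT", name="b")]
        split = [_feat(800, 1000, cls="NUT", name="b1"),
                 _feat(100, 250, cls="NUT", name="a1"),
                 _feat(1000, 1200, cls="NUT", name="b2"),
                 _feat(250, 400, cls="NUT", name="a2")]
        assert class_fold_change(mut, wt, whole) == pytest.approx(
            class_fold_change(mut, wt, split), rel=1e-12)

    def test_matches_naive_double_loop(self):
        from conftest import random_track
        rng = np.random.default_rng(3)
        mut, wt = random_track(rng, SIZES), random_track(rng, SIZES)
        feats = [_feat(100, 400, cls="NUT", name="a"),
                 _feat(800, 1200, "-", cls="NUT", name="b")]
        num = den = 0.0
        for f in feats:
            idx = 0 if f.strand == "+" else 1
            for i in range(f.interval.start, f.interval.end):
                num += mut.depths["chrI"][idx][i]
                den += wt.depths["chrI"][idx][i]
        assert class_fold_change(mut, wt, feats) == pytest.approx(
            (num + 1) / (den + 1), rel=1e-12)


class TestRegionSetSignal:
    def test_uniform_track(self):
        t = _track(plus=3.0, minus=3.0)
        feats = [_feat(300, 400, name="a"), _feat(800, 900, "-", name="b")]
        vals, excluded = region_set_signal(t, feats, anchor="TES",
                                           offset_start=0, offset_end=150)
        assert excluded == []
        np.testing.assert_allclose(vals, 3.0 * 150)

    def test_empty_feature_list(self):
        vals, excluded = region_set_signal(_track(), [], anchor="TES")
        assert vals.size == 0 and excluded == []

    def test_missing_anchor_excluded(self):
        vals, excluded = region_set_signal(_track(plus=1.0),
                                           [_feat(100, 200)], anchor="CPS")
        assert excluded == ["snR1"] and vals.size == 0

    def test_upstream_offsets_match_bruteforce(self):
        from conftest import random_track
        rng = np.random.default_rng(4)
        t = random_track(rng, SIZES)
        feats = [_feat(500, 700, "+", name="a"), _feat(1500, 1700, "-", name="b")]
        vals, _ = region_set_signal(t, feats, anchor="TES",
                                    offset_start=-100, offset_end=500)
        # plus feature: TES 699, window [599, 1199); minus: TES 1500, [1001,1601)
        want_a = naive_region_sum(*t.depths["chrI"], 599, 1199, "+")
        want_b = naive_region_sum(*t.depths["chrI"], 1001, 1601, "-")
        np.testing.assert_allclose(vals, [want_a, want_b])


class TestRankTest:
    def test_exact_small_sample_case(self):
        p = region_rank_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(rank_sum_pvalue_enumeration([1, 2, 3],
                                                              [10, 11, 12]))

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(400 + seed)
        vals = rng.permutation(40)[:9].astype(float)
        a, b = vals[:4], vals[4:]
        assert region_rank_test(a, b) == pytest.approx(
            rank_sum_pvalue_enumeration(a, b))

    def test_identical_samples_p_one(self):
        assert region_rank_test([5.0, 5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, size=60)
        b = rng.normal(5, 1, size=60)
        assert region_rank_test(a, b) < 1e-4

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            region_rank_test([1.0], [2.0, 3.0])


class TestReplicateCorrelation:
    def _feats(self, n=6):
        return [_feat(100 + 300 * i, 250 + 300 * i, name=f"f{i}") for i in range(n)]

    def test_self_correlation_is_one(self):
        from conftest import random_track
        rng = np.random.default_rng(7)
        t = random_track(rng, SIZES)
        assert replicate_correlation(t, t, self._feats()) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        from conftest import random_track
        rng = np.random.default_rng(8)
        a, b = random_track(rng, SIZES), random_track(rng, SIZES)
        feats = self._feats()
        xs = np.array([region_signal(a, f.interval) for f in feats])
        ys = np.array([region_signal(b, f.interval) for f in feats])
        want = (np.sum((xs - xs.mean()) * (ys - ys.mean()))
                / np.sqrt(np.sum((xs - xs.mean()) ** 2)
                          * np.sum((ys - ys.mean()) ** 2)))
        assert replicate_correlation(a, b, feats) == pytest.approx(want, rel=1e-12)

    def test_zero_variance_is_nan(self):
        flat = _track(plus=2.0)
        from conftest import random_track
        rng = np.random.default_rng(9)
        assert np.isnan(replicate_correlation(flat, random_track(rng, SIZES),
                                              self._feats()))


class TestQpcrOccupancy:
    @pytest.mark.parametrize("eff,ct_in,ct_ip,expected", [
        (2.0, 20.0, 25.0, 0.03125),
        (2.0, 18.0, 18.0, 1.0),
        (1.9, 3.0, 0.0, 6.859),
    ])
    def test_formula(self, eff, ct_in, ct_ip, expected):
        assert qpcr_occupancy(eff, ct_in, ct_ip) == pytest.approx(expected)

    @pytest.mark.parametrize("eff", [1.0, 0.5, 2.5])
    def test_invalid_efficiency_rejected(self, eff):
        with pytest.raises(ValueError):
            qpcr_occupancy(eff, 20, 25)
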