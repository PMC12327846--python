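import numpy as np
import pytest

import chapkit as ck
from chapkit.peaks import _above_runs

from conftest import gaussian_bump_track, match_summits


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_convolve(values, weights, radius, circular=True):
    """Direct-sum convolution: profile[x] = sum_i w[i] * v[(x-i) mod L]."""
    L = len(values)
    out = np.zeros(L)
    for x in range(L):
        acc = 0.0
        for i in range(-radius, radius + 1):
            j = x - i
            if circular:
                acc += weights[i + radius] * values[j % L]
            elif 0 <= j < L:
                acc += weights[i + radius] * values[j]
        out[x] = acc
    return out


def brute_force_expected_width(values, circular=True, fold=3.0):
    """Re-derive the median FWHM directly from the stated procedure."""
    v = np.asarray(values, float)
    L = len(v)
    mu = v.mean()
    above = v > fold * mu
    if not above.any():
        return None
    # maximal runs (wrap-merged)
    runs, cur = [], []
    for x in range(L):
        if above[x]:
            cur.append(x)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    if circular and len(runs) > 1 and runs[0][0] == 0 and \
            runs[-1][-1] == L - 1:
        runs[0] = [x - L for x in runs[-1]] + runs[0]
        runs.pop()
    widths = []
    for run in runs:
        apex = max(run, key=lambda x: (v[x % L], -x))
        half = v[apex % L] / 2
        left = apex
        while v[(left - 1) % L] >= half and apex - left < L - 1:
            left -= 1
        right = apex
        while v[(right + 1) % L] >= half and right - apex < L - 1:
            right += 1
        widths.append(right - left)
    widths.sort()
    return widths[(len(widths) - 1) // 2]


# ---------------------------------------------------------------------------
# width estimation
# ---------------------------------------------------------------------------

class TestExpectedWidth:
    def test_triangular_peak_fwhm_is_100(self):
        v = np.zeros(5000)
        apex = 2500
        for d in range(101):
            v[apex - d] = v[apex + d] = 100 - d
        t = ck.CoverageTrack("chr", v)
        assert ck.estimate_expected_width(t) == 100

    def test_median_of_two_bumps_is_lower_middle(self):
        t = gaussian_bump_track(10_000, [2000, 7000], [100, 100], [50, 90])
        w = ck.estimate_expected_width(t)
        assert abs(w - 50) <= 2

    def test_detection_threshold_is_three_mean_coverage(self):
        def track_with_apex_fold(fold):
            v = np.ones(1000)
            for _ in range(100):  # fixed point: apex == fold * mean
                v[500] = fold * v.mean()
            return ck.CoverageTrack("chr", v)

        # apex at 2.9x the track mean -> nothing detectable
        with pytest.raises(ck.NoPeaksError):
            ck.estimate_expected_width(track_with_apex_fold(2.9))
        # apex at 3.1x the mean -> one provisional peak
        assert ck.estimate_expected_width(track_with_apex_fold(3.1)) >= 0

    def test_no_peaks_error_carries_mean(self, flat_track):
        with pytest.raises(ck.NoPeaksError) as e:
            ck.estimate_expected_width(flat_track)
        assert e.value.mean_coverage == pytest.approx(10.0)

    def test_matches_brute_force_oracle_on_random_tracks(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            L = 4000
            n = rng.integers(2, 6)
            summits = np.sort(rng.choice(np.arange(200, L - 200, 400),
                                         size=n, replace=False))
            heights = rng.uniform(50, 300, size=n)
            widths = rng.uniform(30, 120, size=n)
            t = gaussian_bump_track(L, summits, heights, widths,
                                    background=rng.uniform(0, 5))
            assert ck.estimate_expected_width(t) == \
                brute_force_expected_width(t.values)

    def test_wrap_run_is_single_run(self):
        v = np.zeros(100)
        v[95:] = 10
        v[:5] = 10
        runs = _above_runs(v > 1, circular=True)
        assert len(runs) == 1 and len(runs[0]) == 10


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

class TestKernel:
    @pytest.mark.parametrize("width", [8, 25, 80, 137])
    def test_symmetric_zero_sum_positive_center(self, width):
        k = ck.build_kernel(width)
        assert np.allclose(k.weights, k.weights[::-1])
        assert abs(k.weights.sum()) < 1e-12
        assert k.weights[k.radius] > 0
        assert k.radius == int(np.ceil(4 * width / 8))

    def test_width_below_8_rejected(self):
        with pytest.raises(ValueError):
            ck.build_kernel(7)

    def test_matched_bump_response_peaks_at_center(self):
        t = gaussian_bump_track(4000, [2000], [100], [80])
        k = ck.build_kernel(80)
        profile = ck.convolve(t, k)
        assert abs(int(np.argmax(profile)) - 2000) <= 1


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

class TestConvolve:
    def test_zero_track_zero_profile(self):
        t = ck.CoverageTrack("chr", np.zeros(1000))
        k = ck.build_kernel(40)
        assert (ck.convolve(t, k) == 0).all()

    def test_constant_track_zero_profile(self, flat_track):
        k = ck.build_kernel(40)
        assert np.abs(ck.convolve(flat_track, k)).max() < 1e-9

    def test_impulse_response_is_kernel(self):
        v = np.zeros(500)
        v[250] = 1.0
        k = ck.build_kernel(40)
        profile = ck.convolve(ck.CoverageTrack("chr", v), k)
        r = k.radius
        assert np.allclose(profile[250 - r:250 + r + 1], k.weights)

    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_naive_sum(self, circular):
        rng = np.random.default_rng(23)
        v = rng.poisson(10, size=1500).astype(float)
        t = ck.CoverageTrack("chr", v, circular=circular)
        k = ck.build_kernel(64)
        fast = ck.convolve(t, k)
        slow = naive_convolve(v, k.weights, k.radius, circular)
        scale = np.abs(slow).max()
        assert np.abs(fast - slow).max() <= 1e-9 * scale

    def test_linearity(self):
        rng = np.random.default_rng(24)
        a = rng.poisson(10, 800).astype(float)
        b = rng.poisson(10, 800).astype(float)
        k = ck.build_kernel(40)
        lhs = ck.convolve(ck.CoverageTrack("chr", 2 * a + 3 * b), k)
        rhs = 2 * ck.convolve(ck.CoverageTrack("chr", a), k) \
            + 3 * ck.convolve(ck.CoverageTrack("chr", b), k)
        assert np.allclose(lhs, rhs)

    def test_kernel_radius_must_fit(self):
        t = ck.CoverageTrack("chr", np.ones(50))
        with pytest.raises(ValueError, match="radius"):
            ck.convolve(t, ck.build_kernel(100))


# ---------------------------------------------------------------------------
# summit detection
# ---------------------------------------------------------------------------

class TestDetectSummits:
    def test_single_bump_gives_argmax(self):
        t = gaussian_bump_track(2000, [700], [100], [60])
        k = ck.build_kernel(60)
        profile = ck.convolve(t, k)
        cands = ck.detect_summits(profile)
        assert cands == [int(np.argmax(profile))]

    def test_constant_profile_no_candidates(self):
        assert ck.detect_summits(np.full(500, 3.0)) == []

    def test_two_bumps_two_candidates_near_truth(self):
        t = gaussian_bump_track(4000, [1000, 3000], [100, 120], [60, 60])
        profile = ck.convolve(t, ck.build_kernel(60))
        cands = ck.detect_summits(profile)
        assert len(cands) == 2
        for c, s in zip(sorted(cands), [1000, 3000]):
            assert abs(c - s) <= 60 / 4

    def test_plateau_reports_center_rounded_down(self):
        p = np.zeros(100)
        p[40:45] = 5.0  # plateau positions 40..44
        cands = ck.detect_summits(p, circular=False)
        assert cands == [42]
        p2 = np.zeros(100)
        p2[40:44] = 5.0  # even plateau 40..43 -> floor(41.5) = 41
        assert ck.detect_summits(p2, circular=False) == [41]

    def test_nonpositive_candidates_dropped(self):
        p = -np.abs(np.arange(-50, 50, dtype=float)) - 1  # max is -1
        assert ck.detect_summits(p, circular=False) == []

    def test_circular_summit_at_origin(self):
        t = gaussian_bump_track(2000, [0], [100], [60])
        profile = ck.convolve(t, ck.build_kernel(60))
        cands = ck.detect_summits(profile)
        assert len(cands) == 1
        assert ck.circular_distance(cands[0], 0, 2000) <= 2


# ---------------------------------------------------------------------------
# filtering + normalization
# ---------------------------------------------------------------------------

class TestScoreFilter:
    def test_height_threshold(self):
        v = np.ones(2000)
        t = ck.CoverageTrack("chr", v)
        mu = t.mean
        profile = np.ones(2000)
        keep = ck.score_filter([100, 200], profile, t, 40, min_fold=3)
        assert len(keep) == 0  # raw height 1 = mu < 3mu
        v2 = np.ones(2000)
        v2[100] = 2.9
        v2[200] = 3.2  # mean is ~1.0016, so 3.2 > 3*mu, 2.9 < 3*mu
        t2 = ck.CoverageTrack("chr", v2)
        keep2 = ck.score_filter([100, 200], profile, t2, 40, min_fold=3)
        assert [p.summit for p in keep2.peaks] == [200]

    def test_empty_candidates_valid(self, flat_track):
        ps = ck.score_filter([], np.zeros(2000), flat_track, 40)
        assert len(ps) == 0 and ps.expected_width == 40

    def test_overlapping_extents_keep_higher_score(self, flat_track):
        profile = np.zeros(2000)
        profile[1000] = 5.0
        profile[1010] = 9.0
        v = np.full(2000, 1.0)
        v[1000] = v[1010] = 50.0
        t = ck.CoverageTrack("chr", v)
        ps = ck.score_filter([1000, 1010], profile, t, 40, min_fold=3)
        assert [p.summit for p in ps.peaks] == [1010]

    def test_extent_is_centered_width_window(self, flat_track):
        profile = np.zeros(2000)
        profile[500] = 1.0
        v = np.full(2000, 1.0)
        v[500] = 100.0
        ps = ck.score_filter([500], profile, ck.CoverageTrack("chr", v),
                             80, min_fold=3)
        p = ps.peaks[0]
        assert (p.start, p.end) == (460, 540)


class TestNormalize:
    def test_worked_example(self):
        v = np.zeros(1000)
        v[0:100] = 100.0   # background mass 10000
        v[100:200] = 50.0  # peak extent mass 5000
        t = ck.CoverageTrack("chr", v)
        ps = ck.PeakSet(
            peaks=[ck.Peak(summit=150, start=100, end=200,
                           raw_height=50.0, score=2.5)],
            expected_width=100, mean_coverage=t.mean, genome_length=1000)
        out = ck.normalize_peakset(ps, t)
        assert out.norm_coefficient == pytest.approx(10_000.0)
        assert out.peaks[0].norm_intensity == pytest.approx(250.0)

    @pytest.mark.parametrize("c", [0.1, 10.0, 137.0])
    def test_scale_invariance(self, c):
        t = gaussian_bump_track(5000, [1000, 3500], [120, 200], [60, 80],
                                background=10)
        ps = ck.call_peaks(t)
        t2 = ck.CoverageTrack("chr", t.values * c)
        ps2 = ck.call_peaks(t2)
        a = np.array([p.norm_intensity for p in ps.peaks])
        b = np.array([p.norm_intensity for p in ps2.peaks])
        assert len(a) == len(b)
        assert np.abs(a - b).max() <= 1e-6 * np.abs(a).max()

    def test_empty_peakset_b_is_total(self, flat_track):
        ps = ck.PeakSet(peaks=[], expected_width=40,
                        mean_coverage=flat_track.mean, genome_length=2000)
        out = ck.normalize_peakset(ps, flat_track)
        assert out.norm_coefficient == flat_track.values.sum()

    def test_nonpositive_b_errors(self):
        v = np.zeros(1000)
        v[100:200] = 10.0
        t = ck.CoverageTrack("chr", v)
        ps = ck.PeakSet(
            peaks=[ck.Peak(150, 100, 200, 10.0, 1.0)],
            expected_width=100, mean_coverage=t.mean, genome_length=1000)
        with pytest.raises(ck.NormalizationError):
            ck.normalize_peakset(ps, t)


# ---------------------------------------------------------------------------
# full caller
# ---------------------------------------------------------------------------

class TestCallPeaks:
    def test_noise_free_planted_peaks_recovered_exactly(self):
        summits = [1000, 3000, 5000, 7000, 9000]
        t = gaussian_bump_track(10_000, summits,
                                [100, 150, 200, 120, 180],
                                [60, 60, 80, 70, 90], background=10)
        ps = ck.call_peaks(t)
        assert len(ps) == 5
        for got, want in zip(sorted(ps.summits()), summits):
            assert abs(got - want) <= 2

    def test_blacklist_excludes_summit(self):
        summits = [1000, 3000, 5000, 7000, 9000]
        t = gaussian_bump_track(10_000, summits,
                                [100, 150, 200, 120, 180],
                                [60, 60, 80, 70, 90], background=10)
        ps = ck.call_peaks(t, blacklist=[(2900, 3100)])
        assert len(ps) == 4
        assert all(not (2900 <= s < 3100) for s in ps.summits())

    def test_all_background_raises_no_peaks(self, flat_track):
        with pytest.raises(ck.NoPeaksError):
            ck.call_peaks(flat_track)

    def test_shift_covariance(self):
        t = gaussian_bump_track(8000, [2000, 5000], [150, 200], [60, 80],
                                background=10)
        ps = ck.call_peaks(t)
        k = 1234
        t2 = ck.CoverageTrack("chr", np.roll(t.values, k))
        ps2 = ck.call_peaks(t2)
        assert sorted((s + k) % 8000 for s in ps.summits()) == \
            sorted(ps2.summits().tolist())

    def test_score_monotone_in_planted_height(self):
        base_heights = [100.0, 150.0]
        scores = []
        for h in (150.0, 200.0, 300.0):
            t = gaussian_bump_track(8000, [2000, 5000],
                                    [base_heights[0], h], [60, 80],
                                    background=10)
            ps = ck.call_peaks(t)
            target = min(ps.peaks,
                         key=lambda p: abs(p.summit - 5000))
            scores.append(target.score)
        assert scores[0] < scores[1] < scores[2]

    def test_poisson_recovery_with_truth(self, small_truth):
        recalls, precisions = [], []
        for rep in (1, 2, 3):
            track = ck.simulate_coverage(small_truth, "iron", rep,
                                         "poisson", seed=5)
            ps = ck.call_peaks(track)
            planted = [p.summit for p in small_truth.peaks_in("iron")]
            rec, prec, _ = match_summits(
                ps.summits().tolist(), planted, len(small_truth.genome),
                ps.expected_width / 2)
            recalls.append(rec)
            precisions.append(prec)
        assert min(recalls) >= 0.9 and min(precisions) >= 0.9


def test_peak_table_roundtrip(tmp_path):
    t = gaussian_bump_track(5000, [1000, 3500], [120, 200], [60, 80],
                            background=10)
    t.sample, t.condition, t.replicate = "s1", "iron", 2
    ps = ck.call_peaks(t)
    path = tmp_path / "peaks.bed"
    ck.write_peaks(ps, path)
    back = ck.read_peaks(path)
    assert back.summits().tolist() == ps.summits().tolist()
    assert back.norm_coefficient == pytest.approx(ps.norm_coefficient)
    assert back.sample == "s1" and back.condition == "iron"
    assert back.replicate == 2 and back.genome_length == 5000
    for a, b in zip(back.peaks, ps.peaks):
        assert a.norm_intensity == pytest.approx(b.norm_intensity,
                                                 rel=1e-4)
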