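"""Scenario statistics vs brute-force textbook oracles."""

import numpy as np
import pytest

import speckleperf as sp
from speckleperf.analysis import AnalysisError, GradientProfile, _two_piece_fit


def profile(d, y, **kw):
    return GradientProfile(distances_cm=np.asarray(d, float), rpu=np.asarray(y, float), **kw)


class TestSegmentSummary:
    def test_f_statistic_matches_textbook_formula(self):
        """One-way ANOVA F on a 9-point toy vs the between/within
        variance-ratio formula computed by hand."""
        groups = {"ischemic": [1.0, 2.0, 3.0], "watershed": [4.0, 6.0, 8.0], "perfused": [7.0, 9.0, 11.0]}
        d = [0.5, 1.0, 1.5, 4.5, 5.0, 5.5, 8.5, 9.0, 9.5]
        y = groups["ischemic"] + groups["watershed"] + groups["perfused"]
        summ = sp.segment_summary(profile(d, y))

        vals = [np.asarray(v) for v in groups.values()]
        grand = np.concatenate(vals).mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
        f_expect = (ss_between / 2) / (ss_within / 6)
        assert summ.anova.statistic == pytest.approx(f_expect, rel=1e-12)
        assert summ.per_segment["watershed"][0] == pytest.approx(6.0)

    def test_identical_groups_give_f_zero_p_one(self):
        d = [0.5, 1.0, 1.5, 4.5, 5.0, 5.5, 8.5, 9.0, 9.5]
        summ = sp.segment_summary(profile(d, [5.0] * 9))
        assert summ.anova.statistic == 0.0
        assert summ.anova.p_value == 1.0

    def test_empty_segment_named_in_error(self):
        with pytest.raises(AnalysisError, match="watershed"):
            sp.segment_summary(profile([0.5, 1.0, 8.5, 9.0], [1, 2, 9, 9]))

    def test_p_decreases_with_segment_separation(self):
        """Larger configured separation -> smaller ANOVA p (3-level sweep)."""
        rng = np.random.default_rng(0)
        d = np.concatenate([np.linspace(0, 2, 5), np.linspace(4, 6, 5), np.linspace(8, 10, 5)])
        ps = []
        for sep in (1.0, 4.0, 16.0):
            y = np.concatenate([np.zeros(5), np.full(5, sep), np.full(5, 2 * sep)])
            y = y + rng.normal(0, 1.0, size=15)
            ps.append(sp.segment_summary(profile(d, y)).anova.p_value)
        assert ps[0] > ps[1] > ps[2]


class TestPairedComparisons:
    def test_t_statistic_matches_hand_formula(self):
        """Paired t on a printed 4-pair toy: t = dbar / (sd/sqrt(n))."""
        a = np.array([10.0, 12.0, 9.0, 14.0])
        b = np.array([8.0, 9.0, 8.5, 10.0])
        res = sp.compare_anastomoses(a, b)
        diff = a - b
        t_expect = diff.mean() / (diff.std(ddof=1) / np.sqrt(4))
        assert res.statistic == pytest.approx(t_expect, rel=1e-12)
        assert res.paired and res.n == 4

    def test_identical_point_sets_zero_difference(self):
        a = [3.0, 4.0, 5.0, 6.0]
        res = sp.compare_anastomoses(a, a)
        assert res.group_means[0] == res.group_means[1]
        assert res.p_value == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(AnalysisError, match="length"):
            sp.compare_anastomoses([1, 2, 3], [1, 2, 3, 4])

    def test_compare_arcs_restricted_to_perfused_watershed(self):
        d = np.arange(0.0, 10.5, 0.5)
        mes = profile(d, np.linspace(0, 100, len(d)))
        anti = profile(d, np.linspace(0, 100, len(d)) - 5.0)
        res = sp.compare_arcs(mes, anti)
        # matched points: 5 in [4,6] plus 5 in [8,10]
        assert res.n == 10
        assert res.group_means[0] - res.group_means[1] == pytest.approx(5.0)

    def test_compare_arcs_needs_matched_points(self):
        mes = profile([0.0, 1.0, 2.0], [1, 2, 3])
        anti = profile([0.0, 1.0, 2.0], [1, 2, 3])
        with pytest.raises(AnalysisError, match="matched"):
            sp.compare_arcs(mes, anti)  # no samples in watershed/perfused


class TestDeclineOnset:
    def test_exact_recovery_on_noiseless_two_piece(self):
        """Break at 4.0 with slopes 20 and 4: exhaustive search recovers it."""
        d = np.arange(2.0, 8.1, 0.5)
        y = np.where(d < 4.0, 20.0 * (d - 4.0) + 60.0, 4.0 * (d - 4.0) + 60.0)
        assert sp.detect_decline_onset(profile(d, y)) == 4.0

    def test_perfectly_linear_profile_has_no_onset(self):
        d = np.arange(2.0, 8.1, 0.5)
        assert sp.detect_decline_onset(profile(d, 10.0 * d)) is None

    def test_two_piece_fit_is_least_squares(self):
        """SSE at the true break is zero for exact two-piece data."""
        d = np.arange(2.0, 8.1, 0.5)
        y = np.where(d < 5.0, 30.0 * (d - 5.0) + 80.0, 2.0 * (d - 5.0) + 80.0)
        sse, sl, sr = _two_piece_fit(d, y, 5.0)
        assert sse == pytest.approx(0.0, abs=1e-18)
        assert sl == pytest.approx(30.0) and sr == pytest.approx(2.0)

    def test_insufficient_span_rejected(self):
        with pytest.raises(AnalysisError, match="spanning"):
            sp.detect_decline_onset(profile([3.0, 4.0, 5.0, 6.0], [1, 2, 3, 4]))


class TestMapRegression:
    def test_collinear_points_r2_one_slope_exact(self):
        s = sp.OcclusionSeries("arterial", "perfused", [60.0, 50.0, 40.0, 30.0], [90.0, 70.0, 50.0, 30.0])
        res = sp.map_rpu_regression(s)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_r2_matches_correlation_squared_on_toy(self):
        """5-point toy: R^2 equals the hand-computed squared Pearson r."""
        x = np.array([65.0, 55.0, 45.0, 35.0, 25.0])
        y = np.array([95.0, 80.0, 72.0, 40.0, 30.0])
        res = sp.map_rpu_regression(sp.OcclusionSeries("venous", "perfused", x, y))
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r2_expect = sxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert res.r_squared == pytest.approx(r2_expect, rel=1e-12)

    def test_zero_map_variance_rejected(self):
        with pytest.raises(AnalysisError):
            sp.map_rpu_regression(
                sp.OcclusionSeries("arterial", "perfused", [50.0, 50.0 - 1e-13, 50.0 - 2e-13], [1, 2, 3])
            )


class TestEndToEndRecovery:
    def test_two_level_scene_recovers_mid_level(self, default_optics):
        """References on ground truth 0 and 100; an ROI at level g reads
        back g within 2 RPU points through the full imaging chain."""
        g = 40.0
        scene = sp.build_flat_scene([0.0, g, 100.0], patch_px=61, gap_px=10)
        video = sp.render_video(scene, default_optics, n_frames=16, seed=17)
        maps = sp.video_to_flow_maps(video.frames)
        refs = (scene.landmarks["hot_reference"], scene.landmarks["cold_reference"])
        m = sp.rpu_over_frames(maps, refs, scene.landmarks["patch_1"], n=5)
        assert m.mean_rpu == pytest.approx(g, abs=2.0)

    def test_arc_profile_distances_strictly_increasing(self, gradient_runs):
        for res in gradient_runs[:1]:
            for prof in res.profiles.values():
                assert np.all(np.diff(prof.distances_cm) > 0)

    def test_venous_slope_steeper_than_arterial(self, occlusion_runs):
        art = occlusion_runs["arterial"].regressions["perfused"].slope
        ven = occlusion_runs["venous"].regressions["perfused"].slope
        assert abs(ven) > abs(art)

    def test_segment_recovery_within_tolerance_across_seeds(self, gradient_runs):
        """Pooled over 5 seeds, recovered segment means sit within 3/3/2
        points of the configured 98.8/78.3/1.9 ground truth."""
        pooled = {}
        for seg in ("perfused", "watershed", "ischemic"):
            vals = np.concatenate(
                [r.profiles["centerline"].segment_values(seg) for r in gradient_runs]
            )
            pooled[seg] = vals.mean()
        assert pooled["perfused"] == pytest.approx(98.8, abs=3.0)
        assert pooled["watershed"] == pytest.approx(78.3, abs=3.0)
        assert pooled["ischemic"] == pytest.approx(1.9, abs=2.0)
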