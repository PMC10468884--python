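"""RPU quantification: region extraction, the ratio, frame averaging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import speckleperf as sp
from speckleperf.rpu import (
    DegenerateReferenceError,
    RegionError,
    disk_offsets,
    select_frames,
)


def make_map(values) -> sp.FlowIndexMap:
    return sp.FlowIndexMap(values=np.asarray(values, dtype=float))


def brute_force_disk(area_px: int) -> set[tuple[int, int]]:
    """Nearest-pixel selection oracle with the angle/row-major tie rule."""
    cands = []
    for dr in range(-25, 26):
        for dc in range(-25, 26):
            d2 = dr * dr + dc * dc
            ang = np.mod(np.arctan2(dr, dc), 2 * np.pi)
            cands.append((d2, ang, dr, dc))
    cands.sort()
    return {(dr, dc) for _, _, dr, dc in cands[:area_px]}


class TestExtractRegion:
    def test_default_area_is_317_pixels(self):
        m = make_map(np.ones((60, 60)))
        region = sp.extract_region(m, (30, 30))
        assert region.area == 317

    def test_uniform_map_mean(self):
        m = make_map(np.full((50, 50), 3.25))
        assert sp.extract_region(m, (25, 25)).mean_raw == 3.25

    def test_small_area_matches_brute_force_oracle(self):
        m = make_map(np.arange(25.0).reshape(5, 5))
        region = sp.extract_region(m, (2, 2), area_px=5)
        oracle = brute_force_disk(5)
        chosen = {(r - 2, c - 2) for r, c in region.pixels}
        assert chosen == oracle
        expect = np.mean([m.values[2 + dr, 2 + dc] for dr, dc in oracle])
        assert region.mean_raw == pytest.approx(expect)

    @pytest.mark.parametrize("area", [21, 317])
    def test_offsets_match_brute_force(self, area):
        got = {tuple(p) for p in disk_offsets(area)}
        assert got == brute_force_disk(area)

    def test_border_clipping_rejected_with_center_named(self):
        m = make_map(np.ones((40, 40)))
        with pytest.raises(RegionError, match=r"\(5\.0, 20\.0\)"):
            sp.extract_region(m, (5, 20))


class TestComputeRpu:
    @pytest.fixture()
    def refs(self):
        return sp.ReferencePair.from_values(hot_raw=50.0, cold_raw=2.0)

    def test_hot_endpoint_is_100(self, refs):
        assert sp.compute_rpu(50.0, refs) == 100.0

    def test_cold_endpoint_is_0(self, refs):
        assert sp.compute_rpu(2.0, refs) == 0.0

    def test_midpoint_is_50(self, refs):
        assert sp.compute_rpu(26.0, refs) == 50.0

    def test_values_beyond_references_not_clipped(self, refs):
        assert sp.compute_rpu(55.0, refs) > 100.0
        assert sp.compute_rpu(1.0, refs) < 0.0

    def test_swapped_references_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            sp.ReferencePair.from_values(hot_raw=2.0, cold_raw=50.0)

    @given(
        roi=st.floats(0.0, 100.0),
        cold=st.floats(0.5, 10.0),
        sep=st.floats(1.0, 100.0),
        a=st.floats(-50.0, 50.0),
        b=st.floats(0.01, 100.0),
    )
    def test_affine_invariance(self, roi, cold, sep, a, b):
        """RPU is unchanged when all raws are rescaled x -> a + b x."""
        refs = sp.ReferencePair.from_values(cold + sep, cold)
        refs2 = sp.ReferencePair.from_values(a + b * (cold + sep), a + b * cold)
        r1 = sp.compute_rpu(roi, refs)
        r2 = sp.compute_rpu(a + b * roi, refs2)
        assert r2 == pytest.approx(r1, abs=1e-6)


class TestFrameAveraging:
    def _maps(self, levels):
        return [sp.FlowIndexMap(values=np.full((40, 40), v)) for v in levels]

    def test_constant_sequence_equals_single_frame(self):
        maps = self._maps([10.0] * 8)
        refs = sp.ReferencePair.from_values(20.0, 0.0)
        m = sp.rpu_over_frames(maps, refs, (20, 20), n=5, area_px=21)
        assert m.mean_rpu == sp.compute_rpu(10.0, refs) == 50.0

    def test_single_frame_degenerate_averaging(self):
        maps = self._maps([12.0, 14.0, 16.0])
        refs = sp.ReferencePair.from_values(20.0, 0.0)
        m = sp.rpu_over_frames(maps, refs, (20, 20), n=1, selector=[1], area_px=21)
        assert m.mean_rpu == sp.compute_rpu(14.0, refs)

    def test_identity_selector_arithmetic_mean(self):
        # per-frame raw 8,10,12,10,10 with refs (20, 0) -> RPUs 40,50,60,50,50
        maps = self._maps([8.0, 10.0, 12.0, 10.0, 10.0])
        refs = sp.ReferencePair.from_values(20.0, 0.0)
        m = sp.rpu_over_frames(maps, refs, (20, 20), n=5, selector=range(5), area_px=21)
        np.testing.assert_allclose(m.rpu_per_frame, [40, 50, 60, 50, 50])
        assert m.mean_rpu == 50.0

    def test_references_resampled_per_frame(self):
        """With coordinate refs, each frame is normalized by its own
        reference samples, so a global per-frame gain cancels."""
        base = np.zeros((60, 120))
        base[:, :60] = 30.0  # hot half
        base[:, 60:] = 2.0  # cold half
        maps = [sp.FlowIndexMap(values=base * g) for g in (1.0, 2.0, 0.5, 1.5, 1.0)]
        m = sp.rpu_over_frames(
            maps, ((30, 30), (30, 90)), (30, 30), n=5, selector=range(5)
        )
        np.testing.assert_allclose(m.rpu_per_frame, 100.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(RegionError, match="at least 5"):
            sp.rpu_over_frames(self._maps([1.0] * 3), sp.ReferencePair.from_values(2, 1), (20, 20), n=5)

    def test_cardiac_selector_spans_window(self):
        idx = select_frames(120, n=5, cardiac_window_s=0.5, frame_rate=120.0)
        assert idx[0] == 0 and idx[-1] == 59 and len(idx) == 5


class TestValidateReferences:
    def test_extreme_references_pass(self, rng):
        vals = rng.uniform(1.0, 50.0, size=(50, 50))
        refs = sp.ReferencePair.from_values(vals.max() + 1, vals.min() - 0.5)
        report = sp.validate_references(refs, make_map(vals))
        assert report.ok

    def test_weak_separation_warns(self, rng):
        vals = rng.uniform(1.0, 50.0, size=(50, 50))
        refs = sp.ReferencePair.from_values(26.0, 25.0)
        with pytest.warns(UserWarning, match="separation"):
            report = sp.validate_references(refs, make_map(vals))
        assert not report.ok
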