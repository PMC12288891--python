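"""Background estimation, thresholding segmentation and patch extraction."""

import numpy as np
import pytest

from dhmpheno.preprocess import (PhaseFrame, estimate_background,
                                 extract_cells, filter_and_extract, segment,
                                 subtract_background)


def _dome_frame(shape, center, radius=10.0, peak=2.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    q = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / radius**2
    return peak * np.clip(1.0 - q, 0.0, None)


def _corrected(pixels, frame_id=0):
    return PhaseFrame(np.asarray(pixels, dtype=np.float32),
                      frame_id=frame_id, corrected=True)


class TestBackground:
    def test_constant_frames_give_constant_background(self):
        frames = np.full((50, 8, 9), 0.3)
        np.testing.assert_array_equal(estimate_background(frames),
                                      np.full((8, 9), 0.3))

    def test_outlier_pixel_suppressed_by_median(self):
        frames = np.zeros((50, 6, 6))
        frames[7, 2, 3] = 10.0
        bg = estimate_background(frames)
        # brute-force per-pixel median oracle
        for r in range(6):
            for c in range(6):
                vals = sorted(frames[i, r, c] for i in range(50))
                expected = 0.5 * (vals[24] + vals[25])
                assert bg[r, c] == expected

    def test_single_frame_is_identity(self):
        frame = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(estimate_background([frame], n=1), frame)

    def test_fewer_frames_than_requested_warns(self):
        frames = np.zeros((5, 4, 4))
        with pytest.warns(UserWarning, match="5 frames"):
            estimate_background(frames, n=50)


class TestSubtraction:
    def test_frame_equal_to_background_gives_zero(self):
        f = np.random.default_rng(0).normal(size=(6, 7))
        out = subtract_background(PhaseFrame(f), f)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-7)
        assert out.corrected

    def test_equals_elementwise_oracle(self, rng):
        f = rng.normal(size=(5, 6))
        bg = rng.normal(size=(5, 6))
        out = subtract_background(PhaseFrame(f), bg)
        for r in range(5):
            for c in range(6):
                assert out.pixels[r, c] == pytest.approx(f[r, c] - bg[r, c],
                                                         abs=1e-6)

    def test_zero_background_is_identity(self, rng):
        f = rng.normal(size=(5, 6)).astype(np.float32)
        out = subtract_background(PhaseFrame(f), np.zeros((5, 6)))
        np.testing.assert_array_equal(out.pixels, f)

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(4, 4\).*\(5, 5\)"):
            subtract_background(PhaseFrame(np.zeros((4, 4))), np.zeros((5, 5)))


def _flood_fill_components(binary):
    """Independent 8-connected component oracle (BFS on the mask)."""
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    h, w = binary.shape
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and binary[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


class TestSegment:
    def test_empty_frame_yields_no_contours(self):
        assert segment(_corrected(np.zeros((50, 50)))) == []

    def test_requires_corrected_frame(self):
        with pytest.raises(ValueError, match="corrected"):
            segment(PhaseFrame(np.zeros((10, 10))))

    def test_single_dome_region_matches_flood_fill_oracle(self):
        f = _dome_frame((60, 60), (30, 30), radius=12, peak=2.0)
        conts = segment(_corrected(f), threshold=0.8)
        assert len(conts) == 1
        oracle = _flood_fill_components(f > 0.8)
        assert len(oracle) == 1
        got = set()
        r0, c0 = conts[0].bbox
        for r, c in zip(*np.nonzero(conts[0].mask)):
            got.add((r + r0, c + c0))
        assert got == oracle[0]
        assert conts[0].area_px == len(oracle[0])

    def test_two_separated_domes_give_two_contours(self):
        f = (_dome_frame((80, 120), (40, 30)) + _dome_frame((80, 120), (40, 90)))
        assert len(segment(_corrected(f))) == 2

    def test_scan_order_is_deterministic(self):
        f = (_dome_frame((120, 80), (30, 40)) + _dome_frame((120, 80), (90, 40)))
        conts = segment(_corrected(f))
        assert conts[0].centroid[0] < conts[1].centroid[0]

    @pytest.mark.parametrize("thresholds", [(0.2, 0.8, 1.2, 1.9, 2.5)])
    def test_raising_threshold_never_adds_contours(self, thresholds, rng):
        f = sum(_dome_frame((100, 150), (rng.uniform(20, 80), rng.uniform(20, 130)),
                            radius=rng.uniform(5, 12), peak=rng.uniform(1, 3))
                for _ in range(6))
        counts = [len(segment(_corrected(f), threshold=t)) for t in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFilterAndExtract:
    def _blob_frame(self, n_pixels, shape=(200, 200)):
        """A rectangular blob of exactly n_pixels above threshold."""
        f = np.zeros(shape)
        rows = n_pixels // 5
        rem = n_pixels - rows * 5
        f[100:100 + rows, 100:105] = 2.0
        if rem:
            f[100 + rows, 100:100 + rem] = 2.0
        return _corrected(f)

    @pytest.mark.parametrize("area,kept", [(30, 0), (31, 1)])
    def test_strict_30px_area_boundary(self, area, kept):
        frame = self._blob_frame(area)
        conts = segment(frame)
        assert conts[0].area_px == area
        patches, _ = filter_and_extract(frame, conts)
        assert len(patches) == kept

    def test_centered_dome_patch_equals_frame(self):
        f = _dome_frame((96, 96), (48, 48), radius=10, peak=2.0)
        frame = _corrected(f)
        patches, rejected = filter_and_extract(frame, segment(frame))
        assert rejected == 0
        assert len(patches) == 1
        np.testing.assert_array_equal(patches[0].patch, frame.pixels)
        assert patches[0].patch.shape == (96, 96)

    def test_near_border_cell_is_dropped_and_counted(self):
        f = _dome_frame((200, 200), (10, 100), radius=8, peak=2.0)
        frame = _corrected(f)
        patches, rejected = filter_and_extract(frame, segment(frame))
        assert patches == []
        assert rejected == 1

    def test_mask_aligned_with_patch(self):
        f = _dome_frame((200, 200), (100, 100), radius=10, peak=2.0)
        frame = _corrected(f)
        patches, _ = filter_and_extract(frame, segment(frame))
        (p,) = patches
        # every masked pixel is above threshold, every unmasked below
        assert (p.patch[p.mask] > 0.8).all()
        assert (p.patch[~p.mask] <= 0.8).all()


def test_full_extraction_is_deterministic():
    from dhmpheno.phantoms import render_spike_in

    frames, _, _ = render_spike_in(0.5, 30, seed=8, cells_per_frame=10)
    with pytest.warns(UserWarning):
        a = extract_cells(frames)
    with pytest.warns(UserWarning):
        b = extract_cells(frames)
    assert a.survivors == b.survivors == len(a.patches)
    for pa, pb in zip(a.patches, b.patches):
        assert pa.patch.tobytes() == pb.patch.tobytes()
        assert pa.cell_id == pb.cell_id
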