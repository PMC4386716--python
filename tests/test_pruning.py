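import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import camoband as cb


class TestRegionEntropy:
    @pytest.mark.parametrize(
        "sizes,total,expected",
        [([32, 32], 64, 1.0), ([64], 64, 0.0), ([16, 16, 16, 16], 64, 2.0)],
    )
    def test_analytic_cases(self, sizes, total, expected):
        assert cb.region_entropy(sizes, total) == pytest.approx(expected)

    def test_sizes_must_sum_to_total(self):
        with pytest.raises(ValueError):
            cb.region_entropy([10, 10], 64)

    def test_empty_sizes_rejected(self):
        with pytest.raises(ValueError):
            cb.region_entropy([], 0)

    @settings(derandomize=True, max_examples=60)
    @given(sizes=st.lists(st.integers(1, 500), min_size=1, max_size=25))
    def test_bounded_by_log2_m(self, sizes):
        total = sum(sizes)
        h = cb.region_entropy(sizes, total)
        m = len(sizes)
        assert 0.0 <= h <= np.log2(m) + 1e-9
        if len(set(sizes)) == 1:
            assert h == pytest.approx(np.log2(m))

    @settings(derandomize=True, max_examples=60)
    @given(
        sizes=st.lists(st.integers(2, 500), min_size=1, max_size=20),
        which=st.integers(0, 10**6),
        cut=st.integers(0, 10**6),
    )
    def test_splitting_a_region_strictly_increases_entropy(self, sizes, which, cut):
        total = sum(sizes)
        h0 = cb.region_entropy(sizes, total)
        i = which % len(sizes)
        part = 1 + cut % (sizes[i] - 1)
        split = sizes[:i] + [part, sizes[i] - part] + sizes[i + 1 :]
        assert cb.region_entropy(split, total) > h0

    def test_two_region_split_never_exceeds_one_bit(self):
        # the method's ideal outcome: object + background, any size ratio
        for a in (1, 10, 100, 2047, 2048):
            assert cb.region_entropy([a, 4096 - a], 4096) <= 1.0 + 1e-12


class TestSegmentBand:
    def test_left_right_halves(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 10.0
        seg = cb.segment_band(img)
        assert seg.region_count == 2
        assert sorted(seg.region_sizes.tolist()) == [32, 32]
        assert seg.entropy == pytest.approx(1.0)

    def test_constant_image_single_region(self):
        seg = cb.segment_band(np.full((8, 8), 3.0))
        assert seg.region_count == 1
        assert seg.entropy == 0.0

    def test_checkerboard_connectivity_convention(self):
        # 8-connectivity joins diagonal same-class squares: 2 regions, 1 bit.
        yy, xx = np.mgrid[0:8, 0:8]
        board = ((yy + xx) % 2) * 10.0
        seg8 = cb.segment_band(board, connectivity=8)
        assert seg8.region_count == 2
        assert seg8.entropy == pytest.approx(1.0)
        # under 4-connectivity every square is isolated: 64 regions, 6 bits
        seg4 = cb.segment_band(board, connectivity=4)
        assert seg4.region_count == 64
        assert seg4.entropy == pytest.approx(6.0)

    def test_every_pixel_in_exactly_one_region(self, default_cube):
        cube, _ = default_cube
        seg = cb.segment_band(cube.band(49))
        assert seg.region_sizes.sum() == cube.n_lines * cube.n_samples
        assert seg.labels.min() >= 1
        assert seg.labels.max() == seg.region_count
        assert seg.entropy <= np.log2(seg.region_count) + 1e-9


class TestPrune:
    def test_compact_blob_band_is_kept(self):
        # one 410-pixel rectangle on a 64x64 grid: sizes {410, 3686},
        # H = -(410/4096)log2(410/4096) - (3686/4096)log2(3686/4096) ~ 0.47
        img = np.zeros((64, 64))
        img[20:30, 10:51] = 100.0
        cube = cb.Hypercube(img[:, :, None], np.array([500.0]))
        sel = cb.prune([0], cube, threshold=1.0)
        assert sel.selected == [0]
        assert sel.entropies[0] == pytest.approx(0.468, abs=0.005)

    def test_spatially_noisy_bands_are_rejected(self):
        # bimodal but spatially scrambled: shatters into many specks
        rejected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img = rng.choice([0.0, 100.0], size=(64, 64))
            cube = cb.Hypercube(img[:, :, None], np.array([500.0]))
            sel = cb.prune([0], cube, threshold=1.0)
            if sel.fallback:
                rejected += 1
            assert sel.entropies[0] > 1.0
        assert rejected == 10

    def test_fallback_keeps_lowest_entropy_candidate(self):
        rng = np.random.default_rng(1)
        data = np.stack(
            [rng.choice([0.0, 100.0], size=(32, 32)) for _ in range(3)], axis=2
        )
        cube = cb.Hypercube(data, np.array([500.0, 510.0, 520.0]))
        sel = cb.prune([0, 1, 2], cube, threshold=1.0)
        assert sel.fallback
        assert sel.selected == [sel.candidates[int(np.argmin(sel.entropies))]]

    def test_partition_invariants(self, default_cube):
        cube, _ = default_cube
        curve = cb.build_curve(cube)
        sel = cb.prune(curve.candidates or [0, 10, 20], cube)
        rejected_bands = [b for b, _ in sel.rejected]
        assert sorted(sel.selected + rejected_bands) == sorted(sel.candidates)
        assert not set(sel.selected) & set(rejected_bands)
        assert len(sel.selected) <= len(sel.candidates)
        if not sel.fallback:
            assert all(h <= sel.threshold
                       for b, h in zip(sel.candidates, sel.entropies) if b in sel.selected)

    def test_empty_candidates_rejected(self, default_cube):
        cube, _ = default_cube
        with pytest.raises(ValueError):
            cb.prune([], cube)
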