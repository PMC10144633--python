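"""Visual domain: equalization, morphology, eye-state profile, blink dynamics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatiguefusion.errors import DetectionError, InvalidParameterError
from fatiguefusion.fixtures import render_eye_frames
from fatiguefusion.visual import (
    CLOSED,
    OPEN,
    BrightBlobEyePairDetector,
    EyePairROI,
    EyeStateSeries,
    VisualFeatureVector,
    blink_dynamics,
    classify_eye_state,
    detect_eye_pair,
    equalize_histogram,
    morphological_pipeline,
)


def rle_oracle(states, fps):
    """Independent run-length oracle for the blink-dynamics features."""
    dt = 1.0 / fps
    runs = [(k, len(list(g))) for k, g in itertools.groupby(states)]
    ecp = sum(n for k, n in runs if k == CLOSED) * dt
    bkc = sum(
        1 for i, (k, _) in enumerate(runs) if k == CLOSED and 0 < i < len(runs) - 1
    )
    oc = sum(1 for a, b in zip(states, states[1:]) if (a, b) == (OPEN, CLOSED))
    co = sum(1 for a, b in zip(states, states[1:]) if (a, b) == (CLOSED, OPEN))
    ocop = dt if oc else 0.0
    cocp = dt if co else 0.0
    return ecp, ocop, cocp, ocop + cocp, oc + co, bkc


class TestEqualizeHistogram:
    def test_constant_image_maps_to_full_scale(self):
        img = np.full((8, 8), 77, dtype=np.uint8)
        out = equalize_histogram(img)
        assert np.all(out == 255)

    def test_two_level_image_preserves_order(self):
        out = equalize_histogram(np.array([[0, 0], [255, 255]], dtype=np.uint8))
        # direct CDF: level 0 -> 0.5 -> 128, level 255 -> 1.0 -> 255
        assert np.array_equal(out, np.array([[128, 128], [255, 255]]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rank_order_of_levels_preserved(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        out = equalize_histogram(img)
        levels = np.unique(img)
        mapped = [out[img == lv][0] for lv in levels]
        assert all(a <= b for a, b in zip(mapped, mapped[1:]))

    def test_cdf_near_linear_with_many_levels(self):
        # every level 0..255 present equally often: output CDF within 1/256 of linear
        img = np.tile(np.arange(256, dtype=np.uint8), (16, 1))
        out = equalize_histogram(img)
        cdf = np.cumsum(np.bincount(out.ravel(), minlength=256)) / out.size
        linear = (np.arange(256) + 1) / 256
        assert np.max(np.abs(cdf - linear)) <= 1 / 256 + 1e-12

    def test_idempotent_up_to_quantization(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        once = equalize_histogram(img)
        twice = equalize_histogram(once)
        assert np.max(np.abs(twice.astype(int) - once.astype(int))) <= 1

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            equalize_histogram(np.empty((0, 0)))


class TestMorphologicalPipeline:
    def test_flat_roi_yields_no_edges(self):
        assert not morphological_pipeline(np.full((20, 30), 50.0)).any()

    def test_bright_disk_yields_boundary_ring(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disk_img = np.where((xx - 20) ** 2 + (yy - 20) ** 2 <= 12**2, 200.0, 10.0)
        edges = morphological_pipeline(disk_img, selem_radius=2)
        r = np.hypot(yy - 20, xx - 20)
        assert edges[(r > 11) & (r < 16)].any()  # ring near the boundary
        assert not edges[r < 8].any()  # interior clean
        assert not edges[r > 19].any()  # far field clean

    def test_salt_noise_removed_by_opening(self):
        img = np.zeros((30, 30))
        img[5, 5] = img[20, 17] = 255.0  # isolated specks
        assert not morphological_pipeline(img, selem_radius=2).any()

    def test_selem_larger_than_roi_rejected(self):
        with pytest.raises(InvalidParameterError):
            morphological_pipeline(np.zeros((4, 4)), selem_radius=5)


class TestClassifyEyeState:
    def test_all_zero_roi_is_closed(self):
        assert classify_eye_state(np.zeros((5, 16), dtype=bool)) == CLOSED

    def test_three_white_runs_is_open(self):
        row = np.array([int(c) for c in "0001100110011000"], dtype=bool)
        roi = np.tile(row, (3, 1))
        assert classify_eye_state(roi) == OPEN  # 6 transitions >= 6

    def test_single_white_run_is_closed(self):
        row = np.zeros(16, dtype=bool)
        row[6:10] = True
        roi = np.tile(row, (3, 1))
        assert classify_eye_state(roi) == CLOSED  # 2 transitions

    def test_min_run_filters_single_pixel_noise(self):
        row = np.array([0, 1, 0, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
        roi = np.tile(row, (3, 1))
        assert classify_eye_state(roi, min_run=1) == OPEN
        assert classify_eye_state(roi, min_run=2) == CLOSED

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_eye_state(np.empty((3, 0)))


class TestBlinkDynamics:
    def make(self, states, fps=30.0):
        return EyeStateSeries(
            states=tuple(states),
            timestamps=np.arange(len(states)) / fps,
            fps=fps,
        )

    def test_all_open_has_no_closures(self):
        vec = blink_dynamics(self.make([OPEN] * 60, fps=30))
        assert (vec.ECP, vec.BKC, vec.ICFC) == (0.0, 0.0, 0.0)

    def test_single_blink_run_lengths(self):
        states = [OPEN] * 30 + [CLOSED] * 15 + [OPEN] * 45
        vec = blink_dynamics(self.make(states, fps=30))
        assert vec.ECP == pytest.approx(0.5)
        assert vec.BKC == 1
        assert vec.TCT == pytest.approx(vec.OCOP + vec.COCP)

    def test_alternating_states_count_every_boundary(self):
        n = 21
        states = [OPEN if i % 2 == 0 else CLOSED for i in range(n)]
        vec = blink_dynamics(self.make(states))
        assert vec.ICFC == n - 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_run_length_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            n = int(rng.integers(1, 120))
            states = [OPEN if rng.random() < 0.6 else CLOSED for _ in range(n)]
            vec = blink_dynamics(self.make(states))
            expected = rle_oracle(states, 30.0)
            got = (vec.ECP, vec.OCOP, vec.COCP, vec.TCT, vec.ICFC, vec.BKC)
            assert got == pytest.approx(expected)

    def test_tct_identity_holds_exactly(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            states = [OPEN if rng.random() < 0.5 else CLOSED for _ in range(40)]
            vec = blink_dynamics(self.make(states))
            assert vec.TCT == vec.OCOP + vec.COCP

    def test_empty_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            blink_dynamics(self.make([]))


class TestDetectEyePair:
    def test_explicit_roi_passthrough(self):
        frame = np.zeros((100, 200), dtype=np.uint8)
        roi = detect_eye_pair(frame, roi=(10, 20, 80, 30))
        assert roi.as_tuple() == (10, 20, 80, 30)

    def test_roi_out_of_bounds_rejected(self):
        frame = np.zeros((50, 60), dtype=np.uint8)
        with pytest.raises(InvalidParameterError):
            detect_eye_pair(frame, roi=(30, 30, 40, 10))

    def test_blob_detector_overlaps_ground_truth(self):
        seq, gt = render_eye_frames(5, 30, [OPEN] * 5, seed=11)
        det = BrightBlobEyePairDetector()
        for frame in seq.frames:
            found = detect_eye_pair(frame, detector=det)
            a, b = found.as_tuple(), gt.eye_roi.as_tuple()
            ix = max(0, min(a[0] + a[2], b[0] + b[2]) - max(a[0], b[0]))
            iy = max(0, min(a[1] + a[3], b[1] + b[3]) - max(a[1], b[1]))
            inter = ix * iy
            union = a[2] * a[3] + b[2] * b[3] - inter
            assert inter / union >= 0.5

    def test_flat_frame_raises_detection_error(self):
        with pytest.raises(DetectionError):
            detect_eye_pair(np.full((60, 80), 9, dtype=np.uint8))


def test_feature_vector_invariants_on_fixture_sequences():
    rng = np.random.default_rng(5)
    states = [OPEN if rng.random() < 0.8 else CLOSED for _ in range(45)]
    seq, gt = render_eye_frames(45, 30, states, seed=6)
    from fatiguefusion.visual import extract_visual_features

    vec = extract_visual_features(seq, roi=gt.eye_roi)
    assert isinstance(vec, VisualFeatureVector)
    assert vec.TCT == vec.OCOP + vec.COCP
    assert 0 <= vec.ECP <= 45 / 30
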