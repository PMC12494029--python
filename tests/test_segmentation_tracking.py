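"""FA segmentation recipe and LAP track linking rules."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import make_segment
from fawave.segmentation import mask_iou, preprocess, segment_fas, segment_stack
from fawave.synthetic import generate_stack, stack_preset
from fawave.tracking import (
    classify_assembly,
    nearest_neighbor_tracks,
    track_fas,
)

PX = 0.2  # um


def _blob_frame(centers_px, r_px=4, ny=96, nx=96, amp=500.0, bg=10.0):
    yy, xx = np.mgrid[0:ny, 0:nx]
    img = np.full((ny, nx), bg)
    for cx, cy in centers_px:
        disk = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2).astype(float)
        img += amp * ndimage.gaussian_filter(disk, 1.0)
    return img


class TestPreprocess:
    def test_impulse_noise_removed_by_median(self):
        stack = np.full((5, 32, 32), 20.0)
        stack[2, 16, 16] = 5000.0
        out = preprocess(stack)
        # hot pixel suppressed relative to its unfiltered response
        ref = preprocess(np.full((5, 32, 32), 20.0))
        assert abs(out[2, 16, 16] - ref[2, 16, 16]) < 1.0

    def test_blob_center_remains_local_extremum(self):
        frame = _blob_frame([(48, 48)])
        out = preprocess(np.stack([frame] * 3))[1]
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert abs(peak[0] - 48) <= 1 and abs(peak[1] - 48) <= 1

    def test_flat_image_stays_flat(self):
        out = preprocess(np.full((3, 32, 32), 7.0))
        assert np.allclose(out, out[0, 16, 16])

    def test_short_stack_falls_back_to_2d(self):
        with pytest.warns(UserWarning, match="falling back to 2D"):
            preprocess(np.random.default_rng(0).uniform(0, 1, (2, 16, 16)))


class TestSegmentFAs:
    def test_two_separated_blobs_found_at_truth(self):
        frame = _blob_frame([(30, 30), (60, 60)])
        segs = segment_fas(preprocess(frame[None])[0], PX)
        assert len(segs) == 2
        got = sorted((s.centroid_um[0], s.centroid_um[1]) for s in segs)
        for (gx, gy), (tx, ty) in zip(got, [(30 * PX, 30 * PX), (60 * PX, 60 * PX)]):
            assert abs(gx - tx) < PX and abs(gy - ty) < PX

    def test_tiny_blob_removed_by_area_gate(self):
        # ~5-px response at 0.15 um/px is ~0.11 um^2 -> below the 0.2 gate
        frame = _blob_frame([(48, 48)], r_px=0.9)
        segs = segment_fas(preprocess(frame[None])[0], pixel_size_um=0.15)
        assert len(segs) == 0
        # the same object passes once it is larger than the gate
        frame = _blob_frame([(48, 48)], r_px=4)
        segs = segment_fas(preprocess(frame[None])[0], pixel_size_um=0.15)
        assert len(segs) == 1 and segs[0].area_um2 >= 0.2

    def test_touching_blobs_split_by_watershed(self):
        frame = _blob_frame([(44, 48), (54, 48)], r_px=4)
        segs = segment_fas(preprocess(frame[None])[0], PX)
        assert len(segs) == 2

    def test_flat_frame_yields_nothing(self):
        assert segment_fas(np.zeros((32, 32)), PX) == []


class TestSegmentationOnGeneratorStacks:
    def test_iou_against_ground_truth_at_default_snr(self, noisy_stack):
        cfg, stack, truth = noisy_stack
        segs = segment_stack(preprocess(stack.channel("ypet")), cfg.pixel_size_um)[0]
        assert len(segs) == len(cfg.fas)
        gt = truth.fa_label_stack[0]
        for s in segs:
            m = np.zeros(gt.shape, bool)
            m[s.pixels[:, 0], s.pixels[:, 1]] = True
            iou = max(mask_iou(m, gt == k) for k in range(1, gt.max() + 1))
            assert iou >= 0.7


class TestTracking:
    def test_single_drifting_blob_single_track(self):
        frames = [
            [make_segment(t, 1, 5.0 + 0.5 * t, 5.0)] for t in range(10)
        ]
        tracks = track_fas(frames)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 10

    def test_jump_beyond_gate_breaks_track(self):
        # 6 frames, 3-um jump, 6 more frames: both fragments < 7 frames
        frames = [[make_segment(t, 1, 5.0, 5.0)] for t in range(6)]
        frames += [[make_segment(t, 1, 8.0, 5.0)] for t in range(6, 12)]
        assert track_fas(frames) == []

    def test_crossing_blobs_match_nearest_neighbor_oracle(self):
        # two blobs crossing in y while separated > 2x the per-frame step
        frames = []
        for t in range(12):
            frames.append([
                make_segment(t, 1, 2.0 + 0.8 * t, 2.0),
                make_segment(t, 2, 12.0 - 0.8 * t, 7.0),
            ])
        lap = track_fas(frames)
        oracle = nearest_neighbor_tracks(frames)
        assert len(lap) == len(oracle) == 2
        for tl, to in zip(lap, oracle):
            np.testing.assert_allclose(tl.centroids_um, to.centroids_um)

    def test_short_track_discarded(self):
        frames = [[make_segment(t, 1, 5.0, 5.0)] for t in range(6)]
        assert track_fas(frames) == []

    def test_merge_keeps_larger_parent(self):
        # big and small blob converge onto one segment at frame 8
        frames = []
        for t in range(8):
            frames.append([
                make_segment(t, 1, 5.0, 5.0, area_um2=4.0),
                make_segment(t, 2, 5.0, 5.0 + 1.6 * (8 - t) / 8 + 0.2, area_um2=1.0),
            ])
        frames.append([make_segment(8, 1, 5.0, 5.0, area_um2=5.0)])
        tracks = track_fas(frames, min_len_frames=7)
        # the merged continuation belongs to the large-area parent
        assert any(tr.n_frames == 9 and tr.segments[0].area_um2 == 4.0 for tr in tracks)

    def test_excessive_movement_excluded(self):
        # wandering path: net > 2 um and path length > 5x net
        rng = np.random.default_rng(0)
        x, y, frames = 5.0, 5.0, []
        for t in range(40):
            frames.append([make_segment(t, 1, x, y)])
            ang = rng.uniform(0, 2 * np.pi)
            x += 1.5 * np.cos(ang) + 0.08
            y += 1.5 * np.sin(ang)
        tracks = track_fas(frames)
        total_net = [tr.path_stats_um() for tr in tracks]
        for total, net in total_net:
            assert not (net > 2.0 and total > 5 * net)


class TestClassifyAssembly:
    def _track(self, size_indices):
        from fawave.tracking import FATrack

        tr = FATrack(track_id=0)
        for t, s in enumerate(size_indices):
            tr.segments.append(make_segment(t, 1, 5.0, 5.0, area_um2=1.0, brightness=s))
        return tr

    def test_constant_stable(self):
        assert classify_assembly(self._track([1.0] * 10)) == "stable"

    def test_ramp_up_assembling(self):
        assert classify_assembly(self._track(np.linspace(1.0, 1.5, 10))) == "assembling"

    def test_decay_disassembling(self):
        assert classify_assembly(self._track(np.linspace(1.0, 0.6, 10))) == "disassembling"

    def test_rescaling_invariance(self):
        vals = list(np.linspace(1.0, 1.5, 10))
        assert classify_assembly(self._track([10 * v for v in vals])) == classify_assembly(
            self._track(vals)
        )

    def test_short_track_raises(self):
        with pytest.raises(ValueError, match="too short"):
            classify_assembly(self._track([1.0, 1.0]))
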