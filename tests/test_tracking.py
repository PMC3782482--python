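import math

import numpy as np
import pytest

from flychain import synthscene as ss
from flychain import tracking as tr

CHAMBER = (83, 417)
BG = np.full(CHAMBER, ss.BACKGROUND_LEVEL)


def _frame_from_masks(masks):
    img = np.full(CHAMBER, ss.BACKGROUND_LEVEL)
    for m in masks:
        img[m] = ss.FLY_LEVEL
    return img


class TestSegmentFlies:
    def test_empty_chamber_yields_nothing(self):
        assert tr.segment_flies(BG.copy(), BG) == []

    def test_six_separated_flies_recovered(self):
        rng = np.random.default_rng(1)
        positions = [(20 + 40 * (i % 2), 30 + 60 * i) for i in range(6)]
        masks = [ss.render_fly(p, rng.uniform(0, 6.28), ss.FlyShape(), CHAMBER)
                 for p in positions]
        sils = tr.segment_flies(_frame_from_masks(masks), BG)
        assert len(sils) == 6
        assert not any(s.merged for s in sils)
        got = sorted(tuple(s.pixels.mean(axis=0)) for s in sils)
        want = sorted(tuple(np.argwhere(m).mean(axis=0)) for m in masks)
        for g, w in zip(got, want):
            assert np.linalg.norm(np.subtract(g, w)) < 1.0

    def test_overlapping_flies_flagged_merged(self):
        # a pair overlapping by ~30% plus four separated singles: the pair
        # forms one component, flagged merged against the single-fly median
        m1 = ss.render_fly((41, 100), 0.0, ss.FlyShape(), CHAMBER)
        m2 = ss.render_fly((41, 110), 0.0, ss.FlyShape(), CHAMBER)
        singles = [ss.render_fly((25 + 30 * (i % 2), 180 + 55 * i), 0.7 * i,
                                 ss.FlyShape(), CHAMBER) for i in range(4)]
        sils = tr.segment_flies(_frame_from_masks([m1, m2] + singles), BG)
        merged = [s for s in sils if s.merged]
        assert len(sils) == 5
        assert len(merged) == 1
        assert merged[0].area > np.count_nonzero(m1) * 1.5

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(tr.ParameterError):
            tr.segment_flies(np.zeros((5, 5)), np.zeros((6, 6)))


class TestSplitMerged:
    def test_touching_pair_split_near_truth(self):
        m1 = ss.render_fly((41, 100), 0.0, ss.FlyShape(), CHAMBER)
        m2 = ss.render_fly((41, 120), 0.0, ss.FlyShape(), CHAMBER)  # head-to-tail touch
        blob = tr.Silhouette(pixels=np.argwhere(m1 | m2), merged=True)
        parts = tr.split_merged(blob, expected=2)
        assert len(parts) == 2
        truth = sorted([np.argwhere(m1).mean(axis=0)[1], np.argwhere(m2).mean(axis=0)[1]])
        got = sorted(p.pixels.mean(axis=0)[1] for p in parts)
        for g, t in zip(got, truth):
            assert abs(g - t) < 3.0

    def test_partition_invariant(self):
        m = ss.render_fly((41, 100), 0.5, ss.FlyShape(), CHAMBER)
        blob = tr.Silhouette(pixels=np.argwhere(m), merged=True)
        parts = tr.split_merged(blob, expected=2)
        union = np.vstack([p.pixels for p in parts])
        assert len(union) == blob.area
        assert {tuple(p) for p in union} == {tuple(p) for p in blob.pixels}

    def test_expected_below_two_rejected(self):
        blob = tr.Silhouette(pixels=np.argwhere(
            ss.render_fly((41, 100), 0.0, ss.FlyShape(), CHAMBER)), merged=True)
        with pytest.raises(tr.ParameterError):
            tr.split_merged(blob, expected=1)


class TestFitBodyEllipse:
    def test_solid_ellipse_moments(self):
        # 19 x 8 px solid ellipse at 30 degrees: orientation within 2 deg,
        # axes within 10%
        theta = math.radians(30)
        rr, cc = np.mgrid[0:83, 0:417]
        u = np.array([math.sin(theta), math.cos(theta)])
        x = (rr - 41) * u[0] + (cc - 200) * u[1]
        y = -(rr - 41) * u[1] + (cc - 200) * u[0]
        inside = (x / 9.5) ** 2 + (y / 4.0) ** 2 <= 1
        pose = tr.fit_body_ellipse(tr.Silhouette(pixels=np.argwhere(inside)))
        d = (pose.orientation - theta) % math.pi
        assert min(d, math.pi - d) < math.radians(2)
        assert pose.major_axis_len == pytest.approx(19, rel=0.10)
        assert pose.minor_axis_len == pytest.approx(8, rel=0.10)
        assert not pose.degenerate

    def test_disc_is_degenerate(self):
        rr, cc = np.mgrid[0:30, 0:30]
        disc = (rr - 15) ** 2 + (cc - 15) ** 2 <= 64
        pose = tr.fit_body_ellipse(tr.Silhouette(pixels=np.argwhere(disc)))
        assert pose.degenerate

    def test_orientation_unoriented_mod_pi(self, fly_factory):
        s1, _, _ = fly_factory(heading=math.radians(30))
        s2, _, _ = fly_factory(heading=math.radians(210))
        p1, p2 = tr.fit_body_ellipse(s1), tr.fit_body_ellipse(s2)
        assert p1.orientation == pytest.approx(p2.orientation, abs=1e-6)

    def test_tiny_blob_rejected(self):
        with pytest.raises(tr.ShapeError):
            tr.fit_body_ellipse(tr.Silhouette(pixels=[[0, 0], [0, 1]]))


class TestAssignHeadTail:
    def test_sharp_end_is_tail(self, fly_factory):
        # teardrop heading east: tail (sharp) at the west end
        sil, true, _ = fly_factory(position=(41, 200), heading=0.0)
        pose = tr.assign_head_tail(sil, tr.fit_body_ellipse(sil))
        assert pose.H[1] > pose.T[1]
        assert np.linalg.norm(pose.H - true.H) < 3.0

    def test_symmetric_blob_follows_previous_heading(self):
        rr, cc = np.mgrid[0:83, 0:417]
        inside = ((rr - 41) / 4.0) ** 2 + ((cc - 200) / 9.5) ** 2 <= 1  # plain ellipse
        sil = tr.Silhouette(pixels=np.argwhere(inside))
        pose = tr.fit_body_ellipse(sil)
        prev = tr.FlyPose(centroid=(41, 200), major_axis_len=19, minor_axis_len=8,
                          orientation=0.0, H=(41, 209), T=(41, 191))
        # force the tie-break path regardless of tiny corner asymmetries
        pose.degenerate = False
        got = tr.assign_head_tail(sil, pose, prev=prev)
        assert got.H[1] > got.T[1] or not _ambiguous(sil, pose)

    def test_corner_rule_overrides_stale_prev(self, fly_factory):
        sil, true, _ = fly_factory(position=(41, 200), heading=0.0)
        # previous heading 90 deg off: the response gap (>10%) must win
        prev = tr.FlyPose(centroid=(41, 200), major_axis_len=19, minor_axis_len=8,
                          orientation=math.pi / 2, H=(50, 200), T=(32, 200))
        pose = tr.assign_head_tail(sil, tr.fit_body_ellipse(sil), prev=prev)
        assert np.linalg.norm(pose.H - true.H) < np.linalg.norm(pose.H - true.T)

    def test_degenerate_without_prev_flagged_unreliable(self):
        rr, cc = np.mgrid[0:30, 0:30]
        disc = (rr - 15) ** 2 + (cc - 15) ** 2 <= 64
        sil = tr.Silhouette(pixels=np.argwhere(disc))
        pose = tr.assign_head_tail(sil, tr.fit_body_ellipse(sil))
        assert pose.ht_unreliable


def _ambiguous(sil, pose):
    e1 = pose.centroid + pose.major_axis_len / 2 * pose.axis_unit
    e2 = pose.centroid - pose.major_axis_len / 2 * pose.axis_unit
    r1, r2 = tr._harris_endpoint_responses(sil, e1, e2)
    return abs(r1 - r2) < tr.HT_TIE_FRACTION * max(abs(r1), abs(r2))


class TestPoseRecoveryAccuracy:
    def test_on_200_random_single_fly_frames(self, random_single_fly_frames):
        """Median centroid error < 1 px, axis-angle error < 3 deg, head/tail
        right in >= 95% of non-degenerate frames (renderer ground truth)."""
        cent_err, ang_err, ht_ok, n_valid = [], [], 0, 0
        for pos, th, mask in random_single_fly_frames:
            pix = np.argwhere(mask)
            sil = tr.Silhouette(pixels=pix)
            pose = tr.assign_head_tail(sil, tr.fit_body_ellipse(sil))
            cent_err.append(np.linalg.norm(pose.centroid - pix.mean(axis=0)))
            d = (pose.orientation - th) % math.pi
            ang_err.append(math.degrees(min(d, math.pi - d)))
            if pose.degenerate or pose.ht_unreliable:
                continue
            n_valid += 1
            true_H = pos + 9.5 * np.array([math.sin(th), math.cos(th)])
            ht_ok += np.linalg.norm(pose.H - true_H) < np.linalg.norm(pose.T - true_H)
        assert np.median(cent_err) < 1.0
        assert np.median(ang_err) < 3.0
        assert ht_ok / n_valid >= 0.95

    def test_rotation_equivariance(self, fly_factory):
        sil, _, mask = fly_factory(position=(41, 60), heading=math.radians(20))
        rot = np.rot90(mask)  # 90 deg CCW
        p1 = tr.fit_body_ellipse(sil)
        p2 = tr.fit_body_ellipse(tr.Silhouette(pixels=np.argwhere(rot)))
        d = (p2.orientation - p1.orientation) % math.pi
        assert min(abs(d - math.pi / 2), abs(d - math.pi / 2)) < math.radians(2)


class TestLinkPoses:
    def test_nearest_centroid_matching(self):
        prev = [
            tr.FlyPose(centroid=(10, 10), major_axis_len=19, minor_axis_len=8, orientation=0),
            tr.FlyPose(centroid=(50, 50), major_axis_len=19, minor_axis_len=8, orientation=0),
        ]
        matches = tr.link_poses(prev, np.array([[51, 49], [11, 12]]))
        assert matches[0] is prev[1]
        assert matches[1] is prev[0]

    def test_no_previous_poses(self):
        assert tr.link_poses([], np.array([[1, 2]])) == [None]
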