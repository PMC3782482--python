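import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flychain import chain_geometry as cg
from flychain import synthscene as ss
from flychain import tracking as tr

CHAMBER = (83, 417)


def _pose(centroid, heading, length=19.0, width=8.0):
    u = np.array([math.sin(heading), math.cos(heading)])
    c = np.asarray(centroid, float)
    return tr.FlyPose(
        centroid=c, major_axis_len=length, minor_axis_len=width,
        orientation=heading % math.pi,
        H=c + length / 2 * u, T=c - length / 2 * u,
    )


class TestHeadBase:
    def test_collinear_arithmetic(self):
        q = cg.head_base((0, 10), (0, -9), q_offset=5)
        np.testing.assert_allclose(q, (0, 5))

    def test_zero_offset_is_head(self):
        np.testing.assert_allclose(cg.head_base((3, 4), (0, 0), 0), (3, 4))

    def test_short_body_rejected(self):
        with pytest.raises(cg.GeometryError):
            cg.head_base((0, 4), (0, 0), q_offset=5)


class TestChainRegionContains:
    def setup_method(self):
        self.pose = _pose((0, 0), heading=0.0)  # head at (0, 9.5), east
        self.params = cg.ChainParams()
        self.Q = cg.head_base(self.pose.H, self.pose.T, 5.0)

    def test_boundary_point_on_axis_inside(self):
        p = self.Q + np.array([0.0, self.params.radius])
        assert cg.chain_region_contains(self.pose, self.params, p)

    def test_point_behind_q_outside(self):
        assert not cg.chain_region_contains(self.pose, self.params, self.Q - (0, 3))

    def test_monotone_in_k(self):
        ang = 0.66 * math.pi / 2 + 0.01
        p = self.Q + 10 * np.array([math.sin(ang), math.cos(ang)])
        assert not cg.chain_region_contains(self.pose, self.params, p)
        wider = cg.ChainParams(L=13.0, k=0.8, q_offset=5.0)
        assert cg.chain_region_contains(self.pose, wider, p)

    def test_degenerate_pose_has_empty_region(self):
        pose = _pose((0, 0), 0.0)
        pose.degenerate = True
        assert not cg.chain_region_contains(pose, self.params, (0, 12))

    @given(
        st.floats(0, 2 * math.pi),
        st.floats(0.5, 25.0),
        st.floats(10.0, 14.0),
        st.floats(0.4, 0.9),
    )
    def test_region_monotone_in_L_and_k(self, ang, dist, L, k):
        """The region at (L,k) is a subset of the region at (L', k') >= (L, k)."""
        pose = _pose((40, 40), heading=1.0)
        Q = cg.head_base(pose.H, pose.T, 5.0)
        p = Q + dist * np.array([math.sin(ang), math.cos(ang)])
        small = cg.ChainParams(L=L, k=k)
        big = cg.ChainParams(L=L + 1.0, k=min(k + 0.1, 1.0))
        if cg.chain_region_contains(pose, small, p):
            assert cg.chain_region_contains(pose, big, p)


class TestDetectChainEdges:
    def test_follower_behind_leader_single_edge(self):
        leader = _pose((41, 120), 0.0)
        follower = _pose((41, 91), 0.0)  # head 10 px behind leader's tail
        masks = [
            ss.render_fly(p.centroid, 0.0, ss.FlyShape(), CHAMBER)
            for p in (leader, follower)
        ]
        sils = [tr.Silhouette(pixels=np.argwhere(m)) for m in masks]
        g = cg.detect_chain_edges([leader, follower], sils)
        assert (1, 0) in g.edges
        assert (0, 1) not in g.edges

    def test_far_apart_no_edges(self):
        a, b = _pose((41, 50), 0.0), _pose((41, 150), 0.0)
        g = cg.detect_chain_edges([a, b], None)
        assert g.edges == []

    def test_parallel_side_by_side_no_edges(self):
        a, b = _pose((20, 100), 0.0), _pose((60, 100), 0.0)
        masks = [ss.render_fly(p.centroid, 0.0, ss.FlyShape(), CHAMBER) for p in (a, b)]
        sils = [tr.Silhouette(pixels=np.argwhere(m)) for m in masks]
        g = cg.detect_chain_edges([a, b], sils)
        assert g.edges == []

    def test_unreliable_pose_receives_but_never_chases(self):
        leader = _pose((41, 120), 0.0)
        leader.ht_unreliable = True
        follower = _pose((41, 91), 0.0)
        g = cg.detect_chain_edges([leader, follower], None)
        assert all(i != 0 for i, _ in g.edges)
        assert (1, 0) in g.edges

    def test_ellipse_fallback_matches_silhouette_route(self):
        leader = _pose((41, 118), 0.0)
        follower = _pose((41, 90), 0.0)
        masks = [ss.render_fly(p.centroid, 0.0, ss.FlyShape(), CHAMBER)
                 for p in (leader, follower)]
        sils = [tr.Silhouette(pixels=np.argwhere(m)) for m in masks]
        with_sil = cg.detect_chain_edges([leader, follower], sils)
        no_sil = cg.detect_chain_edges([leader, follower], None)
        assert set(with_sil.edges) == set(no_sil.edges)


class TestChainIndex:
    def test_single_edge_counts_both_flies(self):
        # one chaser plus its passive recipient score 2
        g = cg.ChainGraph(frame_index=0, edges=[(0, 1)])
        assert cg.chain_index(g) == 2

    def test_empty_graph_scores_zero(self):
        assert cg.chain_index(cg.ChainGraph(frame_index=0, edges=[])) == 0

    def test_three_fly_train_scores_three(self):
        g = cg.ChainGraph(frame_index=0, edges=[(0, 1), (1, 2)])
        assert cg.chain_index(g) == 3

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError):
            cg.ChainGraph(frame_index=0, edges=[(1, 1)])


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("angle_deg,shift", [(0, (7.3, -11.1)), (90, (0, 0)), (37, (5, 5))])
    def test_chain_index_invariant(self, angle_deg, shift):
        rng = np.random.default_rng(4)
        base = [(41 + rng.uniform(-15, 15), 120 + 30 * i + rng.uniform(-10, 10))
                for i in range(4)]
        headings = rng.uniform(0, 2 * math.pi, 4)
        a = math.radians(angle_deg)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        center = np.array([41.0, 180.0])

        def poses(transform):
            out = []
            for (r, c), h in zip(base, headings):
                p = np.array([r, c])
                if transform:
                    # in (row, col) coordinates this R maps heading h to h - a
                    p = R @ (p - center) + center + shift
                    h = h - a
                out.append(_pose(p, h))
            return out

        g0 = cg.detect_chain_edges(poses(False), None)
        g1 = cg.detect_chain_edges(poses(True), None)
        assert cg.chain_index(g0) == cg.chain_index(g1)
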