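"""Chain-region construction and per-frame chain-index scoring.

A chasing fly projects a fan-shaped "chain region" in front of its head.
The region is anchored at Q, the rear end of the head area, which sits on
the tail-to-head segment 5 px (0.6 mm) behind the head H.  A point p is
inside the region when it lies within radius ``q_offset + L`` of Q (so the
fan extends exactly L beyond the head along the body axis) and the angle
between ``p - Q`` and the body direction ``H - T`` is at most ``k * pi/2``.
L = 13 px and k = 0.66 are the constants at which automatic scores match an
experienced human observer.

A directed chasing edge i -> j exists when any pixel of fly j's body falls
inside fly i's chain region.  The chain index of a frame is the number of
distinct flies incident to at least one edge — chasers and passive
recipients (the leader of a train) both count, so a single chasing pair
scores 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tracking import FlyPose, Silhouette

__all__ = [
    "ChainParams",
    "ChainGraph",
    "head_base",
    "chain_region_contains",
    "detect_chain_edges",
    "chain_index",
]


class GeometryError(ValueError):
    """Degenerate geometry (e.g. body shorter than the head-area offset)."""


@dataclass(frozen=True)
class ChainParams:
    """Constants defining the chain region.

    L : length constant, px — how far the fan reaches beyond the head.
    k : angle constant in (0, 1] — half-angle of the fan is k*pi/2.
    q_offset : px — distance from head H back to the fan anchor Q.
    """

    L: float = 13.0
    k: float = 0.66
    q_offset: float = 5.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not 0 < self.k <= 1:
            raise ValueError("k must be in (0, 1]")
        if self.q_offset < 0:
            raise ValueError("q_offset must be non-negative")

    @property
    def radius(self) -> float:
        """Fan radius measured from Q."""
        return self.q_offset + self.L

    @property
    def half_angle(self) -> float:
        """Fan half-angle in radians."""
        return self.k * math.pi / 2.0


@dataclass
class ChainGraph:
    """Directed chasing graph of one frame."""

    frame_index: int
    edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")

    @property
    def chain_index(self) -> int:
        return chain_index(self)


def head_base(H, T, q_offset: float = 5.0) -> np.ndarray:
    """Anchor point Q on segment TH at distance ``q_offset`` from the head H."""
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    d = T - H
    body_len = float(np.linalg.norm(d))
    if body_len <= q_offset:
        raise GeometryError(
            f"body length {body_len:.2f} px must exceed q_offset {q_offset} px"
        )
    if q_offset == 0:
        return H.copy()
    return H + (q_offset / body_len) * d


def chain_region_contains(pose: FlyPose, params: ChainParams, p) -> bool:
    """Whether point ``p`` lies inside the fly's fan-shaped chain region.

    Boundary points count as inside; Q itself does not (distance must be
    positive).  A degenerate pose, or one with unreliable head/tail, has an
    empty region.
    """
    if pose.degenerate or pose.ht_unreliable or pose.H is None or pose.T is None:
        return False
    Q = head_base(pose.H, pose.T, params.q_offset)
    d = np.asarray(p, dtype=float) - Q
    dist = float(np.linalg.norm(d))
    if dist <= 0 or dist > params.radius:
        return False
    body_dir = pose.H - pose.T
    cosang = float(d @ body_dir) / (dist * float(np.linalg.norm(body_dir)))
    ang = math.acos(min(1.0, max(-1.0, cosang)))
    return ang <= params.half_angle + 1e-12


def _body_points(pose: FlyPose, silhouette: Silhouette | None) -> np.ndarray:
    """Pixel set representing a fly's body: silhouette if available, else the
    fitted-ellipse interior rasterized at integer pixel centres."""
    if silhouette is not None and silhouette.area > 0:
        return silhouette.pixels.astype(float)
    a = pose.major_axis_len / 2.0
    b = pose.minor_axis_len / 2.0
    u = pose.axis_unit
    n = np.array([-u[1], u[0]])
    r0, c0 = pose.centroid
    half = math.ceil(max(a, b))
    rr, cc = np.mgrid[
        math.floor(r0) - half : math.ceil(r0) + half + 1,
        math.floor(c0) - half : math.ceil(c0) + half + 1,
    ]
    dr = rr - r0
    dc = cc - c0
    x = dr * u[0] + dc * u[1]
    y = dr * n[0] + dc * n[1]
    inside = (x / max(a, 1e-9)) ** 2 + (y / max(b, 1e-9)) ** 2 <= 1.0
    return np.column_stack([rr[inside], cc[inside]]).astype(float)


def _region_test_vec(pose: FlyPose, params: ChainParams, pts: np.ndarray) -> bool:
    """True if any of ``pts`` (N,2) is inside the pose's chain region."""
    Q = head_base(pose.H, pose.T, params.q_offset)
    d = pts - Q
    dist = np.linalg.norm(d, axis=1)
    ok = (dist > 0) & (dist <= params.radius)
    if not ok.any():
        return False
    body_dir = pose.H - pose.T
    body_dir = body_dir / np.linalg.norm(body_dir)
    cosang = (d[ok] @ body_dir) / dist[ok]
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    return bool((ang <= params.half_angle + 1e-12).any())


def detect_chain_edges(
    poses: list[FlyPose],
    silhouettes: list[Silhouette | None] | None = None,
    params: ChainParams = ChainParams(),
    frame_index: int = 0,
) -> ChainGraph:
    """Build the directed chasing graph of one frame.

    Edge i -> j (i != j) iff some pixel of fly j's body lies inside fly i's
    chain region.  Flies with unreliable head/tail or degenerate poses emit
    no edges but can still be chased (receive edges).
    """
    n = len(poses)
    if silhouettes is None:
        silhouettes = [None] * n
    if len(silhouettes) != n:
        raise ValueError("poses and silhouettes must be index-aligned")
    bodies = [_body_points(p, s) for p, s in zip(poses, silhouettes)]
    edges: list[tuple[int, int]] = []
    for i, pose in enumerate(poses):
        if (
            pose.degenerate
            or pose.ht_unreliable
            or pose.H is None
            or pose.T is None
        ):
            continue
        if np.linalg.norm(pose.H - pose.T) <= params.q_offset:
            continue
        for j in range(n):
            if j == i or len(bodies[j]) == 0:
                continue
            if _region_test_vec(pose, params, bodies[j]):
                edges.append((i, j))
    return ChainGraph(frame_index=frame_index, edges=edges)


def chain_index(graph: ChainGraph) -> int:
    """Number of distinct flies incident to at least one chasing edge."""
    members: set[int] = set()
    for i, j in graph.edges:
        members.add(i)
        members.add(j)
    return len(members)
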