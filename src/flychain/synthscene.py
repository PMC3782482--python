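"""Synthetic chamber scenes with exact ground truth.

Renders backlit-chamber frames containing dark teardrop fly silhouettes —
an ellipse whose posterior half tapers to a point, because a real fly's
abdominal tip is sharper than its head — over a light background, with
scripted trajectories and optional Gaussian intensity noise.  Every frame
carries ground truth: true head/tail/centroid per fly and the true chain
index under stated region constants.

The ground-truth chain index comes from a brute-force pixel oracle written
independently of the analytic region predicate used by the scoring
pipeline: it rasterizes each fly's fan region over the whole chamber grid
and intersects the resulting pixel sets with the other flies' body masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chain_geometry import ChainParams
from .imaging import FrameSequence

__all__ = [
    "FlyShape",
    "SceneSpec",
    "TruePose",
    "GroundTruth",
    "render_fly",
    "render_scene",
    "oracle_chain_index",
    "scenario_idle",
    "scenario_dispersed",
    "scenario_chain_train",
]

# default chamber: 50 x 10 mm at 0.12 mm/px
DEFAULT_CHAMBER_SHAPE = (83, 417)  # rows, cols
BACKGROUND_LEVEL = 220.0
FLY_LEVEL = 60.0


@dataclass(frozen=True)
class FlyShape:
    """Teardrop silhouette geometry.

    ``length`` and ``width`` are the full body length/width in px (defaults
    match a 2.27-mm fly at 0.12 mm/px).  ``sharpness`` >= 1 controls how
    abruptly the posterior half tapers: the half-width profile is
    ``b*(1-|u|^2)^(sharpness/2)`` for axial position u in [-1, 0), which for
    sharpness=2 gives straight sides meeting in a point at the abdominal
    tip, while the anterior half stays a rounded half-ellipse.
    """

    length: float = 19.0
    width: float = 8.0
    sharpness: float = 2.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.sharpness < 1:
            raise ValueError("invalid fly shape")


@dataclass
class TruePose:
    """Scripted ground-truth pose: position is the shape centre, heading the
    unit vector from tail to head; H and T are the silhouette tips."""

    position: np.ndarray
    heading_rad: float
    shape: FlyShape = field(default_factory=FlyShape)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)

    @property
    def unit(self) -> np.ndarray:
        return np.array([math.sin(self.heading_rad), math.cos(self.heading_rad)])

    @property
    def H(self) -> np.ndarray:
        return self.position + (self.shape.length / 2.0) * self.unit

    @property
    def T(self) -> np.ndarray:
        return self.position - (self.shape.length / 2.0) * self.unit


@dataclass
class SceneSpec:
    """Scripted scene: one list of per-fly poses per frame."""

    trajectory: list[list[TruePose]]  # [frame][fly]
    chamber_shape: tuple[int, int] = DEFAULT_CHAMBER_SHAPE
    noise_sigma: float = 0.0
    seed: int | None = None
    background_level: float = BACKGROUND_LEVEL
    fly_level: float = FLY_LEVEL

    @property
    def n_frames(self) -> int:
        return len(self.trajectory)


@dataclass
class GroundTruth:
    """Per-frame true poses, body masks, mask centroids and chain indices."""

    poses: list[list[TruePose]]
    masks: list[list[np.ndarray]]  # boolean chamber-size masks
    centroids: list[np.ndarray]  # (n_flies, 2) true mask centroids per frame
    chain_index: np.ndarray
    params: ChainParams


def render_fly(
    position,
    heading_rad: float,
    shape: FlyShape = FlyShape(),
    chamber_shape: tuple[int, int] = DEFAULT_CHAMBER_SHAPE,
) -> np.ndarray:
    """Boolean silhouette mask of one teardrop fly.

    The anterior (head) half is a half-ellipse; the posterior half tapers to
    a sharp point at the abdominal tip.  Deterministic in its arguments.
    """
    position = np.asarray(position, dtype=float)
    a = shape.length / 2.0
    b = shape.width / 2.0
    u = np.array([math.sin(heading_rad), math.cos(heading_rad)])
    nvec = np.array([-u[1], u[0]])

    r0 = max(int(math.floor(position[0] - a - 2)), 0)
    r1 = min(int(math.ceil(position[0] + a + 2)) + 1, chamber_shape[0])
    c0 = max(int(math.floor(position[1] - a - 2)), 0)
    c1 = min(int(math.ceil(position[1] + a + 2)) + 1, chamber_shape[1])
    mask = np.zeros(chamber_shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - position[0]
    dc = cc - position[1]
    x = dr * u[0] + dc * u[1]  # along axis, + toward head
    y = dr * nvec[0] + dc * nvec[1]
    uax = np.clip(x / a, -1.0, 1.0)
    half_w = np.where(
        uax >= 0,
        b * np.sqrt(np.clip(1 - uax**2, 0, None)),
        b * np.clip(1 - uax**2, 0, None) ** (shape.sharpness / 2.0),
    )
    inside = (np.abs(x) <= a) & (np.abs(y) <= half_w)
    mask[r0:r1, c0:c1] = inside
    return mask


def render_scene(spec: SceneSpec, params: ChainParams = ChainParams()):
    """Render frames at 1 fps plus full ground truth.

    Flies are composited dark-on-light; Gaussian noise (if any) comes from a
    generator seeded by ``spec.seed`` so identical specs yield identical
    frames.  Ground-truth chain indices are computed by the pixel oracle.
    """
    rng = np.random.default_rng(spec.seed)
    frames: list[np.ndarray] = []
    all_masks: list[list[np.ndarray]] = []
    all_centroids: list[np.ndarray] = []
    indices = []
    for frame_poses in spec.trajectory:
        img = np.full(spec.chamber_shape, spec.background_level, dtype=float)
        masks = []
        cents = []
        for p in frame_poses:
            m = render_fly(p.position, p.heading_rad, p.shape, spec.chamber_shape)
            img[m] = spec.fly_level
            masks.append(m)
            coords = np.argwhere(m)
            cents.append(coords.mean(axis=0) if len(coords) else p.position)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
            img = np.clip(img, 0, 255)
        frames.append(img)
        all_masks.append(masks)
        all_centroids.append(np.asarray(cents))
        indices.append(oracle_chain_index(frame_poses, params, masks))
    seq = FrameSequence(frames=frames, fps=1.0)
    truth = GroundTruth(
        poses=spec.trajectory,
        masks=all_masks,
        centroids=all_centroids,
        chain_index=np.asarray(indices),
        params=params,
    )
    return seq, truth


def _rasterize_fan(
    H: np.ndarray, T: np.ndarray, params: ChainParams, chamber_shape: tuple[int, int]
) -> np.ndarray:
    """Brute-force pixel mask of one fly's fan region over the whole chamber.

    Written independently of the analytic predicate in chain_geometry: the
    anchor, radius test and angular test are recomputed here from scratch
    using a whole-grid atan2 formulation.
    """
    axis = H - T
    body_len = math.hypot(axis[0], axis[1])
    if body_len <= params.q_offset:
        return np.zeros(chamber_shape, dtype=bool)
    ux, uy = axis[0] / body_len, axis[1] / body_len
    Q = (H[0] - params.q_offset * ux, H[1] - params.q_offset * uy)
    rr, cc = np.mgrid[0 : chamber_shape[0], 0 : chamber_shape[1]]
    dr = rr - Q[0]
    dc = cc - Q[1]
    dist = np.hypot(dr, dc)
    # signed angle between the pixel offset and the body direction
    cross = dr * uy - dc * ux
    dot = dr * ux + dc * uy
    ang = np.abs(np.arctan2(cross, dot))
    return (dist > 0) & (dist <= params.q_offset + params.L) & (
        ang <= params.k * math.pi / 2.0 + 1e-12
    )


def oracle_chain_index(
    poses: list[TruePose],
    params: ChainParams,
    masks: list[np.ndarray] | None = None,
    chamber_shape: tuple[int, int] | None = None,
) -> int:
    """Ground-truth chain index by exhaustive pixel intersection.

    Every fly's fan region is rasterized over the full chamber grid and
    intersected with every other fly's body mask; flies incident to any
    overlap (as chaser or recipient) are counted.
    """
    if masks is None:
        if chamber_shape is None:
            chamber_shape = DEFAULT_CHAMBER_SHAPE
        masks = [
            render_fly(p.position, p.heading_rad, p.shape, chamber_shape)
            for p in poses
        ]
    else:
        chamber_shape = masks[0].shape if masks else DEFAULT_CHAMBER_SHAPE
    in_chain: set[int] = set()
    for i, p in enumerate(poses):
        fan = _rasterize_fan(p.H, p.T, params, chamber_shape)
        for j in range(len(poses)):
            if j == i:
                continue
            if np.logical_and(fan, masks[j]).any():
                in_chain.add(i)
                in_chain.add(j)
    return len(in_chain)


# ---------------------------------------------------------------------------
# scripted scenarios


def scenario_idle(
    n_flies: int = 6,
    n_frames: int = 10,
    chamber_shape: tuple[int, int] = DEFAULT_CHAMBER_SHAPE,
    shape: FlyShape = FlyShape(),
) -> SceneSpec:
    """Well-separated stationary flies: true chain index 0 everywhere."""
    h, w = chamber_shape
    margin = shape.length
    xs = np.linspace(margin, w - margin, n_flies)
    poses = [
        TruePose(position=(h / 2.0, x), heading_rad=math.pi / 2.0, shape=shape)
        for x in xs
    ]
    return SceneSpec(trajectory=[list(poses) for _ in range(n_frames)],
                     chamber_shape=chamber_shape)


def scenario_dispersed(
    n_flies: int = 6,
    n_frames: int = 10,
    seed: int = 0,
    chamber_shape: tuple[int, int] = DEFAULT_CHAMBER_SHAPE,
    shape: FlyShape = FlyShape(),
    min_gap: float | None = None,
) -> SceneSpec:
    """Random walks with rejection sampling keeping silhouettes apart."""
    rng = np.random.default_rng(seed)
    h, w = chamber_shape
    margin = shape.length / 2.0 + 2
    if min_gap is None:
        min_gap = shape.length + 4
    frames = []
    positions = _sample_separated(rng, n_flies, h, w, margin, min_gap)
    headings = rng.uniform(0, 2 * math.pi, size=n_flies)
    for _ in range(n_frames):
        frames.append(
            [
                TruePose(position=positions[i].copy(), heading_rad=headings[i], shape=shape)
                for i in range(n_flies)
            ]
        )
        # random walk (~8 px/s, a walking fly at 0.12 mm/px), re-rejecting collisions
        for i in range(n_flies):
            for _attempt in range(20):
                cand = positions[i] + rng.normal(0, 8, size=2)
                cand[0] = np.clip(cand[0], margin, h - margin)
                cand[1] = np.clip(cand[1], margin, w - margin)
                others = np.delete(positions, i, axis=0)
                if len(others) == 0 or np.linalg.norm(others - cand, axis=1).min() >= min_gap:
                    positions[i] = cand
                    break
            headings[i] += rng.normal(0, 0.3)
    return SceneSpec(trajectory=frames, chamber_shape=chamber_shape, seed=seed)


def _sample_separated(rng, n, h, w, margin, min_gap):
    pts: list[np.ndarray] = []
    for _ in range(10000):
        cand = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        if all(np.linalg.norm(cand - p) >= min_gap for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.asarray(pts)
    raise RuntimeError("could not place flies with the requested separation")


def scenario_chain_train(
    n_train: int = 3,
    n_flies: int | None = None,
    n_frames: int = 10,
    gap: float = 10.0,
    chamber_shape: tuple[int, int] = DEFAULT_CHAMBER_SHAPE,
    shape: FlyShape = FlyShape(),
) -> SceneSpec:
    """A head-to-tail train of ``n_train`` flies walking along the chamber,
    with any remaining flies parked far away.  While the train holds, the
    true chain index equals ``n_train``.

    ``gap`` is the head-to-tail-tip distance between successive flies; the
    default 10 px puts each follower's head well inside chasing range of the
    fly ahead.
    """
    if n_flies is None:
        n_flies = n_train
    if n_flies < n_train:
        raise ValueError("n_flies must be >= n_train")
    h, w = chamber_shape
    row = h / 2.0
    pitch = shape.length + gap
    frames = []
    for f in range(n_frames):
        lead_col = shape.length + 5 + n_train * pitch + f  # train creeps forward
        poses = []
        for i in range(n_train):
            col = lead_col - i * pitch
            # heading 0 points along +col: each follower faces the fly ahead
            poses.append(TruePose(position=(row, col), heading_rad=0.0, shape=shape))
        # park extras in the far corner, spaced out and out of range
        for i in range(n_flies - n_train):
            poses.append(
                TruePose(
                    position=(h * 0.25, w - shape.length - 5 - i * (shape.length + 25)),
                    heading_rad=-math.pi / 2.0,
                    shape=shape,
                )
            )
        frames.append(poses)
    return SceneSpec(trajectory=frames, chamber_shape=chamber_shape)
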