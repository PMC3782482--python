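"""Fly segmentation and pose estimation from background-subtracted frames.

Each fly appears as a dark silhouette on the backlit background.  The
difference image ``background - frame`` (clipped at zero) is binarized with
Otsu's method; connected components in a plausible area range become fly
silhouettes.  Pose follows from image moments: the centroid is the pixel mean
and the body axis is the principal eigenvector of the pixel-coordinate
covariance matrix, with axis lengths ``4*sqrt(eigenvalue)`` (the full axes of
the uniform solid ellipse with the same second moments).

The major axis is unoriented, so head and tail are disambiguated with the
Harris & Stephens corner response on the lightly smoothed silhouette: the
abdominal tip of a fly is sharper than the head, so the axis endpoint with
the stronger corner response is the tail.  When the two responses are nearly
equal and a previous-frame pose is available, the assignment minimizing the
angular change is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import corner_harris
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label

__all__ = [
    "Silhouette",
    "FlyPose",
    "segment_flies",
    "split_merged",
    "fit_body_ellipse",
    "assign_head_tail",
    "link_poses",
    "DEFAULT_MIN_AREA",
]

# Single fly ~19 px long, ~8 px wide at 0.12 mm/px -> area of order 120 px^2.
# Anything below DEFAULT_MIN_AREA is debris / reflections.
DEFAULT_MIN_AREA = 40.0


class ShapeError(ValueError):
    """Silhouette too small or ill-conditioned for a pose fit."""


class ParameterError(ValueError):
    pass


@dataclass
class Silhouette:
    """Connected cluster of foreground pixels attributed to one (or more) flies.

    ``pixels`` is an (N, 2) array of (row, col) coordinates.  ``merged`` marks
    blobs larger than the plausible single-fly maximum, i.e. touching flies.
    """

    pixels: np.ndarray
    chamber_id: int = 0
    frame_index: int = 0
    merged: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)

    @property
    def area(self) -> int:
        return len(self.pixels)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class FlyPose:
    """Fitted body geometry of one fly in one frame.

    ``centroid``/``H``/``T`` are (row, col) points; ``orientation`` is the
    unoriented major-axis angle in radians measured from the +col axis toward
    +row (i.e. ``atan2(d_row, d_col)`` of the axis direction), reduced
    modulo pi.  ``H`` (head) and ``T`` (tail/abdominal tip) lie on the major
    axis.  ``degenerate`` flags near-circular blobs whose axis is unstable;
    ``ht_unreliable`` flags frames where head and tail could not be told
    apart.
    """

    centroid: np.ndarray
    major_axis_len: float
    minor_axis_len: float
    orientation: float
    H: np.ndarray | None = None
    T: np.ndarray | None = None
    degenerate: bool = False
    ht_unreliable: bool = False

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.H is not None:
            self.H = np.asarray(self.H, dtype=float)
        if self.T is not None:
            self.T = np.asarray(self.T, dtype=float)

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit vector along the (unoriented) major axis, (row, col)."""
        return np.array([math.sin(self.orientation), math.cos(self.orientation)])

    @property
    def heading(self) -> np.ndarray | None:
        """Unit vector from tail to head, or None before H/T assignment."""
        if self.H is None or self.T is None:
            return None
        d = self.H - self.T
        n = np.linalg.norm(d)
        return d / n if n > 0 else None


def segment_flies(
    frame: np.ndarray,
    background: np.ndarray,
    chamber_id: int = 0,
    frame_index: int = 0,
    min_area: float = DEFAULT_MIN_AREA,
    max_area: float | None = None,
) -> list[Silhouette]:
    """Extract fly silhouettes from one chamber frame.

    The difference image ``background - frame`` (flies are dark, so the
    difference is positive at flies) is thresholded with Otsu's method and
    8-connected components within ``[min_area, max_area]`` are returned.
    Components above ``max_area`` are returned flagged ``merged`` for
    downstream splitting.  ``max_area=None`` derives the bound as 1.6x the
    median component area: a blob of two touching flies is close to twice a
    single fly's area even with substantial overlap, so the threshold must
    sit strictly between one and two body areas.

    An effectively uniform difference image (empty chamber) yields an empty
    list, not an error.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ParameterError("frame and background must share a shape")
    diff = np.clip(background - frame, 0, None)
    if diff.max() - diff.min() < 1e-9:
        return []
    thresh = threshold_otsu(diff)
    binary = diff > thresh
    # Otsu on a near-empty chamber splits noise; demand real contrast.
    if diff[binary].size == 0 or diff[binary].mean() < 0.1 * diff.max():
        return []
    labels, n = label(binary, connectivity=2, return_num=True)
    if n == 0:
        return []
    areas = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    if max_area is None:
        plausible = areas[areas >= min_area]
        med = np.median(plausible) if plausible.size else np.inf
        max_area = 1.6 * med
    out: list[Silhouette] = []
    for lab_id, area in zip(range(1, n + 1), areas):
        if area < min_area:
            continue
        coords = np.argwhere(labels == lab_id)
        out.append(
            Silhouette(
                pixels=coords,
                chamber_id=chamber_id,
                frame_index=frame_index,
                merged=area > max_area,
            )
        )
    return out


def split_merged(blob: Silhouette, expected: int, seed: int = 0) -> list[Silhouette]:
    """Partition a merged blob into ``expected`` silhouettes.

    Touching flies produce one connected component; their pixels are split by
    k-means clustering on pixel coordinates.  The union of the parts equals
    the blob, and each part inherits the blob's frame/chamber tags.
    """
    if expected < 2:
        raise ParameterError("expected must be >= 2 to split a merged blob")
    from scipy.cluster.vq import kmeans2

    pts = blob.pixels.astype(float)
    # deterministic seeding keeps repeated runs identical
    _, assignment = kmeans2(pts, expected, minit="++", seed=seed)
    parts = []
    for c in range(expected):
        sel = blob.pixels[assignment == c]
        if len(sel) == 0:
            continue
        parts.append(
            Silhouette(
                pixels=sel,
                chamber_id=blob.chamber_id,
                frame_index=blob.frame_index,
                merged=False,
            )
        )
    return parts


# eigenvalue ratio below which the blob is treated as circular (no stable axis)
DEGENERATE_EIGRATIO = 1.2


def fit_body_ellipse(s: Silhouette) -> FlyPose:
    """Fit an equivalent uniform ellipse to a silhouette via image moments.

    Centroid = mean pixel coordinate; orientation = direction of the principal
    eigenvector of the pixel-coordinate covariance matrix; full axis lengths =
    ``4*sqrt(eigenvalue)``, which for a uniform solid ellipse recovers the
    true axes.  Blobs whose eigenvalue ratio is below 1.2 are flagged
    degenerate (near-circular, axis direction unstable).
    """
    if s.area < 3:
        raise ShapeError(f"need >= 3 pixels to fit an ellipse, got {s.area}")
    pts = s.pixels.astype(float)
    centroid = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    v = evecs[:, 1]  # principal axis, (row, col)
    orientation = math.atan2(v[0], v[1]) % math.pi
    degenerate = lam_minor > 0 and lam_major / max(lam_minor, 1e-12) < DEGENERATE_EIGRATIO
    return FlyPose(
        centroid=centroid,
        major_axis_len=4.0 * math.sqrt(lam_major),
        minor_axis_len=4.0 * math.sqrt(lam_minor),
        orientation=orientation,
        degenerate=degenerate,
    )


def _axis_endpoints(pose: FlyPose) -> tuple[np.ndarray, np.ndarray]:
    half = pose.major_axis_len / 2.0
    u = pose.axis_unit
    return pose.centroid + half * u, pose.centroid - half * u


def _max_response_near(resp: np.ndarray, point: np.ndarray, radius: float = 3.0) -> float:
    r0 = max(int(math.floor(point[0] - radius)), 0)
    r1 = min(int(math.ceil(point[0] + radius)) + 1, resp.shape[0])
    c0 = max(int(math.floor(point[1] - radius)), 0)
    c1 = min(int(math.ceil(point[1] + radius)) + 1, resp.shape[1])
    if r0 >= r1 or c0 >= c1:
        return -np.inf
    window = resp[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    within = (rr - point[0]) ** 2 + (cc - point[1]) ** 2 <= radius**2
    if not within.any():
        return -np.inf
    return float(window[within].max())


# relative response gap below which the corner rule is considered ambiguous
HT_TIE_FRACTION = 0.10
# Harris smoothing: sigma 1 px at silhouette scale, evaluated on a 3x
# supersampled grid (so sigma 3 in supersampled pixels).  Supersampling
# suppresses the aliasing of the few-pixel-wide abdominal tip that would
# otherwise dominate the corner response.
HARRIS_SIGMA = 1.0
HARRIS_UPSAMPLE = 3


def _harris_endpoint_responses(
    s: Silhouette, e1: np.ndarray, e2: np.ndarray, radius: float = 3.0
) -> tuple[float, float]:
    """Max Harris corner response near each axis endpoint.

    The binary silhouette is cropped, block-replicated ``HARRIS_UPSAMPLE``-
    fold, Gaussian-smoothed at sigma ``HARRIS_SIGMA`` (original-pixel units)
    and fed to the Harris detector; responses are read within ``radius``
    original pixels of each endpoint.
    """
    up = HARRIS_UPSAMPLE
    lo = s.pixels.min(axis=0) - 6
    hi = s.pixels.max(axis=0) + 7
    lo = np.maximum(lo, 0)
    sub = np.zeros(tuple(hi - lo), dtype=float)
    sub[s.pixels[:, 0] - lo[0], s.pixels[:, 1] - lo[1]] = 1.0
    big = np.kron(sub, np.ones((up, up)))
    smoothed = gaussian(big, sigma=HARRIS_SIGMA * up, preserve_range=True)
    resp = corner_harris(smoothed)

    def at(e: np.ndarray) -> float:
        ee = (np.asarray(e) - lo + 0.5) * up - 0.5
        return _max_response_near(resp, ee, radius * up)

    return at(e1), at(e2)


def assign_head_tail(
    s: Silhouette,
    pose: FlyPose,
    prev: FlyPose | None = None,
    shape: tuple[int, int] | None = None,
) -> FlyPose:
    """Resolve which major-axis endpoint is the head.

    The Harris corner response is computed on the Gaussian-smoothed (sigma
    1 px) binary silhouette; the endpoint with the larger maximal response
    within a 3-px radius is the tail (the abdominal tip is sharper than the
    head).  If the two responses differ by less than 10% and ``prev`` is
    given, the assignment that minimizes the angular change from the previous
    heading wins; with no ``prev`` the corner rule decides regardless.

    A degenerate pose with no previous pose cannot be oriented: H/T are set
    along the (arbitrary) axis and flagged unreliable so chain-region
    construction skips this fly-frame.
    """
    if shape is None:
        shape = tuple(s.pixels.max(axis=0) + 5)
    if pose.degenerate and prev is None:
        e1, e2 = _axis_endpoints(pose)
        pose.H, pose.T = e1, e2
        pose.ht_unreliable = True
        return pose

    e1, e2 = _axis_endpoints(pose)
    r1, r2 = _harris_endpoint_responses(s, e1, e2)

    scale = max(abs(r1), abs(r2), 1e-12)
    ambiguous = abs(r1 - r2) < HT_TIE_FRACTION * scale
    if (ambiguous or pose.degenerate) and prev is not None and prev.heading is not None:
        h = prev.heading
        # keep the endpoint whose direction from centroid best matches prev heading
        d1 = (e1 - pose.centroid) @ h
        pose.H, pose.T = (e1, e2) if d1 >= 0 else (e2, e1)
        return pose
    if r1 > r2:
        pose.T, pose.H = e1, e2
    else:
        pose.T, pose.H = e2, e1
    return pose


def link_poses(
    prev_poses: list[FlyPose], centroids: np.ndarray
) -> list[FlyPose | None]:
    """Match current detections to previous-frame poses by nearest centroid.

    Greedy assignment on pairwise distance; used only to supply the
    previous-frame pose for the head/tail tie-break, not for long-range
    identity tracking.  Returns, for each current centroid, the matched
    previous pose or None.
    """
    if not prev_poses or len(centroids) == 0:
        return [None] * len(centroids)
    prev_c = np.stack([p.centroid for p in prev_poses])
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    dists = np.linalg.norm(centroids[:, None, :] - prev_c[None, :, :], axis=2)
    matches: list[FlyPose | None] = [None] * len(centroids)
    used: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
    assigned: set[int] = set()
    for ci, pi in order:
        if ci in assigned or pi in used:
            continue
        matches[ci] = prev_poses[pi]
        assigned.add(int(ci))
        used.add(int(pi))
    return matches
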