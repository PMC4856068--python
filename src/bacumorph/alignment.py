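"""Rigid alignment of bone point clouds to a canonical anatomical frame.

The bone is placed so that its proximal end sits at the origin, its long
axis runs along +z, the broad axis of a reference cross-section runs along
x, and the dorsal direction is +y.  The transform is built in three steps:

1. the two points furthest apart define a provisional proximal-distal axis;
2. the centroids of the convex hulls of the 10% most proximal and 10% most
   distal point slabs refine that axis (proximal centroid -> origin, distal
   centroid -> +z);
3. the minimum bounding rectangle (MBR) of a thin cross-sectional band at
   15.00-15.25% of the length fixes the x-axis (long side of the MBR), and
   the bone's slight dorsal curvature near the distal end disambiguates the
   dorsal-ventral direction.

All transforms are proper rotations plus translations; reflections are never
used, since the bone is chiral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .config import PipelineConfig
from .pointcloud import DegenerateInputError, PointCloud

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-9


class AlignmentError(RuntimeError):
    """Raised when an alignment stage fails; names the offending stage."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``first`` then ``self``."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (for audit logs)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class AlignedCloud:
    """A point cloud expressed in the canonical frame."""

    points: np.ndarray
    transform: RigidTransform
    z_length: float
    dv_flipped: bool = False
    specimen_id: str = "specimen"
    meta: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * (K @ K)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def _rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def diameter_pair(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two points furthest apart (the diameter of the cloud).

    Computed on the convex hull; ties are broken by lexicographic order of
    the (sorted) pair coordinates so the result is deterministic.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise DegenerateInputError("diameter_pair needs at least 2 points")
    if np.allclose(points, points[0]):
        raise DegenerateInputError("all points identical; diameter undefined")
    try:
        hull_pts = points[ConvexHull(points).vertices]
    except QhullError:
        # flat or near-degenerate cloud: fall back to all input points
        hull_pts = np.unique(points, axis=0)
    d2 = np.sum((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1)
    best = np.max(d2)
    ii, jj = np.where(np.isclose(d2, best, rtol=0, atol=best * 1e-15))
    # order each candidate pair lexicographically, then pick the smallest pair
    pairs = []
    for i, j in zip(ii, jj):
        if i == j:
            continue
        a, b = hull_pts[i], hull_pts[j]
        if tuple(b) < tuple(a):
            a, b = b, a
        pairs.append((tuple(a), tuple(b)))
    a, b = min(pairs)
    return np.array(a), np.array(b)


def hull_centroid(points: np.ndarray, mode: str = "volume") -> np.ndarray:
    """Centroid of the convex hull of a 3D point set.

    mode='volume' returns the volume-weighted centroid of the hull
    polyhedron via tetrahedral decomposition (robust to uneven point
    density); mode='vertices' returns the plain mean of hull vertices.
    Coplanar input falls back to the mean of all points with a warning.
    """
    points = np.asarray(points, dtype=float)
    try:
        hull = ConvexHull(points)
    except QhullError:
        warnings.warn(
            "end slab is (near-)coplanar; using plain centroid", stacklevel=2
        )
        return points.mean(axis=0)
    if mode == "vertices":
        return points[hull.vertices].mean(axis=0)
    # tetrahedra from an interior reference point to each hull facet
    ref = points[hull.vertices].mean(axis=0)
    total_vol = 0.0
    centroid = np.zeros(3)
    for simplex in hull.simplices:
        a, b, c = points[simplex]
        vol = abs(np.dot(a - ref, np.cross(b - ref, c - ref))) / 6.0
        centroid += vol * (a + b + c + ref) / 4.0
        total_vol += vol
    if total_vol <= 0:
        return points[hull.vertices].mean(axis=0)
    return centroid / total_vol


def _z_slab(points: np.ndarray, lo_frac: float, hi_frac: float) -> np.ndarray:
    """Points whose z lies in [lo, hi) fractions of the z-extent (half-open)."""
    z = points[:, 2]
    zmin, zmax = z.min(), z.max()
    length = zmax - zmin
    lo = zmin + lo_frac * length
    hi = zmin + hi_frac * length
    mask = (z >= lo) & (z < hi)
    if hi_frac >= 1.0:  # make the top slab inclusive of the extreme point
        mask |= np.isclose(z, zmax)
    return points[mask]


def mbr_2d(points2d: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area bounding rectangle of a 2D point set.

    Uses rotating calipers over convex-hull edges (the optimal rectangle has
    a side collinear with a hull edge).  Returns (angle, long_side,
    short_side) where ``angle`` is the orientation of the *long* side in
    radians, reduced to [0, pi).
    """
    pts = np.asarray(points2d, dtype=float)
    if len(pts) < 3:
        raise DegenerateInputError("mbr_2d needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateInputError(f"mbr_2d: collinear input ({exc})") from exc
    hp = pts[hull.vertices]
    edges = np.roll(hp, -1, axis=0) - hp
    angles = np.arctan2(edges[:, 1], edges[:, 0]) % np.pi
    angles = np.unique(angles)
    best = None
    for theta in angles:
        c, s = np.cos(-theta), np.sin(-theta)
        rot = hp @ np.array([[c, -s], [s, c]]).T
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        area = w * h
        if best is None or area < best[0] - 1e-15 * best[0]:
            if w >= h:
                best = (area, theta % np.pi, w, h)
            else:
                best = (area, (theta + np.pi / 2) % np.pi, h, w)
    _, angle, long_side, short_side = best
    return float(angle), float(long_side), float(short_side)


def end_centroid_registration(
    points: np.ndarray,
    end_frac: float = 0.10,
    hull_centroid_mode: str = "volume",
    proximal_end: str = "auto",
) -> RigidTransform:
    """Refine the provisional axis using end-slab hull centroids.

    The ``end_frac`` most proximal and most distal slabs (fractions of the
    provisional z-extent) are sliced out, the centroid of each slab's convex
    hull computed, and the rigid transform returned that maps the proximal
    centroid to the origin and the distal centroid onto the +z axis.

    With ``proximal_end='auto'`` the slab whose cross-section (projected on
    the provisional x-y plane) has the larger minimum-bounding-rectangle
    area is taken as proximal — the base of the bone is its broad end.
    """
    points = np.asarray(points, dtype=float)
    slab_lo = _z_slab(points, 0.0, end_frac)
    slab_hi = _z_slab(points, 1.0 - end_frac, 1.0)
    for name, slab in (("proximal", slab_lo), ("distal", slab_hi)):
        if len(slab) < 4:
            raise DegenerateInputError(
                f"{name} end slab has only {len(slab)} points"
            )
    c_lo = hull_centroid(slab_lo, hull_centroid_mode)
    c_hi = hull_centroid(slab_hi, hull_centroid_mode)
    if proximal_end == "auto":
        def _area(slab: np.ndarray) -> float:
            try:
                _, w, h = mbr_2d(slab[:, :2])
                return w * h
            except DegenerateInputError:
                return 0.0
        prox, dist = (c_lo, c_hi) if _area(slab_lo) >= _area(slab_hi) else (c_hi, c_lo)
    elif proximal_end == "low":
        prox, dist = c_lo, c_hi
    else:
        prox, dist = c_hi, c_lo
    axis = dist - prox
    if np.linalg.norm(axis) < 1e-12:
        raise DegenerateInputError("end centroids coincide")
    R = _rotation_aligning(axis, np.array([0.0, 0.0, 1.0]))
    return RigidTransform(R, -R @ prox)


def _band_points(
    points: np.ndarray, lo_frac: float, hi_frac: float, max_doublings: int = 5
) -> np.ndarray:
    """Half-open fractional z-band with symmetric doubling if empty."""
    lo, hi = lo_frac, hi_frac
    for attempt in range(max_doublings + 1):
        band = _z_slab(points, max(lo, 0.0), min(hi, 1.0))
        if len(band):
            if attempt:
                warnings.warn(
                    f"z-band [{lo_frac:.4f}, {hi_frac:.4f}) empty; widened "
                    f"{attempt}x to [{lo:.4f}, {hi:.4f})",
                    stacklevel=3,
                )
            return band
        centre = 0.5 * (lo + hi)
        half = hi - lo  # double the thickness
        lo, hi = centre - half, centre + half
    raise AlignmentError(
        f"z-band [{lo_frac:.4f}, {hi_frac:.4f}) still empty after "
        f"{max_doublings} doublings"
    )


def mbr_orient(
    points: np.ndarray, band: tuple[float, float] = (0.1500, 0.1525)
) -> RigidTransform:
    """Rotation about z aligning the band's MBR long side with the x-axis."""
    slab = _band_points(points, band[0], band[1])
    if len(slab) < 3:
        # widen further until the rectangle is defined
        width = band[1] - band[0]
        lo, hi = band
        for _ in range(5):
            centre = 0.5 * (lo + hi)
            width *= 2
            lo, hi = centre - width / 2, centre + width / 2
            slab = _z_slab(points, max(lo, 0.0), min(hi, 1.0))
            if len(slab) >= 3:
                break
        else:
            raise AlignmentError("MBR band has fewer than 3 points")
    angle, _, _ = mbr_2d(slab[:, :2])
    return RigidTransform(_rot_z(-angle), np.zeros(3))


def resolve_dorsoventral(
    points: np.ndarray, distal_frac: float = 0.25
) -> tuple[RigidTransform, bool]:
    """Fix the dorsal-ventral direction using the bone's distal curvature.

    If the mean y of the most-distal ``distal_frac`` of points is negative,
    the cloud is rotated by pi about the z-axis (a proper rotation flipping
    both x and y, preserving chirality and the proximal-distal convention)
    so that the dorsal bow points to +y.  Returns (transform, flipped).
    """
    points = np.asarray(points, dtype=float)
    distal = _z_slab(points, 1.0 - distal_frac, 1.0)
    mean_y = float(distal[:, 1].mean())
    # ambiguity threshold: numerically zero, or statistically indistinguishable
    # from zero given the sampling noise of the distal points
    scale = max(float(np.abs(points).max()), 1.0)
    sem = float(distal[:, 1].std(ddof=1) / np.sqrt(len(distal))) if len(distal) > 1 else 0.0
    if abs(mean_y) < max(1e-12 * scale, 2.0 * sem):
        warnings.warn(
            "dorsal-ventral orientation is ambiguous (no measurable distal "
            "curvature); no flip applied",
            stacklevel=2,
        )
        return RigidTransform.identity(), False
    if mean_y < 0:
        return RigidTransform(_rot_z(np.pi), np.zeros(3)), True
    return RigidTransform.identity(), False


def align(cloud: PointCloud, config: PipelineConfig | None = None) -> AlignedCloud:
    """Compose the full three-step alignment into the canonical frame."""
    config = config or PipelineConfig()
    pts = np.asarray(cloud.points, dtype=float)
    if len(pts) < 4:
        raise DegenerateInputError("align requires at least 4 points")
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            p1, p2 = diameter_pair(pts)
            axis = p2 - p1
            R1 = _rotation_aligning(axis, np.array([0.0, 0.0, 1.0]))
            t1 = RigidTransform(R1, -R1 @ p1)
            pts1 = t1.apply(pts)
        except Exception as exc:
            raise AlignmentError(
                f"stage 'diameter axis' failed for {cloud.specimen_id}: {exc}"
            ) from exc
        try:
            t2 = end_centroid_registration(
                pts1,
                end_frac=config.end_frac,
                hull_centroid_mode=config.hull_centroid_mode,
                proximal_end=config.proximal_end,
            )
            pts2 = t2.apply(pts1)
        except Exception as exc:
            raise AlignmentError(
                f"stage 'end-centroid registration' failed for "
                f"{cloud.specimen_id}: {exc}"
            ) from exc
        try:
            t3 = mbr_orient(pts2, band=config.mbr_band)
            pts3 = t3.apply(pts2)
        except Exception as exc:
            raise AlignmentError(
                f"stage 'MBR orientation' failed for {cloud.specimen_id}: {exc}"
            ) from exc
        try:
            t4, flipped = resolve_dorsoventral(pts3)
            pts4 = t4.apply(pts3)
        except Exception as exc:
            raise AlignmentError(
                f"stage 'dorsoventral resolution' failed for "
                f"{cloud.specimen_id}: {exc}"
            ) from exc
        caught = [str(w.message) for w in wlist]
    for msg in caught:
        logger.warning("%s: %s", cloud.specimen_id, msg)
        warnings.warn(f"{cloud.specimen_id}: {msg}", stacklevel=2)
    transform = t4.compose(t3.compose(t2.compose(t1)))
    z = pts4[:, 2]
    return AlignedCloud(
        points=pts4,
        transform=transform,
        z_length=float(z.max() - z.min()),
        dv_flipped=flipped,
        specimen_id=cloud.specimen_id,
        meta=dict(cloud.meta),
        warnings=caught,
    )
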