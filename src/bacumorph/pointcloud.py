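"""Point-cloud containers and I/O.

A segmented bone is represented as a plain set of x-y-z points in physical
units (voxel index times voxel size).  Micro-CT stacks are segmented by
thresholding and 26-connected component labelling; interior voxels are kept,
since the bone's internal (medullary) structure is informative downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: default micro-CT voxel edge length, in micrometres
DEFAULT_VOXEL_SIZE_UM = 15.5


class DegenerateInputError(ValueError):
    """Raised when a point set is too small or too flat to process."""


class XYZParseError(ValueError):
    """Raised when an xyz text file contains a malformed row."""


@dataclass
class PointCloud:
    """Raw bone points in scanner coordinates.

    Parameters
    ----------
    points : (n, 3) float array
        x-y-z coordinates in physical units.
    voxel_size : float
        Edge length of one voxel in the same units as ``points``.
    specimen_id : str
        Nonempty identifier.
    meta : dict
        Free-form metadata (strain, lab, replicate id, ...).
    """

    points: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM
    specimen_id: str = "specimen"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if not self.specimen_id:
            raise ValueError("specimen_id must be nonempty")

    def __len__(self) -> int:
        return len(self.points)


def _require_noncoplanar(points: np.ndarray, what: str = "point cloud") -> None:
    if len(points) < 4:
        raise DegenerateInputError(
            f"{what} has {len(points)} points; at least 4 non-coplanar "
            "points are required"
        )


def read_xyz(
    path: str | Path,
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM,
    scale_by_voxel_size: bool = False,
    specimen_id: str | None = None,
) -> PointCloud:
    """Read a whitespace/comma-delimited three-column xyz text file.

    Lines starting with ``#`` and blank lines are ignored.  Row order is
    preserved.  With ``scale_by_voxel_size`` the file is interpreted as voxel
    indices and multiplied by ``voxel_size``.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) != 3:
                raise XYZParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise XYZParseError(f"{path}:{lineno}: {exc}") from exc
    points = np.asarray(rows, dtype=float).reshape(-1, 3)
    _require_noncoplanar(points, f"file {path}")
    if scale_by_voxel_size:
        points = points * voxel_size
    return PointCloud(
        points=points,
        voxel_size=voxel_size,
        specimen_id=specimen_id or path.stem,
    )


def write_xyz(cloud: PointCloud, path: str | Path) -> None:
    """Write a cloud as three-column text, round-trippable bit-exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# specimen_id: {cloud.specimen_id}\n")
        for x, y, z in cloud.points:
            # repr of a Python float round-trips bit-exactly
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def segment_stack(
    stack: np.ndarray,
    threshold: float,
    min_voxels: int = 1,
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM,
    specimen_prefix: str = "component",
) -> list[PointCloud]:
    """Segment bones out of a grayscale voxel stack.

    Voxels with intensity >= ``threshold`` are grouped into 26-connected
    components; components with at least ``min_voxels`` voxels are returned
    as point clouds (interior voxels included), sorted by size descending.
    Voxel index (i, j, k) maps to physical coordinate (i, j, k) *
    ``voxel_size`` with 0-based indices.
    """
    from scipy import ndimage

    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("stack must be a nonempty 3D array")
    mask = stack >= threshold
    # 26-neighbourhood: full 3x3x3 structuring element
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_components = ndimage.label(mask, structure=structure)
    clouds: list[PointCloud] = []
    if n_components:
        counts = np.bincount(labels.ravel())[1:]
        order = np.argsort(-counts, kind="stable")
        for rank, comp_idx in enumerate(order):
            if counts[comp_idx] < min_voxels:
                continue
            ijk = np.argwhere(labels == comp_idx + 1)
            clouds.append(
                PointCloud(
                    points=ijk.astype(float) * voxel_size,
                    voxel_size=voxel_size,
                    specimen_id=f"{specimen_prefix}_{rank}",
                    meta={"n_voxels": int(counts[comp_idx])},
                )
            )
    if not clouds:
        msg = f"no connected component reached min_voxels={min_voxels}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return clouds
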