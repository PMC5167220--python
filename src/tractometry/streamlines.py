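"""Streamline geometry: resampling, orientation, distances, file I/O.

A streamline is an ordered polyline of 3D points in world coordinates
(mm, RAS+).  Point-wise correspondence across subjects requires every
fiber to be resampled to the same number of equidistant points and
oriented consistently against an atlas prototype.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "as_streamline",
    "arc_length",
    "resample_polyline",
    "orient_fiber",
    "hausdorff_distance",
    "directed_hausdorff_distance",
    "mean_closest_point_distance",
    "bundle_distance",
    "load_streamlines",
    "save_streamlines",
]

DISTANCE_VARIANTS = ("symmetric", "directed", "mean-closest-point")


def as_streamline(points: Sequence) -> np.ndarray:
    """Validate and return a streamline as an (n, 3) float array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (n, 3), got {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline has non-finite coordinates")
    if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
        raise ValueError("consecutive duplicate points in streamline")
    return pts


def arc_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample_polyline(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a polyline to ``k`` points equidistant in arc length.

    Endpoints are preserved exactly; interior points are linear
    interpolations along the original polyline.
    """
    pts = as_streamline(points)
    if k < 2:
        raise ValueError("k must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero-length polyline cannot be resampled")
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, 3))
    for dim in range(3):
        out[:, dim] = np.interp(targets, cum, pts[:, dim])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def orient_fiber(fiber: np.ndarray, prototype: np.ndarray) -> np.ndarray:
    """Return ``fiber`` or its reversal, whichever matches the prototype.

    The match score is the mean point-to-point distance at corresponding
    indices; both inputs must be resampled to the same number of points.
    Ties keep the original order.
    """
    f = np.asarray(fiber, dtype=float)
    p = np.asarray(prototype, dtype=float)
    if f.shape != p.shape:
        raise ValueError("fiber and prototype must share shape (same K)")
    forward = np.linalg.norm(f - p, axis=1).mean()
    backward = np.linalg.norm(f[::-1] - p, axis=1).mean()
    return f[::-1].copy() if backward < forward else f


def directed_hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """max over points of ``a`` of the distance to the nearest point of ``b``."""
    d = cdist(np.atleast_2d(a), np.atleast_2d(b))
    return float(d.min(axis=1).max())


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (mm).

    Zero iff the point sets coincide; symmetric in its arguments.
    """
    d = cdist(np.atleast_2d(a), np.atleast_2d(b))
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def mean_closest_point_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetrized mean of closest-point distances, a softer bundle metric."""
    d = cdist(np.atleast_2d(a), np.atleast_2d(b))
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


def bundle_distance(a: np.ndarray, b: np.ndarray, variant: str = "symmetric") -> float:
    """Streamline-to-streamline distance under the configured variant."""
    if variant == "symmetric":
        return hausdorff_distance(a, b)
    if variant == "directed":
        return directed_hausdorff_distance(a, b)
    if variant == "mean-closest-point":
        return mean_closest_point_distance(a, b)
    raise ValueError(f"unknown distance variant {variant!r}; use one of {DISTANCE_VARIANTS}")


def load_streamlines(path: str | Path) -> list[np.ndarray]:
    """Read a TRK or TCK file and return streamlines in world space (mm).

    nibabel's streamline API already maps TRK's voxel-corner origin into
    RAS+ mm, so both formats come back in a common space.
    """
    import nibabel as nib

    tractogram = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tractogram.streamlines]


def save_streamlines(
    streamlines: Iterable[np.ndarray], path: str | Path,
    affine_to_rasmm: np.ndarray | None = None,
) -> None:
    """Write streamlines (world-space mm) to TRK or TCK by file extension."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram

    path = Path(path)
    sl = [np.asarray(s, dtype=np.float32) for s in streamlines]
    tractogram = Tractogram(sl, affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        header = nib.streamlines.TrkFile.create_empty_header()
        if affine_to_rasmm is not None:
            header["voxel_to_rasmm"] = affine_to_rasmm
        nib.streamlines.save(tractogram, str(path), header=header)
    elif path.suffix == ".tck":
        nib.streamlines.save(tractogram, str(path))
    else:
        raise ValueError(f"unsupported streamline format {path.suffix!r} (use .trk or .tck)")
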