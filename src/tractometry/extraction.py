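"""Multi-atlas bundle extraction and along-tract profile construction.

Candidate fibers from a subject are matched to named bundle templates by
streamline-to-streamline distance (symmetric Hausdorff by default).
Decisions from multiple atlas subjects are fused — by default a candidate
belongs to a bundle if it is within the acceptance threshold of *any*
atlas's prototypes (union fusion), recording the minimal distance and the
atlas that achieved it.  Matched fibers are orientation-harmonized
against their nearest prototype so that point index ``i`` corresponds
across subjects.

Where a subject has no matched fiber for an atlas fiber slot, scalar
values are sampled from the subject's registered metric maps at the
prototype's own point locations (map fallback), so every profile is
complete: tract statistics never require complete fiber detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .registry import DEFAULT_K
from .streamlines import bundle_distance, orient_fiber, resample_polyline
from .tensor import METRICS

__all__ = [
    "AtlasBundle",
    "BundleAssignment",
    "SubjectTractProfile",
    "extract_bundle",
    "assign_bundles",
    "sample_map_at_points",
    "build_tract_profile",
]


@dataclass
class AtlasBundle:
    """A named bundle template from one atlas subject.

    All prototypes are resampled to the same K points; ``prototypes`` has
    shape (n_fibers, K, 3).
    """

    name: str
    prototypes: np.ndarray
    atlas_id: int = 0

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if self.prototypes.ndim != 3 or self.prototypes.shape[2] != 3:
            raise ValueError("prototypes must have shape (n_fibers, K, 3)")
        if self.prototypes.shape[0] == 0:
            raise ValueError(f"atlas bundle {self.name!r} has no prototypes")

    @property
    def n_fibers(self) -> int:
        return self.prototypes.shape[0]

    @property
    def k(self) -> int:
        return self.prototypes.shape[1]


@dataclass
class BundleAssignment:
    """Fibers assigned to one bundle, with their match provenance."""

    name: str
    member_indices: np.ndarray  # indices into the candidate list
    fibers: list[np.ndarray]  # resampled, orientation-harmonized
    distances: np.ndarray  # minimal distance to any prototype, mm
    source_atlas: np.ndarray  # atlas_id of the winning prototype
    nearest_prototype: np.ndarray  # prototype row index within that atlas

    @property
    def n_members(self) -> int:
        return len(self.fibers)


@dataclass
class SubjectTractProfile:
    """Per-bundle along-tract scalar values for one subject.

    ``values[bundle]`` has shape (n_slots, K, 4) in canonical metric
    order (FA, MD, RD, AX); ``fallback[bundle]`` is a boolean
    (n_slots, K) mask marking points sampled from the registered scalar
    maps rather than from a traced fiber.
    """

    subject_id: str
    values: dict[str, np.ndarray] = field(default_factory=dict)
    fallback: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for name, arr in self.values.items():
            if arr.ndim != 3 or arr.shape[2] != len(METRICS):
                raise ValueError(f"profile for {name!r} must be (n_slots, K, 4)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"profile for {name!r} contains non-finite values")


def _min_distance_to_atlases(
    fiber: np.ndarray, atlases: list[AtlasBundle], variant: str
) -> tuple[float, int, int]:
    """(min distance, atlas_id, prototype index) over all prototypes."""
    best = (np.inf, -1, -1)
    for atlas in atlases:
        for j, proto in enumerate(atlas.prototypes):
            d = bundle_distance(fiber, proto, variant)
            if d < best[0]:
                best = (d, atlas.atlas_id, j)
    return best


def extract_bundle(
    candidates: list[np.ndarray],
    atlases: list[AtlasBundle],
    threshold: float,
    variant: str = "symmetric",
    k: int = DEFAULT_K,
    fusion: str = "union",
) -> BundleAssignment:
    """Assign candidate fibers to one named bundle.

    A candidate joins the bundle when its minimal distance to any
    prototype is within ``threshold`` (``fusion="union"``), or when a
    majority of atlases each contain a prototype within the threshold
    (``fusion="majority"``).  Members are returned resampled to ``k``
    points and oriented against their nearest prototype.
    """
    if not atlases:
        raise ValueError("at least one atlas bundle is required")
    if threshold <= 0:
        raise ValueError("threshold must be positive (mm)")
    names = {a.name for a in atlases}
    if len(names) != 1:
        raise ValueError(f"atlases mix bundle names {sorted(names)}")
    if fusion not in ("union", "majority"):
        raise ValueError(f"unknown fusion rule {fusion!r}")
    name = atlases[0].name

    member_idx, fibers, dists, atlas_ids, proto_idx = [], [], [], [], []
    atlas_lookup = {a.atlas_id: a for a in atlases}
    for i, cand in enumerate(candidates):
        res = resample_polyline(cand, k) if np.asarray(cand).shape[0] != k else np.asarray(cand, float)
        d, aid, j = _min_distance_to_atlases(res, atlases, variant)
        if fusion == "union":
            accept = d <= threshold
        else:
            votes = sum(
                1
                for a in atlases
                if min(bundle_distance(res, p, variant) for p in a.prototypes) <= threshold
            )
            accept = votes > len(atlases) / 2
        if accept:
            proto = atlas_lookup[aid].prototypes[j]
            member_idx.append(i)
            fibers.append(orient_fiber(res, proto))
            dists.append(d)
            atlas_ids.append(aid)
            proto_idx.append(j)
    return BundleAssignment(
        name=name,
        member_indices=np.asarray(member_idx, dtype=int),
        fibers=fibers,
        distances=np.asarray(dists, dtype=float),
        source_atlas=np.asarray(atlas_ids, dtype=int),
        nearest_prototype=np.asarray(proto_idx, dtype=int),
    )


def assign_bundles(
    candidates: list[np.ndarray],
    atlas: dict[str, list[AtlasBundle]],
    threshold: float,
    bundle_order: list[str] | None = None,
    variant: str = "symmetric",
    k: int = DEFAULT_K,
    fusion: str = "union",
) -> dict[str, BundleAssignment]:
    """Assign every candidate to at most one bundle.

    A fiber within the threshold of several bundles goes to the bundle
    with the minimal distance; exact ties break by registry order.
    """
    order = bundle_order if bundle_order is not None else list(atlas.keys())
    per_bundle = {
        name: extract_bundle(candidates, atlas[name], threshold, variant, k, fusion)
        for name in order
    }
    # Resolve conflicts: keep each candidate only in its closest bundle.
    best: dict[int, tuple[float, int]] = {}  # candidate -> (distance, order position)
    for pos, name in enumerate(order):
        a = per_bundle[name]
        for idx, d in zip(a.member_indices, a.distances):
            cur = best.get(int(idx))
            if cur is None or (d, pos) < cur:
                best[int(idx)] = (d, pos)
    resolved = {}
    for pos, name in enumerate(order):
        a = per_bundle[name]
        keep = [
            m
            for m, idx in enumerate(a.member_indices)
            if best[int(idx)][1] == pos
        ]
        resolved[name] = BundleAssignment(
            name=name,
            member_indices=a.member_indices[keep],
            fibers=[a.fibers[m] for m in keep],
            distances=a.distances[keep],
            source_atlas=a.source_atlas[keep],
            nearest_prototype=a.nearest_prototype[keep],
        )
    return resolved


def sample_map_at_points(
    volume: np.ndarray, affine: np.ndarray, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of a 3D scalar map at world-space points.

    Returns ``(values, out_of_fov)``.  Points outside the field of view
    take the nearest in-volume voxel value and are flagged.
    """
    volume = np.asarray(volume, dtype=float)
    affine = np.asarray(affine, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    det = np.linalg.det(affine[:3, :3])
    if det == 0 or not np.isfinite(det):
        raise ValueError("affine is singular")
    inv = np.linalg.inv(affine)
    vox = (inv[:3, :3] @ pts.T + inv[:3, 3:4])  # (3, n) voxel coordinates
    upper = np.array(volume.shape, dtype=float)[:, None] - 1.0
    out_of_fov = np.any((vox < 0) | (vox > upper), axis=0)
    values = map_coordinates(volume, vox, order=1, mode="nearest")
    return values, out_of_fov


def build_tract_profile(
    subject_id: str,
    assignments: dict[str, BundleAssignment],
    metric_volumes: dict[str, tuple[np.ndarray, np.ndarray]],
    atlas: dict[str, list[AtlasBundle]],
) -> SubjectTractProfile:
    """Attach the four scalar metrics at every fiber slot and sample point.

    Fiber slots are the prototypes of the first atlas for each bundle.
    A slot filled by a matched subject fiber (the closest member whose
    nearest prototype is that slot) is sampled along the fiber; an
    unfilled slot falls back to sampling the subject's maps at the
    prototype's own points, with the fallback flag set.
    """
    missing = [m for m in METRICS if m not in metric_volumes]
    if missing:
        raise ValueError(f"missing metric volumes {missing}")
    shapes = {metric_volumes[m][0].shape for m in METRICS}
    affines = {tuple(np.asarray(metric_volumes[m][1]).ravel()) for m in METRICS}
    if len(shapes) != 1 or len(affines) != 1:
        raise ValueError("metric volumes must share grid shape and affine")

    profile = SubjectTractProfile(subject_id=subject_id)
    for name, atlases in atlas.items():
        slots = atlases[0].prototypes  # (n_slots, K, 3)
        n_slots, k, _ = slots.shape
        values = np.empty((n_slots, k, len(METRICS)))
        fallback = np.ones((n_slots, k), dtype=bool)
        # Pick, per slot, the closest member fiber mapped to that slot.
        slot_fiber: dict[int, np.ndarray] = {}
        slot_dist: dict[int, float] = {}
        assignment = assignments.get(name)
        if assignment is not None:
            for fiber, dist, aid, j in zip(
                assignment.fibers,
                assignment.distances,
                assignment.source_atlas,
                assignment.nearest_prototype,
            ):
                if aid != atlases[0].atlas_id:
                    # Re-anchor fibers matched via another atlas onto the
                    # slot-defining atlas.
                    d_all = np.linalg.norm(
                        slots - fiber[None, :, :], axis=2
                    ).mean(axis=1)
                    j = int(np.argmin(d_all))
                j = int(j)
                if j not in slot_dist or dist < slot_dist[j]:
                    slot_dist[j] = float(dist)
                    slot_fiber[j] = fiber
        for j in range(n_slots):
            pts = slot_fiber.get(j, slots[j])
            for mi, metric in enumerate(METRICS):
                vol, aff = metric_volumes[metric]
                values[j, :, mi], _ = sample_map_at_points(vol, aff, pts)
            fallback[j, :] = j not in slot_fiber
        profile.values[name] = values
        profile.fallback[name] = fallback
    profile.validate()
    return profile
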