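"""Parametric stenosed coronary vessel trees and their voxelized lumen masks.

A vessel tree is a collection of tapering tubular segments laid out along
polyline centerlines.  Each segment may carry focal stenoses that narrow the
lumen according to a smooth shape window.  Trees are rasterized to 3D binary
masks that emulate the lumen segmentation a CT angiography pipeline would
produce, so that downstream centerline extraction and flow simulation can be
exercised without any imaging data.

Coordinate conventions
----------------------
All world coordinates are in millimetres.  Voxel indices are 0-based with
axis order (x, y, z); ``origin`` is the world coordinate of the *center* of
voxel (0, 0, 0).  A voxel belongs to the lumen iff its center lies within the
local radius of the nearest centerline sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StenosisSpec",
    "SegmentSpec",
    "VesselTreeSpec",
    "VesselTree",
    "SampledSegment",
    "VoxelMask",
    "build_tree",
    "voxelize",
    "write_mask",
    "read_mask",
]

#: minimum reference lumen diameter (mm) allowed at a stenosis; mirrors the
#: usual CT-FFR inclusion criterion of a >= 2 mm reference vessel.
MIN_REFERENCE_DIAMETER_MM = 2.0


class GeometryError(ValueError):
    """Raised for invalid vessel-tree specifications."""


@dataclass(frozen=True)
class StenosisSpec:
    """Focal diameter narrowing on a segment.

    Parameters
    ----------
    center_arclength : float
        Arclength position of the throat along the parent segment, mm.
    length : float
        Lesion length, mm; the shape window is supported exactly on
        ``[center - length/2, center + length/2]``.
    diameter_reduction : float
        Diameter stenosis (DS) as a fraction in [0, 1); lumen diameter at
        the throat equals ``(1 - DS) * reference diameter``.
    shape : {"cosine", "gaussian"}
        Narrowing profile.  ``cosine`` is C1-smooth and reaches zero at the
        window edges; ``gaussian`` uses sigma = length / 6, truncated to the
        window.
    """

    center_arclength: float
    length: float
    diameter_reduction: float
    shape: str = "cosine"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GeometryError("stenosis length must be > 0")
        if not (0.0 <= self.diameter_reduction < 1.0):
            raise GeometryError("diameter_reduction must lie in [0, 1)")
        if self.shape not in ("cosine", "gaussian"):
            raise GeometryError(f"unknown stenosis shape {self.shape!r}")

    def window(self, s: np.ndarray) -> np.ndarray:
        """Shape window w(s) with max 1 at the throat and support on the lesion."""
        x = np.asarray(s, dtype=float) - self.center_arclength
        half = self.length / 2.0
        inside = np.abs(x) <= half
        if self.shape == "cosine":
            w = 0.5 * (1.0 + np.cos(np.pi * x / half))
        else:
            sigma = self.length / 6.0
            w = np.exp(-0.5 * (x / sigma) ** 2)
        return np.where(inside, w, 0.0)


@dataclass(frozen=True)
class SegmentSpec:
    """One tubular segment: a polyline centerline with a linear radius taper."""

    id: str
    control_points: tuple  # ((x,y,z), ...) in mm
    reference_radius_proximal: float
    reference_radius_distal: float
    parent_id: str | None = None
    stenoses: tuple = ()

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise GeometryError(f"segment {self.id!r}: need >= 2 3D control points")
        if self.reference_radius_proximal <= 0 or self.reference_radius_distal <= 0:
            raise GeometryError(f"segment {self.id!r}: radii must be > 0")

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.control_points, dtype=float)

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass(frozen=True)
class VesselTreeSpec:
    """A tree of segments with a single root (the inlet)."""

    segments: tuple
    inlet_segment_id: str
    label: str = "LAD"

    def __post_init__(self) -> None:
        if self.label not in ("LAD", "LCX", "RCA"):
            raise GeometryError(f"label must be LAD/LCX/RCA, got {self.label!r}")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise GeometryError("duplicate segment ids")
        if self.inlet_segment_id not in ids:
            raise GeometryError("inlet_segment_id not among segments")

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "coroflow/vessel-tree/1",
                "label": self.label,
                "inlet_segment_id": self.inlet_segment_id,
                "segments": [
                    {
                        "id": s.id,
                        "parent_id": s.parent_id,
                        "control_points": [list(p) for p in s.points],
                        "reference_radius_proximal": s.reference_radius_proximal,
                        "reference_radius_distal": s.reference_radius_distal,
                        "stenoses": [
                            {
                                "center_arclength": st.center_arclength,
                                "length": st.length,
                                "diameter_reduction": st.diameter_reduction,
                                "shape": st.shape,
                            }
                            for st in s.stenoses
                        ],
                    }
                    for s in self.segments
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "VesselTreeSpec":
        d = json.loads(text)
        segs = tuple(
            SegmentSpec(
                id=s["id"],
                parent_id=s.get("parent_id"),
                control_points=tuple(tuple(p) for p in s["control_points"]),
                reference_radius_proximal=s["reference_radius_proximal"],
                reference_radius_distal=s["reference_radius_distal"],
                stenoses=tuple(
                    StenosisSpec(
                        center_arclength=st["center_arclength"],
                        length=st["length"],
                        diameter_reduction=st["diameter_reduction"],
                        shape=st.get("shape", "cosine"),
                    )
                    for st in s.get("stenoses", ())
                ),
            )
            for s in d["segments"]
        )
        return cls(segments=segs, inlet_segment_id=d["inlet_segment_id"], label=d.get("label", "LAD"))


# ---------------------------------------------------------------------------
# Analytic tree


@dataclass
class SampledSegment:
    """Arclength-sampled centerline and radius of one segment."""

    spec: SegmentSpec
    s: np.ndarray        # arclength, mm, s[0] = 0
    points: np.ndarray   # (n, 3) mm
    radius: np.ndarray   # mm, stenosed
    taper: np.ndarray    # mm, reference (healthy) radius
    children: list = field(default_factory=list)

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def radius_at(self, s: float | np.ndarray) -> np.ndarray:
        return np.interp(s, self.s, self.radius)

    def reference_radius_at(self, s: float | np.ndarray) -> np.ndarray:
        return np.interp(s, self.s, self.taper)

    def point_at(self, s: float) -> np.ndarray:
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(s, self.s, self.points[:, k])
        return out


@dataclass
class VesselTree:
    """Analytic vessel tree: per-segment centerline curves and radius functions."""

    spec: VesselTreeSpec
    segments: dict          # id -> SampledSegment
    root_id: str

    @property
    def root(self) -> SampledSegment:
        return self.segments[self.root_id]

    def leaves(self) -> list:
        return [seg for seg in self.segments.values() if not seg.children]

    def min_radius(self) -> float:
        return min(float(seg.radius.min()) for seg in self.segments.values())

    def paths_from_root(self) -> list:
        """All root-to-leaf paths as lists of segment ids."""
        out: list = []

        def walk(seg_id: str, acc: list) -> None:
            acc = acc + [seg_id]
            kids = self.segments[seg_id].children
            if not kids:
                out.append(acc)
            for k in kids:
                walk(k, acc)

        walk(self.root_id, [])
        return out


def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arclength step; returns (s, points)."""
    deltas = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(deltas == 0):
        raise GeometryError("repeated control points")
    s_ctrl = np.concatenate([[0.0], np.cumsum(deltas)])
    total = s_ctrl[-1]
    n = max(int(np.ceil(total / step)) + 1, 5)
    s = np.linspace(0.0, total, n)
    pts = np.column_stack([np.interp(s, s_ctrl, points[:, k]) for k in range(3)])
    return s, pts


def build_tree(spec: VesselTreeSpec, sample_step: float | None = None) -> VesselTree:
    """Turn a :class:`VesselTreeSpec` into an arclength-sampled analytic tree.

    The per-segment radius is ``r(s) = taper(s) * (1 - DS * w(s))`` where
    ``taper`` interpolates linearly between the proximal and distal reference
    radii and ``w`` is the stenosis shape window (max 1 at the throat).

    Raises
    ------
    GeometryError
        For topology errors (cycles, multiple roots, detached children),
        overlapping stenoses, stenoses outside their segment, or a reference
        diameter below 2 mm at a lesion.
    """
    by_id = {s.id: s for s in spec.segments}
    roots = [s for s in spec.segments if s.parent_id is None]
    if len(roots) != 1:
        raise GeometryError(f"expected exactly one root segment, found {len(roots)}")
    if roots[0].id != spec.inlet_segment_id:
        raise GeometryError("inlet_segment_id must be the (single) root segment")
    for s in spec.segments:
        if s.parent_id is not None and s.parent_id not in by_id:
            raise GeometryError(f"segment {s.id!r} references unknown parent {s.parent_id!r}")
    # cycle check by walking up
    for s in spec.segments:
        seen = set()
        cur = s
        while cur.parent_id is not None:
            if cur.id in seen:
                raise GeometryError("cycle detected in segment topology")
            seen.add(cur.id)
            cur = by_id[cur.parent_id]

    sampled: dict[str, SampledSegment] = {}
    for s in spec.segments:
        L = s.length
        # validate stenoses
        intervals = []
        for st in s.stenoses:
            lo = st.center_arclength - st.length / 2.0
            hi = st.center_arclength + st.length / 2.0
            if lo < -1e-9 or hi > L + 1e-9:
                raise GeometryError(
                    f"segment {s.id!r}: stenosis at s={st.center_arclength} mm "
                    f"(length {st.length} mm) lies outside the segment (length {L:.3f} mm)"
                )
            intervals.append((lo, hi, st))
        intervals.sort()
        for (lo1, hi1, _), (lo2, hi2, st2) in zip(intervals, intervals[1:]):
            if lo2 < hi1 - 1e-12:
                raise GeometryError(
                    f"segment {s.id!r}: overlapping stenoses "
                    f"([{lo1:.2f},{hi1:.2f}] and [{lo2:.2f},{hi2:.2f}] mm)"
                )
        step = sample_step
        if step is None:
            r_min_ref = min(s.reference_radius_proximal, s.reference_radius_distal)
            step = min(0.2, r_min_ref / 4.0)
        s_arr, pts = _resample_polyline(s.points, step)
        taper = np.interp(
            s_arr, [0.0, L], [s.reference_radius_proximal, s.reference_radius_distal]
        )
        narrowing = np.zeros_like(s_arr)
        for st in s.stenoses:
            ref_d = 2.0 * np.interp(
                st.center_arclength, [0.0, L],
                [s.reference_radius_proximal, s.reference_radius_distal],
            )
            if ref_d < MIN_REFERENCE_DIAMETER_MM - 1e-9:
                raise GeometryError(
                    f"segment {s.id!r}: reference diameter {ref_d:.2f} mm at stenosis "
                    f"is below the {MIN_REFERENCE_DIAMETER_MM} mm inclusion minimum"
                )
            narrowing += st.diameter_reduction * st.window(s_arr)
        radius = taper * (1.0 - np.minimum(narrowing, 0.999))
        sampled[s.id] = SampledSegment(spec=s, s=s_arr, points=pts, radius=radius, taper=taper)

    # children links + junction attachment check
    for s in spec.segments:
        if s.parent_id is not None:
            parent = sampled[s.parent_id]
            start = sampled[s.id].points[0]
            d = np.linalg.norm(parent.points - start[None, :], axis=1)
            if d.min() > max(1e-6, 0.51 * np.max(np.diff(parent.s))):
                raise GeometryError(
                    f"segment {s.id!r} does not start on the centerline of its parent "
                    f"{s.parent_id!r} (closest approach {d.min():.3g} mm)"
                )
            parent.children.append(s.id)

    return VesselTree(spec=spec, segments=sampled, root_id=spec.inlet_segment_id)


# ---------------------------------------------------------------------------
# Rasterization


@dataclass
class VoxelMask:
    """Binary lumen mask on a regular grid.

    ``grid[i, j, k]`` with axis order (x, y, z); ``origin`` is the world-mm
    coordinate of the center of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing: tuple
    origin: tuple

    def __post_init__(self) -> None:
        self.grid = np.ascontiguousarray(self.grid.astype(bool))
        self.spacing = tuple(float(v) for v in self.spacing)
        self.origin = tuple(float(v) for v in self.origin)
        if self.grid.ndim != 3:
            raise GeometryError("mask grid must be 3D")
        if any(v <= 0 for v in self.spacing):
            raise GeometryError("spacing must be positive")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def voxel_centers_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def boundary_faces_touched(self) -> list:
        """Names of the domain faces the foreground touches (e.g. '-x', '+y')."""
        g = self.grid
        out = []
        for axis, name in ((0, "x"), (1, "y"), (2, "z")):
            lo = np.take(g, 0, axis=axis)
            hi = np.take(g, g.shape[axis] - 1, axis=axis)
            if lo.any():
                out.append("-" + name)
            if hi.any():
                out.append("+" + name)
        return out


def voxelize(tree: VesselTree, spacing: float = 0.35, padding: float = 1.0) -> VoxelMask:
    """Rasterize an analytic tree to a binary lumen mask.

    A voxel is foreground iff its center lies within ``r(s*)`` of the
    centerline, where ``s*`` is the nearest centerline sample.  The domain is
    padded laterally by ``padding`` mm but cut flush at the inlet and outlet
    end planes, so the mask touches the box boundary only there.

    Raises
    ------
    GeometryError
        If ``spacing`` is too coarse to resolve the narrowest throat
        (requires ``spacing <= r_min / 2``), or the tree is empty.
    """
    if not tree.segments:
        raise GeometryError("empty tree")
    r_min = tree.min_radius()
    if spacing > r_min / 2.0 + 1e-12:
        # name the tightest stenosis for the diagnostic
        worst = min(
            tree.segments.values(), key=lambda seg: float(seg.radius.min())
        )
        raise GeometryError(
            f"spacing {spacing} mm cannot resolve the throat of segment "
            f"{worst.spec.id!r} (min radius {r_min:.3f} mm); need spacing <= r/2"
        )

    pts = np.concatenate([seg.points for seg in tree.segments.values()])
    rads = np.concatenate([seg.radius for seg in tree.segments.values()])
    lo = (pts - (rads[:, None] + padding)).min(axis=0)
    hi = (pts + (rads[:, None] + padding)).max(axis=0)

    # cut the box flush at inlet / outlet planes along the local tangent axis
    def clamp_end(seg: SampledSegment, at_start: bool) -> None:
        p = seg.points[0] if at_start else seg.points[-1]
        tangent = (
            seg.points[1] - seg.points[0] if at_start else seg.points[-1] - seg.points[-2]
        )
        axis = int(np.argmax(np.abs(tangent)))
        outward = -tangent[axis] if at_start else tangent[axis]
        if outward < 0:
            lo[axis] = max(lo[axis], p[axis])
        else:
            hi[axis] = min(hi[axis], p[axis])

    clamp_end(tree.root, at_start=True)
    for leaf in tree.leaves():
        clamp_end(leaf, at_start=False)

    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    origin = lo + 0.5 * spacing  # voxel centers start half a voxel inside
    ax = [origin[k] + spacing * np.arange(shape[k]) for k in range(3)]
    tree_kd = cKDTree(pts)
    # query all voxel centers in chunks to bound memory
    grid = np.zeros(tuple(shape), dtype=bool)
    X, Y = np.meshgrid(ax[0], ax[1], indexing="ij")
    for k in range(shape[2]):
        centers = np.column_stack(
            [X.ravel(), Y.ravel(), np.full(X.size, ax[2][k])]
        )
        dist, idx = tree_kd.query(centers, workers=-1)
        grid[:, :, k] = (dist <= rads[idx]).reshape(shape[0], shape[1])

    mask = VoxelMask(grid=grid, spacing=(spacing,) * 3, origin=tuple(origin))
    _check_single_component(mask)
    return mask


def _check_single_component(mask: VoxelMask) -> None:
    from scipy import ndimage

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    _, n = ndimage.label(mask.grid, structure=structure)
    if n == 0:
        raise GeometryError("mask has no foreground")
    if n > 1:
        raise GeometryError(f"mask foreground has {n} 26-connected components, expected 1")


# ---------------------------------------------------------------------------
# NIfTI round trip


def write_mask(mask: VoxelMask, path) -> None:
    """Write a binary mask as NIfTI-1 (affine = diag(spacing) + origin)."""
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path) -> VoxelMask:
    """Read a NIfTI-1 binary mask; rejects non-binary volumes."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    vals = np.unique(data)
    if not np.all(np.isin(vals, [0, 1])):
        raise GeometryError(f"volume is not binary (values {vals[:5]}...)")
    affine = img.affine
    spacing = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(v) for v in affine[:3, 3])
    return VoxelMask(grid=data.astype(bool), spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# Convenience constructors used across tests and the pipeline


def straight_tube_spec(
    radius: float = 1.5,
    length: float = 40.0,
    ds: float | None = None,
    lesion_length: float = 10.0,
    lesion_center: float | None = None,
    shape: str = "cosine",
    label: str = "LAD",
) -> VesselTreeSpec:
    """A single straight x-aligned segment, optionally with one focal stenosis."""
    stenoses = ()
    if ds is not None and ds > 0:
        center = length / 2.0 if lesion_center is None else lesion_center
        stenoses = (
            StenosisSpec(
                center_arclength=center,
                length=lesion_length,
                diameter_reduction=ds,
                shape=shape,
            ),
        )
    seg = SegmentSpec(
        id="seg0",
        control_points=((0.0, 0.0, 0.0), (length, 0.0, 0.0)),
        reference_radius_proximal=radius,
        reference_radius_distal=radius,
        stenoses=stenoses,
    )
    return VesselTreeSpec(segments=(seg,), inlet_segment_id="seg0", label=label)


def bifurcation_spec(
    parent_radius: float = 1.8,
    child_radius: float = 1.3,
    parent_length: float = 20.0,
    child_length: float = 18.0,
    half_angle_deg: float = 30.0,
) -> VesselTreeSpec:
    """A symmetric two-child bifurcation in the x-y plane."""
    a = np.deg2rad(half_angle_deg)
    jx, jy = parent_length, 0.0
    dx, dy = child_length * np.cos(a), child_length * np.sin(a)
    parent = SegmentSpec(
        id="parent",
        control_points=((0.0, 0.0, 0.0), (jx, jy, 0.0)),
        reference_radius_proximal=parent_radius,
        reference_radius_distal=parent_radius,
    )
    c1 = SegmentSpec(
        id="child_a",
        parent_id="parent",
        control_points=((jx, jy, 0.0), (jx + dx, jy + dy, 0.0)),
        reference_radius_proximal=child_radius,
        reference_radius_distal=child_radius,
    )
    c2 = SegmentSpec(
        id="child_b",
        parent_id="parent",
        control_points=((jx, jy, 0.0), (jx + dx, jy - dy, 0.0)),
        reference_radius_proximal=child_radius,
        reference_radius_distal=child_radius,
    )
    return VesselTreeSpec(segments=(parent, c1, c2), inlet_segment_id="parent")
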