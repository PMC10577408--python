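"""Centerline extraction and stenosis quantification from binary lumen masks.

This is the classical image-processing stand-in for a segmentation-driven
lumen model.  The centerline is recovered as the ridge of the Euclidean
distance transform: every open end of the mask (a foreground patch on the
domain boundary) is a terminal, and minimum-cost geometric paths from the
proximal terminal to every distal terminal — with cost falling steeply away
from the distance-transform ridge — trace the medial curves.  Shared path
prefixes become parent branches, so a bifurcated mask yields a branch tree.
The inscribed-sphere radius at each centerline point is the distance
transform value; the diameter stenosis (DS%) of a lesion window is then
read off the diameter profile QCA-style (minimum lumen diameter against a
reference interpolated between the healthy shoulders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .geometry import VoxelMask

__all__ = ["Branch", "Centerline", "LumenProfile", "extract_centerline", "stenosis_degree"]


class LumenError(ValueError):
    """Raised for masks that cannot be analyzed."""


@dataclass
class Branch:
    """One ordered branch of the centerline."""

    branch_id: int
    parent: int | None
    points: np.ndarray     # (n, 3) world mm
    radius: np.ndarray     # mm (inscribed sphere)
    arclength: np.ndarray  # cumulative mm from the branch start


@dataclass
class Centerline:
    """Ordered centerline of a vessel tree with per-point inscribed radius."""

    branches: list = field(default_factory=list)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def junction_degrees(self) -> list:
        """Degree (parent + children) of every junction node."""
        counts: dict = {}
        for b in self.branches:
            if b.parent is not None:
                counts[b.parent] = counts.get(b.parent, 0) + 1
        return [n_children + 1 for n_children in counts.values()]

    def main_path(self) -> Branch:
        """Longest root-to-leaf chain concatenated into one branch.

        Arclength accumulates through the chain from the root origin; used
        for single-vessel diameter and FFR profiles.
        """
        by_id = {b.branch_id: b for b in self.branches}
        children: dict = {}
        for b in self.branches:
            children.setdefault(b.parent, []).append(b.branch_id)
        roots = children.get(None, [])
        if not roots:
            raise LumenError("centerline has no root branch")

        best: tuple[float, list] = (-1.0, [])

        def walk(bid: int, acc: list, length: float) -> None:
            nonlocal best
            acc = acc + [bid]
            length += float(by_id[bid].arclength[-1])
            kids = children.get(bid, [])
            if not kids and length > best[0]:
                best = (length, acc)
            for k in kids:
                walk(k, acc, length)

        for r in roots:
            walk(r, [], 0.0)

        chain = [by_id[b] for b in best[1]]
        pts = np.concatenate([b.points for b in chain])
        rad = np.concatenate([b.radius for b in chain])
        seg = np.diff(pts, axis=0)
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
        return Branch(branch_id=-1, parent=None, points=pts, radius=rad, arclength=s)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.branches:
            for p, r, s in zip(b.points, b.radius, b.arclength):
                rows.append((p[0], p[1], p[2], r, s, b.branch_id))
        return pd.DataFrame(rows, columns=["x", "y", "z", "radius", "arclength", "branch_id"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class LumenProfile:
    """Diameter / area profile of a lesion window and its stenosis degree."""

    arclength: np.ndarray
    diameter: np.ndarray   # mm
    area: np.ndarray       # mm^2, pi (d/2)^2 under the near-circular assumption
    d_min: float
    d_ref: float
    ds_percent: float
    significant: bool      # DS >= 50%


def _validate_mask(mask: VoxelMask) -> None:
    structure = np.ones((3, 3, 3), dtype=bool)
    _, n = ndimage.label(mask.grid, structure=structure)
    if n != 1:
        raise LumenError(f"mask has {n} foreground components; need exactly 1")
    filled = ndimage.binary_fill_holes(mask.grid)
    if not np.array_equal(filled, mask.grid):
        raise LumenError("mask has internal cavities")


def _terminal_points(mask: VoxelMask, edt: np.ndarray) -> list:
    """One terminal voxel (max inscribed radius) per open end of the mask."""
    g = mask.grid
    terminals: list = []
    for axis in range(3):
        for side in (0, g.shape[axis] - 1):
            slab = np.take(g, side, axis=axis)
            if not slab.any():
                continue
            lbl, n = ndimage.label(slab, structure=np.ones((3, 3), dtype=bool))
            eslab = np.take(edt, side, axis=axis)
            for comp in range(1, n + 1):
                sel = lbl == comp
                vals = np.where(sel, eslab, -1.0)
                jk = np.unravel_index(int(np.argmax(vals)), vals.shape)
                ijk = list(jk)
                ijk.insert(axis, side)
                terminals.append(tuple(ijk))
    return terminals


def _smooth(arr: np.ndarray, window: int = 3) -> np.ndarray:
    if len(arr) < window:
        return arr
    kernel = np.ones(window) / window
    out = arr.copy()
    if arr.ndim == 1:
        out[1:-1] = np.convolve(arr, kernel, mode="valid")
        return out
    for k in range(arr.shape[1]):
        out[1:-1, k] = np.convolve(arr[:, k], kernel, mode="valid")
    return out


def _paths_to_branches(paths: list, mask: VoxelMask, edt: np.ndarray) -> list:
    """Merge source-rooted voxel paths into a branch tree by shared prefixes."""
    branches: list[Branch] = []

    def emit(chain: list, parent: int | None) -> int:
        ijk = np.asarray(chain, dtype=float)
        pts = np.asarray(mask.origin) + ijk * np.asarray(mask.spacing)
        rad = np.array([edt[t] for t in chain])
        pts = _smooth(pts)
        rad = _smooth(rad)
        seg = np.diff(pts, axis=0)
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
        bid = len(branches)
        branches.append(
            Branch(branch_id=bid, parent=parent, points=pts, radius=rad, arclength=s)
        )
        return bid

    def split(group: list, parent: int | None) -> None:
        # longest common prefix of all paths in the group
        k = 0
        min_len = min(len(p) for p in group)
        while k < min_len and all(p[k] == group[0][k] for p in group):
            k += 1
        prefix = group[0][:k]
        if len(prefix) >= 2:
            bid = emit(prefix, parent)
        else:
            bid = parent
        suffixes = [p[max(k - 1, 0):] for p in group if len(p) > k]
        if not suffixes:
            return
        by_first: dict = {}
        for p in suffixes:
            by_first.setdefault(p[1] if len(p) > 1 else p[0], []).append(p)
        for sub in by_first.values():
            split(sub, bid)

    split(paths, None)
    return branches


def extract_centerline(mask: VoxelMask) -> Centerline:
    """Extract an ordered, radius-annotated centerline from a lumen mask.

    Pipeline: Euclidean distance transform -> terminal detection on the
    open boundary faces -> minimum-cost medial paths from the proximal
    terminal (largest inscribed radius) to every distal terminal ->
    prefix-merged branch tree -> 3-point moving-average smoothing of points
    and radii.

    Raises
    ------
    LumenError
        For masks with multiple components, cavities, fewer than two open
        ends, or degenerate single-voxel-wide lumina.
    """
    _validate_mask(mask)
    edt = ndimage.distance_transform_edt(mask.grid, sampling=mask.spacing)
    if edt.max() < 1.5 * min(mask.spacing):
        raise LumenError("mask too thin: lumen under two voxels wide everywhere")

    terminals = _terminal_points(mask, edt)
    if len(terminals) < 2:
        raise LumenError(
            f"found {len(terminals)} open end(s); need an inlet and >= 1 outlet"
        )
    source = max(terminals, key=lambda t: edt[t])
    targets = [t for t in terminals if t != source]

    # cost falls off quadratically away from the distance-transform ridge
    with np.errstate(divide="ignore"):
        cost = np.where(mask.grid, (edt.max() / np.maximum(edt, 1e-12)) ** 2, np.inf)
    mcp = MCP_Geometric(cost, fully_connected=True)
    mcp.find_costs([source], targets)
    paths = []
    for t in targets:
        try:
            paths.append([tuple(v) for v in mcp.traceback(t)])
        except ValueError as exc:
            raise LumenError(f"no medial path to terminal {t}: {exc}") from exc
    if any(len(p) < 3 for p in paths):
        raise LumenError("degenerate mask: medial path shorter than 3 voxels")

    branches = _paths_to_branches(paths, mask, edt)
    cl = Centerline(branches=branches)
    for b in cl.branches:
        ijk = np.rint(mask.world_to_index(b.points)).astype(int)
        ijk = np.clip(ijk, 0, np.array(mask.shape) - 1)
        if not mask.grid[ijk[:, 0], ijk[:, 1], ijk[:, 2]].all():
            raise LumenError("centerline left the mask foreground")
    return cl


def stenosis_degree(
    centerline: Centerline | Branch,
    lesion_window: tuple,
) -> LumenProfile:
    """Quantify diameter stenosis within an arclength window of the main path.

    ``d_min`` is the minimum diameter inside the window; ``d_ref`` is the
    reference healthy diameter interpolated linearly between the diameters at
    the window's proximal and distal shoulders, evaluated at the location of
    ``d_min``; ``DS% = 100 (1 - d_min / d_ref)``.  A lesion is flagged
    significant when DS >= 50%.

    Raises
    ------
    LumenError
        If the window lies outside the arclength range or covers fewer than
        three centerline points.
    """
    path = centerline.main_path() if isinstance(centerline, Centerline) else centerline
    s0, s1 = float(lesion_window[0]), float(lesion_window[1])
    if s0 >= s1:
        raise LumenError("lesion window must have s0 < s1")
    if s0 < path.arclength[0] - 1e-9 or s1 > path.arclength[-1] + 1e-9:
        raise LumenError(
            f"lesion window [{s0}, {s1}] mm outside centerline range "
            f"[{path.arclength[0]:.2f}, {path.arclength[-1]:.2f}] mm"
        )
    inside = (path.arclength >= s0) & (path.arclength <= s1)
    if inside.sum() < 3:
        raise LumenError("lesion window covers fewer than 3 centerline points")

    d = 2.0 * path.radius
    d0 = float(np.interp(s0, path.arclength, d))
    d1 = float(np.interp(s1, path.arclength, d))
    s_in = path.arclength[inside]
    d_in = d[inside]
    i_min = int(np.argmin(d_in))
    d_min = float(d_in[i_min])
    s_min = float(s_in[i_min])
    d_ref = float(np.interp(s_min, [s0, s1], [d0, d1]))
    d_ref = max(d_ref, d_min)  # guard: shoulders inside a diffuse lesion
    ds = 100.0 * (1.0 - d_min / d_ref) if d_ref > 0 else 0.0
    return LumenProfile(
        arclength=s_in,
        diameter=d_in,
        area=np.pi * (d_in / 2.0) ** 2,
        d_min=d_min,
        d_ref=d_ref,
        ds_percent=ds,
        significant=ds >= 50.0,
    )
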