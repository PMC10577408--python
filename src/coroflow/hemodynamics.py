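"""Coronary hemodynamics under simulated maximal hyperemia.

Two solvers share the same boundary-condition model:

* :func:`solve_1d` — a reduced-order, closed-form model that integrates
  Poiseuille viscous losses along the centerline and adds a separation
  (expansion) loss per stenosis.  It serves both as the fast computation
  mode and as the independent oracle for the 3D scheme.
* :func:`coroflow.solver3d.solve_3d` — a Cartesian-grid immersed-boundary
  projection solver (momentum predictor, pressure Poisson via BiCGStab,
  velocity correction), exposed here through :class:`FlowProblem`.

FFR is the ratio of mean distal pressure to mean aortic pressure; values
at or below 0.80 flag a flow-limiting lesion.

Units: SI internally; millimetres, mm^3/s and mmHg at the interfaces
(1 mmHg = 133.322 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VesselTree, VoxelMask

__all__ = [
    "MMHG_PA",
    "FluidParams",
    "BoundaryConditions",
    "FlowProblem",
    "FlowSolution",
    "FFRProfile",
    "hyperemic_bcs",
    "solve_1d",
    "extract_ffr",
]

MMHG_PA = 133.322  # Pa per mmHg

#: empirical separation-loss coefficient for focal stenoses
K_SEPARATION = 1.52

#: ischemia cut point on FFR / CT-FFR
FFR_THRESHOLD = 0.80


class HemodynamicsError(ValueError):
    pass


@dataclass(frozen=True)
class FluidParams:
    """Blood treated as a Newtonian fluid.

    Defaults are standard hyperemic blood values: viscosity 3.5 mPa s,
    density 1056 kg/m^3.
    """

    viscosity: float = 3.5e-3  # Pa s
    density: float = 1056.0    # kg/m^3

    def __post_init__(self) -> None:
        if self.viscosity < 0 or self.density <= 0:
            raise HemodynamicsError("viscosity must be >= 0 and density > 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass
class BoundaryConditions:
    """Fixed mean aortic inlet pressure and prescribed hyperemic outlet flows.

    ``outlet_flows`` maps each leaf segment id to its flow in mm^3/s; the
    inlet flow is their sum (mass balance).  The venous reference pressure
    is 0 mmHg.
    """

    pa_mmHg: float = 90.0
    outlet_flows: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pa_mmHg <= 0:
            raise HemodynamicsError("aortic pressure must be positive")
        if any(q < 0 for q in self.outlet_flows.values()):
            raise HemodynamicsError("outlet flows must be >= 0")

    @property
    def inlet_flow(self) -> float:
        """Total inlet flow, mm^3/s."""
        return float(sum(self.outlet_flows.values()))


@dataclass
class FlowProblem:
    """Everything the 3D solver needs."""

    mask: VoxelMask
    bcs: BoundaryConditions
    fluid: FluidParams = field(default_factory=FluidParams)
    inlet_face: str = "-x"
    tolerance: float = 1e-5       # relative velocity-update norm
    max_iterations: int = 20000
    advection: bool = True
    min_voxels_per_diameter: int = 6

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise HemodynamicsError("tolerance must be > 0")


@dataclass
class FlowSolution:
    """Pressure / velocity result of either solver."""

    mode: str                     # "1d" or "3d"
    pa_mmHg: float
    converged: bool
    residual_history: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    # 1D payload
    tree: VesselTree | None = None
    segment_pressure_mmHg: dict | None = None   # seg id -> array on seg.s
    segment_flow: dict | None = None            # seg id -> mm^3/s
    # 3D payload
    mask: VoxelMask | None = None
    pressure_mmHg_field: np.ndarray | None = None
    velocity_faces: tuple | None = None         # (u, v, w) m/s on staggered faces
    divergence_rel: float | None = None

    def axial_flux_mm3s(self) -> np.ndarray:
        """3D only: volumetric flux (mm^3/s) through each x-normal face plane."""
        if self.velocity_faces is None or self.mask is None:
            raise HemodynamicsError("axial flux is defined for 3D solutions only")
        u = self.velocity_faces[0]
        h = self.mask.spacing[0] * 1e-3
        return u.sum(axis=(1, 2)) * h * h * 1e9


@dataclass
class FFRProfile:
    """FFR along a vessel path plus the headline per-lesion value."""

    arclength: np.ndarray
    ffr: np.ndarray
    distal_ffr: dict
    lesion_ffr: float | None
    measurement_s: float | None

    @property
    def flow_limiting(self) -> bool | None:
        if self.lesion_ffr is None:
            return None
        return self.lesion_ffr <= FFR_THRESHOLD


# ---------------------------------------------------------------------------
# Boundary conditions


def hyperemic_bcs(
    tree: VesselTree,
    pa_mmHg: float = 90.0,
    hyperemic_velocity_mm_s: float = 350.0,
) -> BoundaryConditions:
    """Hyperemic boundary conditions from the tree geometry alone.

    Total inlet flow is the hyperemic mean inlet velocity (default
    0.35 m/s) times the inlet lumen area; it is split across the outlets in
    proportion to the cube of each outlet's reference radius (Murray's law).
    """
    leaves = tree.leaves()
    if not leaves:
        raise HemodynamicsError("tree has no outlets")
    r_inlet = float(tree.root.taper[0])
    q_in = hyperemic_velocity_mm_s * np.pi * r_inlet**2  # mm^3/s
    r_out = np.array([float(leaf.taper[-1]) for leaf in leaves])
    if np.any(r_out <= 0):
        bad = leaves[int(np.argmin(r_out))].spec.id
        raise HemodynamicsError(f"outlet {bad!r} has non-positive radius")
    weights = r_out**3 / (r_out**3).sum()
    flows = {leaf.spec.id: float(q_in * w) for leaf, w in zip(leaves, weights)}
    return BoundaryConditions(pa_mmHg=pa_mmHg, outlet_flows=flows)


# ---------------------------------------------------------------------------
# 1D reduced-order solver


def _segment_flows(tree: VesselTree, bcs: BoundaryConditions) -> dict:
    """Flow carried by each segment = sum of leaf flows in its subtree."""
    flows: dict = {}

    def walk(seg_id: str) -> float:
        seg = tree.segments[seg_id]
        if not seg.children:
            q = bcs.outlet_flows.get(seg_id)
            if q is None:
                raise HemodynamicsError(f"no outlet flow prescribed for leaf {seg_id!r}")
        else:
            q = sum(walk(c) for c in seg.children)
        flows[seg_id] = q
        return q

    walk(tree.root_id)
    return flows


def solve_1d(
    tree: VesselTree,
    bcs: BoundaryConditions,
    fluid: FluidParams | None = None,
) -> FlowSolution:
    """Closed-form pressure drop along the tree.

    Per segment the viscous drop is the element-wise Poiseuille integral
    ``dP = int 8 mu Q / (pi r(s)^4) ds`` over the sampled radius profile,
    and each stenosis contributes a separation loss applied at its throat:

        dP_sep = K_t * rho/2 * (A0/As - 1)^2 * (Q/A0)^2,   K_t = 1.52,

    with ``A0`` the reference (healthy taper) area and ``As`` the stenosed
    throat area.  Pressures are continuous at junctions.  Negative pressures
    are flagged in ``warnings`` but the solution is still returned.
    """
    fluid = fluid or FluidParams()
    flows = _segment_flows(tree, bcs)
    pa_pa = bcs.pa_mmHg * MMHG_PA
    pressures: dict = {}
    warnings: list = []

    def solve_segment(seg_id: str, p_in_pa: float) -> None:
        seg = tree.segments[seg_id]
        q = flows[seg_id] * 1e-9            # m^3/s
        s_m = seg.s * 1e-3
        r_m = np.maximum(seg.radius, 1e-9) * 1e-3
        integrand = 8.0 * fluid.viscosity * q / (np.pi * r_m**4)   # Pa/m
        visc = np.concatenate(
            [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(s_m))]
        )
        drop = visc.copy()
        for st in seg.spec.stenoses:
            if st.diameter_reduction <= 0:
                continue
            r_ref = float(seg.reference_radius_at(st.center_arclength)) * 1e-3
            r_thr = float(seg.radius_at(st.center_arclength)) * 1e-3
            a0 = np.pi * r_ref**2
            a_s = np.pi * r_thr**2
            dp_sep = (
                K_SEPARATION * fluid.density / 2.0 * (a0 / a_s - 1.0) ** 2 * (q / a0) ** 2
            )
            drop = drop + np.where(seg.s >= st.center_arclength, dp_sep, 0.0)
        p = p_in_pa - drop
        if p[-1] < 0:
            warnings.append(
                f"segment {seg_id!r}: distal pressure {p[-1] / MMHG_PA:.1f} mmHg < 0"
            )
        pressures[seg_id] = p / MMHG_PA
        for child in seg.children:
            # child taps the parent at its attachment point
            start = tree.segments[child].points[0]
            d = np.linalg.norm(seg.points - start[None, :], axis=1)
            s_att = seg.s[int(np.argmin(d))]
            p_att = float(np.interp(s_att, seg.s, p))
            solve_segment(child, p_att)

    solve_segment(tree.root_id, pa_pa)
    return FlowSolution(
        mode="1d",
        pa_mmHg=bcs.pa_mmHg,
        converged=True,
        warnings=warnings,
        tree=tree,
        segment_pressure_mmHg=pressures,
        segment_flow=flows,
    )


# ---------------------------------------------------------------------------
# FFR extraction


def _main_path_profile(sol: FlowSolution) -> tuple[np.ndarray, np.ndarray, dict]:
    """Concatenated (s, p) profile along the longest root-to-leaf path, plus
    the pressure at every leaf outlet."""
    tree = sol.tree
    paths = tree.paths_from_root()
    lengths = [sum(tree.segments[sid].length for sid in p) for p in paths]
    main = paths[int(np.argmax(lengths))]
    s_all: list = []
    p_all: list = []
    offset = 0.0
    for sid in main:
        seg = tree.segments[sid]
        s_all.append(seg.s + offset)
        p_all.append(sol.segment_pressure_mmHg[sid])
        offset += seg.length
    distal = {
        leaf.spec.id: float(sol.segment_pressure_mmHg[leaf.spec.id][-1])
        for leaf in tree.leaves()
    }
    return np.concatenate(s_all), np.concatenate(p_all), distal


def _lesion_end_on_main_path(tree: VesselTree) -> float | None:
    """Arclength of the distal shoulder of the dominant stenosis on the
    longest root-to-leaf path (None when the path carries no stenosis)."""
    paths = tree.paths_from_root()
    lengths = [sum(tree.segments[sid].length for sid in p) for p in paths]
    main = paths[int(np.argmax(lengths))]
    best = None
    offset = 0.0
    best_ds = 0.0
    for sid in main:
        seg = tree.segments[sid]
        for st in seg.spec.stenoses:
            if st.diameter_reduction > best_ds:
                best_ds = st.diameter_reduction
                best = offset + st.center_arclength + st.length / 2.0
        offset += seg.length
    return best


def extract_ffr(
    solution: FlowSolution,
    centerline=None,
    measurement_offset_mm: float = 20.0,
    lesion_end_s: float | None = None,
) -> FFRProfile:
    """FFR(s) = p(s) / Pa along the main vessel path.

    The headline ``lesion_FFR`` is read at the lesion's distal shoulder plus
    ``measurement_offset_mm`` (default 20 mm), capped at the vessel end.  For
    1D solutions the lesion position comes from the tree specification; for
    3D solutions pass ``lesion_end_s`` (mm along the supplied centerline) and
    the pressure field is averaged over the cross-section disc of radius
    r(s)/2 at each centerline point.
    """
    if not solution.converged:
        raise HemodynamicsError("cannot extract FFR from a non-converged solution")
    pa = solution.pa_mmHg
    if solution.mode == "1d":
        s, p, distal_p = _main_path_profile(solution)
        if lesion_end_s is None:
            lesion_end_s = _lesion_end_on_main_path(solution.tree)
    else:
        if centerline is None:
            raise HemodynamicsError("3D FFR extraction requires a centerline")
        s, p, distal_p = _sample_3d_pressure(solution, centerline)

    ffr = p / pa
    distal_ffr = {k: v / pa for k, v in distal_p.items()}
    lesion_ffr = None
    measurement_s = None
    if lesion_end_s is not None:
        measurement_s = min(lesion_end_s + measurement_offset_mm, float(s[-1]))
        lesion_ffr = float(np.interp(measurement_s, s, ffr))
    return FFRProfile(
        arclength=s,
        ffr=ffr,
        distal_ffr=distal_ffr,
        lesion_ffr=lesion_ffr,
        measurement_s=measurement_s,
    )


def _sample_3d_pressure(sol: FlowSolution, centerline) -> tuple:
    """Disc-averaged pressure (mmHg) at each centerline point of the main path."""
    from .lumen import Branch, Centerline  # local import to avoid cycles

    path = centerline.main_path() if isinstance(centerline, Centerline) else centerline
    mask = sol.mask
    pfield = sol.pressure_mmHg_field
    h = np.asarray(mask.spacing)
    pts = path.points
    tangents = np.gradient(pts, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1)[:, None], 1e-12)
    fg = mask.grid
    nxyz = np.array(fg.shape)
    p_out = np.empty(len(pts))
    for i, (c, t, r) in enumerate(zip(pts, tangents, path.radius)):
        rad = max(r / 2.0, float(h.max()))
        lo = np.maximum(np.floor(mask.world_to_index(c - rad - h)).astype(int), 0)
        hi = np.minimum(np.ceil(mask.world_to_index(c + rad + h)).astype(int) + 1, nxyz)
        if np.any(lo >= hi):
            raise HemodynamicsError("centerline point outside the fluid domain")
        sub = np.stack(
            np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        centers = mask.voxel_centers_world(sub)
        rel = centers - c
        axial = rel @ t
        lateral = np.linalg.norm(rel - axial[:, None] * t[None, :], axis=1)
        sel = (
            (np.abs(axial) <= h.max() / 2.0 + 1e-9)
            & (lateral <= rad)
            & fg[sub[:, 0], sub[:, 1], sub[:, 2]]
        )
        if not sel.any():
            sel = fg[sub[:, 0], sub[:, 1], sub[:, 2]] & (
                np.linalg.norm(rel, axis=1) <= rad + h.max()
            )
        if not sel.any():
            raise HemodynamicsError("centerline point outside the fluid domain")
        p_out[i] = pfield[sub[sel, 0], sub[sel, 1], sub[sel, 2]].mean()
    distal = {"outlet": float(p_out[-1])}
    return path.arclength, p_out, distal
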