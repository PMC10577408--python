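"""Shared fixtures.

The 3D flow solves are the expensive part of the suite, so every solution
that more than one test inspects is computed once per session here.  Flow
rates for the severity sweep are reduced below the hyperemic default to keep
the throat jet comfortably laminar on small grids; the monotonicity and
oracle-agreement properties under test do not depend on the absolute flow.
"""

from __future__ import annotations

import numpy as np
import pytest

import coroflow as cf
from coroflow.lumen import extract_centerline
from coroflow.solver3d import solve_3d

PA = 90.0
RADIUS = 1.5           # mm
RE50_FLOW = 390.47     # mm^3/s -> Re ~ 50 in a 3 mm tube with default blood


def tube_tree(ds: float | None, length: float = 20.0, lesion_center: float = 8.0,
              lesion_length: float = 6.0):
    spec = cf.geometry.straight_tube_spec(
        radius=RADIUS, length=length, ds=ds, lesion_length=lesion_length,
        lesion_center=lesion_center,
    )
    return cf.build_tree(spec)


def solve_tube_3d(ds, q_mm3s, spacing, length=20.0, tolerance=1e-5):
    tree = tube_tree(ds if ds else None, length=length)
    bcs = cf.BoundaryConditions(pa_mmHg=PA, outlet_flows={"seg0": q_mm3s})
    mask = cf.voxelize(tree, spacing=spacing, padding=1.0)
    sol = solve_3d(cf.FlowProblem(mask=mask, bcs=bcs, tolerance=tolerance))
    return tree, mask, sol


def lesion_ffr_pair(ds, q_mm3s, spacing, length=20.0):
    """(FFR_1d, FFR_3d) at the lesion measurement point for one tube."""
    tree, mask, sol3 = solve_tube_3d(ds, q_mm3s, spacing, length=length)
    bcs = cf.BoundaryConditions(pa_mmHg=PA, outlet_flows={"seg0": q_mm3s})
    prof1 = cf.extract_ffr(cf.solve_1d(tree, bcs), measurement_offset_mm=6.0)
    cl = extract_centerline(mask)
    lesion_end = 8.0 + 3.0  # lesion center + half length
    prof3 = cf.extract_ffr(sol3, centerline=cl, measurement_offset_mm=6.0,
                           lesion_end_s=lesion_end)
    f1 = prof1.lesion_ffr
    if f1 is None:  # no stenosis: measure at the same arclength
        f1 = float(np.interp(lesion_end + 6.0, prof1.arclength, prof1.ffr))
    return f1, prof3.lesion_ffr, sol3


@pytest.fixture(scope="session")
def poiseuille_case():
    """Straight tube at Re ~ 50, 12 voxels/diameter."""
    tree, mask, sol = solve_tube_3d(None, RE50_FLOW, spacing=0.25, length=15.0)
    return {"tree": tree, "mask": mask, "sol": sol, "q": RE50_FLOW}


@pytest.fixture(scope="session")
def grid_convergence_errors():
    """Relative Poiseuille pressure-drop error at three refinements."""
    errors = []
    for spacing in (0.5, 0.375, 0.25):
        _, mask, sol = solve_tube_3d(None, RE50_FLOW, spacing=spacing, length=15.0)
        p = sol.pressure_mmHg_field
        nx = p.shape[0]
        i0, i1 = nx // 4, 3 * nx // 4
        dp = (np.nanmean(p[i0]) - np.nanmean(p[i1])) * 133.322
        lm = (i1 - i0) * spacing * 1e-3
        dp_ref = 8 * 3.5e-3 * lm * (RE50_FLOW * 1e-9) / (np.pi * (RADIUS * 1e-3) ** 4)
        errors.append(abs(dp - dp_ref) / dp_ref)
    return errors


@pytest.fixture(scope="session")
def severity_sweep():
    """lesion FFR (1D and 3D) across DS at a fixed reduced flow."""
    q = 300.0
    out = {}
    for ds, spacing in ((0.0, 0.25), (0.3, 0.25), (0.5, 0.2), (0.7, 0.15)):
        f1, f3, sol = lesion_ffr_pair(ds, q, spacing)
        out[ds] = {"ffr_1d": f1, "ffr_3d": f3, "sol": sol}
    return out


@pytest.fixture(scope="session")
def flow_sweep():
    """lesion FFR at DS = 0.5 for two flows (plus the severity-sweep flow)."""
    out = {}
    for q in (300.0, 900.0):
        f1, f3, sol = lesion_ffr_pair(0.5, q, spacing=0.2)
        out[q] = {"ffr_1d": f1, "ffr_3d": f3, "sol": sol}
    return out


@pytest.fixture(scope="session")
def cohort_seed1():
    return cf.sample_cohort(seed=1)
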