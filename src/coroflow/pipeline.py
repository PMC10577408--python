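"""End-to-end pipeline: geometry -> centerline -> FFR -> cohort -> evaluation.

A :class:`RunConfig` gathers the sub-configurations of every stage plus a
single global seed; the seed fans out deterministically to per-stage child
seeds so a report is reproducible from its embedded config alone.  Reports
are a versioned JSON bundle plus the cohort CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diagstats
from .cohort import CohortConfig, sample_cohort
from .geometry import VesselTreeSpec, build_tree, straight_tube_spec, voxelize, write_mask
from .hemodynamics import FluidParams, extract_ffr, hyperemic_bcs, solve_1d

log = logging.getLogger("coroflow")

SCHEMA_TAG = "coroflow/report/1"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, artifacts: dict | None = None):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.artifacts = artifacts or {}


@dataclass
class GeometryConfig:
    spec_path: str | None = None   # JSON VesselTreeSpec; default demo tube if None
    spacing_mm: float = 0.35
    padding_mm: float = 1.0
    demo_radius_mm: float = 1.5
    demo_length_mm: float = 40.0
    demo_ds: float = 0.5
    demo_lesion_length_mm: float = 10.0


@dataclass
class FlowConfig:
    solver: str = "1d"             # "1d" or "3d"
    pa_mmHg: float = 90.0
    hyperemic_velocity_mm_s: float = 350.0
    viscosity_pa_s: float = 3.5e-3
    density_kg_m3: float = 1056.0
    measurement_offset_mm: float = 20.0
    tolerance: float = 1e-5


@dataclass
class EvalConfig:
    ffr_threshold: float = 0.80
    agatston_cut: float = 400.0


@dataclass
class RunConfig:
    seed: int = 17
    output_dir: str = "coroflow_out"
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self) -> str:
        d = asdict(self)
        d["schema"] = "coroflow/run-config/1"
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        d.pop("schema", None)
        return cls(
            seed=d.get("seed", 17),
            output_dir=d.get("output_dir", "coroflow_out"),
            geometry=GeometryConfig(**d.get("geometry", {})),
            flow=FlowConfig(**d.get("flow", {})),
            cohort=CohortConfig(**d.get("cohort", {})),
            evaluation=EvalConfig(**d.get("evaluation", {})),
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write a versioned report bundle.

    Returns the report dict (also written to ``report.json``).  Any stage
    failure raises :class:`PipelineError` naming the stage and listing the
    artifacts completed before it.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # --- geometry ---------------------------------------------------------
    stage = "geometry"
    try:
        if config.geometry.spec_path is not None:
            spec_file = Path(config.geometry.spec_path)
            if not spec_file.exists():
                raise FileNotFoundError(f"spec file not found: {spec_file}")
            spec = VesselTreeSpec.from_json(spec_file.read_text())
        else:
            g = config.geometry
            spec = straight_tube_spec(
                radius=g.demo_radius_mm,
                length=g.demo_length_mm,
                ds=g.demo_ds,
                lesion_length=g.demo_lesion_length_mm,
            )
        tree = build_tree(spec)
        mask = voxelize(tree, spacing=config.geometry.spacing_mm,
                        padding=config.geometry.padding_mm)
        mask_path = out / "mask.nii.gz"
        write_mask(mask, mask_path)
        artifacts["mask"] = str(mask_path)
        log.info("geometry: %d segments, mask %s", len(spec.segments), mask.shape)
    except Exception as exc:
        raise PipelineError(stage, str(exc), artifacts) from exc

    # --- centerline -------------------------------------------------------
    stage = "centerline"
    try:
        from .lumen import extract_centerline

        centerline = extract_centerline(mask)
        cl_path = out / "centerline.csv"
        centerline.to_csv(cl_path)
        artifacts["centerline"] = str(cl_path)
    except Exception as exc:
        raise PipelineError(stage, str(exc), artifacts) from exc

    # --- flow / FFR ---------------------------------------------------------
    stage = "ffr"
    try:
        fl = config.flow
        fluid = FluidParams(viscosity=fl.viscosity_pa_s, density=fl.density_kg_m3)
        bcs = hyperemic_bcs(tree, pa_mmHg=fl.pa_mmHg,
                            hyperemic_velocity_mm_s=fl.hyperemic_velocity_mm_s)
        if fl.solver == "3d":
            from .hemodynamics import FlowProblem
            from .solver3d import solve_3d

            problem = FlowProblem(mask=mask, bcs=bcs, fluid=fluid, tolerance=fl.tolerance)
            sol = solve_3d(problem)
            profile = extract_ffr(sol, centerline=centerline,
                                  measurement_offset_mm=fl.measurement_offset_mm,
                                  lesion_end_s=_demo_lesion_end(config))
        else:
            sol = solve_1d(tree, bcs, fluid)
            profile = extract_ffr(sol, measurement_offset_mm=fl.measurement_offset_mm)
        ffr_payload = {
            "solver": fl.solver,
            "converged": bool(sol.converged),
            "lesion_ffr": profile.lesion_ffr,
            "flow_limiting": profile.flow_limiting,
            "distal_ffr": profile.distal_ffr,
            "arclength_mm": [round(float(s), 4) for s in profile.arclength],
            "ffr": [round(float(f), 6) for f in profile.ffr],
        }
        ffr_path = out / "ffr.json"
        ffr_path.write_text(json.dumps(ffr_payload, indent=2))
        artifacts["ffr"] = str(ffr_path)
    except Exception as exc:
        raise PipelineError(stage, str(exc), artifacts) from exc

    # --- cohort -------------------------------------------------------------
    stage = "cohort"
    try:
        cohort = sample_cohort(config.cohort, seed=config.child_seed("cohort"))
        cohort.to_csv(out)
        artifacts["cohort"] = str(out / "vessels.csv")
    except Exception as exc:
        raise PipelineError(stage, str(exc), artifacts) from exc

    # --- evaluation ---------------------------------------------------------
    stage = "evaluation"
    try:
        report_stats = evaluate_cohort(cohort.vessels, cohort.patients, config.evaluation)
    except Exception as exc:
        raise PipelineError(stage, str(exc), artifacts) from exc

    report = {
        "schema": SCHEMA_TAG,
        "config": yaml.safe_load(config.to_yaml()),
        "seeds": {"global": config.seed, "cohort": config.child_seed("cohort")},
        "ffr": {"solver": config.flow.solver, "lesion_ffr": profile.lesion_ffr},
        "statistics": report_stats,
        "artifacts": artifacts,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _demo_lesion_end(config: RunConfig) -> float | None:
    g = config.geometry
    if g.spec_path is None and g.demo_ds > 0:
        return g.demo_length_mm / 2.0 + g.demo_lesion_length_mm / 2.0
    return None


def evaluate_cohort(vessels, patients, ev: EvalConfig | None = None) -> dict:
    """The full statistics battery on a cohort table; returns a JSON-able dict."""
    ev = ev or EvalConfig()
    thr = ev.ffr_threshold
    truth = vessels["true_ffr"] <= thr

    def perf_dict(cm):
        p = diagstats.performance(cm)
        return {
            name: {
                "estimate": getattr(p, name).estimate,
                "ci95": [getattr(p, name).lo, getattr(p, name).hi],
            }
            for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
        }

    cm_ct = diagstats.confusion(vessels["ctffr"] <= thr, truth)
    cm_ccta = diagstats.confusion(vessels["ds_ge_50"], truth)
    roc_ct = diagstats.roc(vessels["ctffr"].to_numpy(), truth.to_numpy())
    roc_ccta = diagstats.roc(
        vessels["ds_ge_50"].to_numpy().astype(float), truth.to_numpy(),
        lower_is_positive=False,
    )
    delta, z, p_delong = diagstats.delong_compare(roc_ct, roc_ccta)
    thr_youden, j, tie = diagstats.youden_threshold(roc_ct)
    ba = diagstats.bland_altman(vessels["ctffr"], vessels["true_ffr"])
    r, p_rho = diagstats.spearman(vessels["ctffr"], vessels["true_ffr"])
    stat_mc, p_mc = diagstats.mcnemar(
        (vessels["ctffr"] <= thr) == truth, vessels["ds_ge_50"] == truth
    )
    agreement = diagstats.agreement_by_stratum(vessels)

    out = {
        "per_vessel": {
            "n": int(len(vessels)),
            "prevalence": float(truth.mean()),
            "ctffr": perf_dict(cm_ct),
            "ccta": perf_dict(cm_ccta),
            "auc_ctffr": roc_ct.auc,
            "auc_ccta": roc_ccta.auc,
            "delong": {"delta_auc": delta, "z": z, "p": p_delong},
            "youden_threshold": thr_youden,
            "youden_j": j,
            "youden_tied": bool(tie),
            "bland_altman": {
                "bias": ba.bias, "sd": ba.sd, "loa": [ba.loa_low, ba.loa_high],
            },
            "spearman": {"r": r, "p": p_rho},
            "mcnemar": {"statistic": stat_mc, "p": p_mc},
            "agreement_by_ctffr_stratum": {
                str(k): {"n": int(v["n"]), "agreement": float(v["agreement"])}
                for k, v in agreement.iterrows()
            },
        }
    }
    if patients is not None and "patient_ffr" in patients:
        cm_pat = diagstats.confusion(
            patients["patient_ctffr"] <= thr, patients["patient_ffr"] <= thr
        )
        high_cac = vessels["agatston"] >= ev.agatston_cut
        strat = diagstats.stratified_performance(
            vessels, high_cac.map({True: ">=400", False: "<400"})
        )
        out["per_patient"] = {
            "n": int(len(patients)),
            "prevalence": float((patients["patient_ffr"] <= thr).mean()),
            "ctffr": perf_dict(cm_pat),
        }
        out["by_agatston"] = {
            str(idx): {
                "n": int(row["n"]),
                "sensitivity": row["sensitivity"],
                "specificity": row["specificity"],
                "accuracy": row["accuracy"],
            }
            for idx, row in strat.iterrows()
        }
    return out
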