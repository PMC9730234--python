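"""End-to-end planning pipeline and its configuration.

``run_pipeline`` chains the stages: build (or load) a depth map, build the
R90 table, expand beam positions into scan spots, order them zigzag, anneal
each energy group, and evaluate the delivery-time model for both the initial
and the optimized path.  Any stage failure aborts with a stage-labelled
error.  A separate *summary replay* mode evaluates the time model directly
from printed plan summaries (N_B, N_S, N_E, S_i, S_f) so externally reported results
can be reproduced without the underlying geometry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .optimizer import FSAConfig, PlanOptimizationResult, optimize_plan, path_length
from .pdd import EnergyLibrary, build_r90_table
from .phantom import ApplicatorSpec, DepthMap, generate_phantom
from .sequencer import ScanPlan, make_plan
from .timing import MachineParams, PlanSummary, TimeBreakdown, delivery_time

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline", "replay_summary"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    applicator: ApplicatorSpec = ApplicatorSpec("square", 60.0, 5.0)
    phantom_kind: str = "random_smooth"
    depth_min: float = 9.0
    depth_max: float = 37.0
    phantom_seed: int = 0
    depthmap_path: str | None = None  # overrides the generated phantom
    library_path: str | None = None  # None = default four-energy library
    prescription_gy: float = 15.0
    machine: MachineParams = MachineParams()
    fsa: FSAConfig = FSAConfig()
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load and validate a YAML or JSON config file."""
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ValueError(f"config {path} must contain a mapping")
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {
            "applicator",
            "phantom",
            "depthmap_csv",
            "library",
            "prescription_Gy",
            "machine",
            "fsa",
            "output_dir",
        }
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        app_doc = doc.get("applicator", {})
        applicator = ApplicatorSpec(
            shape=app_doc.get("shape", "square"),
            size=float(app_doc.get("size_mm", 60.0)),
            lateral_resolution=float(app_doc.get("lateral_resolution_mm", 5.0)),
        )
        ph = doc.get("phantom", {})
        machine_doc = doc.get("machine", {})
        machine = MachineParams(
            dose_rate=float(machine_doc.get("dose_rate_Gy_per_s", 15.0)),
            arm_speed=float(machine_doc.get("arm_speed_mm_per_s", 50.0)),
            energy_switch_time=float(machine_doc.get("energy_switch_s", 2.0)),
            beam_onoff_time=float(machine_doc.get("beam_onoff_s", 0.020)),
        )
        fsa_doc = doc.get("fsa", {})
        fsa = FSAConfig(
            t0=fsa_doc.get("t0"),
            iterations=int(fsa_doc.get("iterations", 1000)),
            moves_per_iteration=fsa_doc.get("moves_per_iteration"),
            seed=int(fsa_doc.get("seed", 0)),
            restarts=int(fsa_doc.get("restarts", 3)),
            schedule=fsa_doc.get("schedule", "power"),
        )
        depthmap_csv = doc.get("depthmap_csv")
        if depthmap_csv is not None and not Path(depthmap_csv).exists():
            raise ValueError(f"depth-map file not found: {depthmap_csv}")
        library = doc.get("library")
        if library is not None and not Path(library).exists():
            raise ValueError(f"energy-library file not found: {library}")
        return cls(
            applicator=applicator,
            phantom_kind=ph.get("kind", "random_smooth"),
            depth_min=float(ph.get("depth_min_mm", 9.0)),
            depth_max=float(ph.get("depth_max_mm", 37.0)),
            phantom_seed=int(ph.get("seed", 0)),
            depthmap_path=depthmap_csv,
            library_path=library,
            prescription_gy=float(doc.get("prescription_Gy", 15.0)),
            machine=machine,
            fsa=fsa,
            output_dir=doc.get("output_dir"),
        )


@dataclass(frozen=True)
class PipelineResult:
    depthmap: DepthMap
    plan: ScanPlan
    optimization: PlanOptimizationResult
    time_initial: TimeBreakdown
    time_optimized: TimeBreakdown
    config: RunConfig = field(repr=False, default=None)

    @property
    def optimized_plan(self) -> ScanPlan:
        return self.optimization.plan

    def write(self, out_dir: str | Path) -> None:
        """Write plan JSONs, the path-length report CSV and time breakdowns."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.depthmap.to_csv(out / "depthmap.csv")
        self.plan.to_json(out / "plan.json")
        self.optimized_plan.to_json(out / "plan_optimized.json")
        self.optimization.report().to_csv(out / "path_report.csv", index=False)
        (out / "time_breakdown.json").write_text(
            json.dumps(
                {
                    "initial": self.time_initial.rounded(),
                    "optimized": self.time_optimized.rounded(),
                },
                indent=2,
            )
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage label
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def _total_zigzag_length(plan: ScanPlan) -> float:
    return sum(path_length(g.positions()) for g in plan.groups)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute phantom/input → table → spots → zigzag → FSA → timing."""
    depthmap = _stage("phantom")(_load_or_generate_depthmap)(config)
    table = _stage("energy-table")(_build_table)(config)
    plan = _stage("sequencing")(make_plan)(depthmap, table, config.prescription_gy)
    optimization = _stage("optimization")(optimize_plan)(plan, config.fsa)
    time_initial = _stage("timing")(delivery_time)(
        PlanSummary.from_plan(plan, _total_zigzag_length(plan)), config.machine
    )
    time_optimized = _stage("timing")(delivery_time)(
        PlanSummary.from_plan(plan, optimization.s_final), config.machine
    )
    logger.info(
        "pipeline done: N_B=%d N_S=%d N_E=%d S_i=%.2f S_f=%.2f (%.2f%%), "
        "T=%.1f s -> %.1f s [phantom seed %s, fsa seed %d]",
        plan.n_beam_positions,
        plan.n_spots,
        plan.n_energies,
        optimization.s_initial,
        optimization.s_final,
        optimization.delta_s,
        time_initial.delivery,
        time_optimized.delivery,
        config.phantom_seed,
        config.fsa.seed,
    )
    result = PipelineResult(
        depthmap, plan, optimization, time_initial, time_optimized, config
    )
    if config.output_dir:
        result.write(config.output_dir)
    return result


def _load_or_generate_depthmap(config: RunConfig) -> DepthMap:
    if config.depthmap_path:
        return DepthMap.from_csv(config.depthmap_path)
    return generate_phantom(
        config.phantom_kind,
        config.applicator,
        config.depth_min,
        config.depth_max,
        seed=config.phantom_seed,
    )


def _build_table(config: RunConfig):
    library = (
        EnergyLibrary.from_json(config.library_path)
        if config.library_path
        else EnergyLibrary.default()
    )
    return build_r90_table(library)


def replay_summary(
    n_beam_positions: int,
    n_spots: int,
    n_energies: int,
    s_initial: float,
    s_final: float,
    machine: MachineParams = MachineParams(),
    prescription_gy: float = 15.0,
) -> tuple[TimeBreakdown, TimeBreakdown]:
    """Time-model breakdowns for a printed plan summary (no geometry needed)."""
    initial = delivery_time(
        PlanSummary(n_beam_positions, n_spots, n_energies, s_initial, prescription_gy),
        machine,
    )
    optimized = delivery_time(
        PlanSummary(n_beam_positions, n_spots, n_energies, s_final, prescription_gy),
        machine,
    )
    return initial, optimized
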