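"""End-to-end runs: synthetic head model -> montages -> fields -> curves.

``run_pipeline`` executes the full chain for one tumor case in one mode
(transcranial or intracranial) and writes its artifacts (mesh, electrode
layout, Pareto curves, optimal selection, summary) to an output directory.
Stages are cached on disk keyed by a content hash of the configuration
that feeds them, so re-runs with an unchanged configuration reuse the mesh
and lead-field basis, and any upstream change invalidates everything
downstream.

``compare_report`` mirrors the transcranial-vs-intracranial comparison:
coverage at the conventional 0.9 A, the ratio of required currents at 50%
coverage, and ROI field/TER histograms.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import electrodes as el
from . import meshing, mesh_io, optimize, solver
from .optimize import (
    Criterion,
    ROIDefinition,
    SweepResult,
    TER_ARREST,
    TER_POSITIVE,
)
from .ter import TERPolynomial

log = logging.getLogger("ttfsim")

#: Conventional transcranial TTF current level (A), used in reports.
CONVENTIONAL_CURRENT_A = 0.9

#: Tumor presets mimicking the three study cases on the spherical head:
#: a superficial ("temporal", with resection cavity), a deep-central
#: ("thalamic", with core) and an inferior ("brainstem") tumor.
TUMOR_PRESETS: Dict[str, meshing.TumorSpec] = {
    "superficial": meshing.TumorSpec(
        center=(45.0, 35.0, 20.0), shell_radius=12.0, resection_radius=7.0
    ),
    "deep": meshing.TumorSpec(center=(0.0, 0.0, 0.0), shell_radius=10.0, core_radius=6.0),
    "inferior": meshing.TumorSpec(center=(0.0, -15.0, -48.0), shell_radius=9.0),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults reproduce the study
    settings (2000-point current grid on [0, 2] A, 90% coverage target,
    0.9 A report line)."""

    mode: str = "intracranial"  # or "transcranial"
    tumor: Union[str, meshing.TumorSpec] = "deep"
    layer_radii: Sequence[float] = meshing.DEFAULT_LAYER_RADII
    resolution_mm: float = meshing.DEFAULT_RESOLUTION_MM
    wm_anisotropy_ratio: Optional[float] = None
    conductivity_overrides: Dict[str, float] = field(default_factory=dict)
    n_currents: int = 2000
    max_current_a: float = 2.0
    coverage_target_percent: float = 90.0
    top_k: int = 5
    seed: int = 0
    out_dir: Union[str, Path] = "ttfsim_run"

    def tumor_spec(self) -> meshing.TumorSpec:
        if isinstance(self.tumor, meshing.TumorSpec):
            return self.tumor
        return TUMOR_PRESETS[self.tumor]

    def current_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.max_current_a, self.n_currents)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        if "tumor" in data and isinstance(data["tumor"], dict):
            data["tumor"] = meshing.TumorSpec(**data["tumor"])
        return cls(**data)

    def content_hash(self, upstream: str = "", fields: Optional[Sequence[str]] = None) -> str:
        d = asdict(self)
        d["out_dir"] = None
        if isinstance(self.tumor, meshing.TumorSpec):
            d["tumor"] = asdict(self.tumor)
        if fields is not None:
            d = {k: d[k] for k in fields}
        blob = json.dumps(d, sort_keys=True, default=str) + upstream
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


_MESH_FIELDS = (
    "mode",
    "tumor",
    "layer_radii",
    "resolution_mm",
    "wm_anisotropy_ratio",
    "conductivity_overrides",
    "seed",
)


@dataclass
class RunResult:
    """In-memory handle on a completed pipeline run."""

    config: RunConfig
    mesh: meshing.HeadMesh
    roi: ROIDefinition
    sweeps: List[SweepResult]
    curves: Dict[str, optimize.CoverageCurve]
    selection: Optional[optimize.OptimalSelection]
    unit_magnitudes: Dict[str, np.ndarray]  # per config, |E| at 1 A on ROI
    out_dir: Path

    def coverage_at(self, current: float, criterion_name: str) -> Dict[str, float]:
        """Coverage (%) of every configuration at a given current."""
        out = {}
        for s in self.sweeps:
            if s.criterion != criterion_name:
                continue
            k = int(np.searchsorted(s.currents, current, side="right")) - 1
            out[s.config_name] = float(s.percents[max(k, 0)])
        return out


def _build_head(config: RunConfig) -> meshing.HeadMesh:
    spec = config.tumor_spec()
    refine = [(spec.center, r) for _, r in spec.nested_parts]
    mesh = meshing.build_layered_sphere_mesh(
        layer_radii=config.layer_radii,
        resolution=config.resolution_mm,
        refine_spheres=refine,
        seed=config.seed,
    )
    mesh = meshing.embed_tumor(mesh, spec)
    table = meshing.TissueConductivityTable.default().overridden(
        **config.conductivity_overrides
    )
    mesh = meshing.assign_conductivity(
        mesh, table, wm_anisotropy_ratio=config.wm_anisotropy_ratio
    )
    if config.mode == "intracranial":
        mesh = meshing.strip_to_intracranial(mesh)
    return mesh


def _cache_path(out_dir: Path, stage: str, h: str) -> Path:
    return out_dir / "cache" / f"{stage}-{h}.npz"


def run_pipeline(config: RunConfig) -> RunResult:
    """Run mesh -> layout -> (lead field | direct solves) -> sweeps -> curves
    -> optimal selection, writing artifacts under ``config.out_dir``."""
    if config.mode not in ("transcranial", "intracranial"):
        raise ValueError(f"unknown mode {config.mode!r}")
    out_dir = Path(config.out_dir)
    (out_dir / "cache").mkdir(parents=True, exist_ok=True)
    poly = TERPolynomial()
    t0 = time.time()

    # -- stage: head mesh ---------------------------------------------------
    mesh_hash = config.content_hash(fields=_MESH_FIELDS)
    mesh_cache = _cache_path(out_dir, "mesh", mesh_hash)
    if mesh_cache.exists():
        log.info("mesh: cache hit (%s)", mesh_hash)
        z = np.load(mesh_cache)
        mesh = meshing.HeadMesh(
            nodes=z["nodes"],
            elements=z["elements"],
            labels=z["labels"],
            conductivity=z["conductivity"],
        )
    else:
        log.info("mesh: building (%s mode)", config.mode)
        mesh = _build_head(config)
        np.savez_compressed(
            mesh_cache,
            nodes=mesh.nodes,
            elements=mesh.elements,
            labels=mesh.labels,
            conductivity=mesh.conductivity,
        )
        mesh_io.write_vtu(mesh, out_dir / "head_mesh.vtu")
    roi = ROIDefinition.from_mesh(mesh)
    log.info(
        "mesh: %d nodes, %d elements, ROI %d elements (%.0f mm^3) [%.1fs]",
        len(mesh.nodes), len(mesh.elements), len(roi.element_ids),
        roi.total_volume, time.time() - t0,
    )

    # -- stage: layout + solves --------------------------------------------
    system = solver.StiffnessSystem(mesh)
    criteria = (TER_POSITIVE, TER_ARREST)
    grid = config.current_grid()
    unit_mags: Dict[str, np.ndarray] = {}

    field_hash = config.content_hash(upstream=mesh_hash)
    field_cache = _cache_path(out_dir, "unitfields", field_hash)
    if field_cache.exists():
        log.info("fields: cache hit (%s)", field_hash)
        z = np.load(field_cache, allow_pickle=False)
        unit_mags = {name: z[name] for name in z.files}
    else:
        if config.mode == "transcranial":
            configs = el.make_transcranial_set(mesh)
            mesh_io.write_electrode_csv(
                [e for c in configs for e in c.electrodes], out_dir / "electrodes.csv"
            )
            for c in configs:
                sol = solver.solve_configuration(system, c, 1.0)
                unit_mags[c.name] = sol.magnitude[roi.element_ids]
        else:
            layout = el.place_intracranial_electrodes(mesh)
            mesh_io.write_electrode_csv(layout, out_dir / "electrodes.csv")
            basis = solver.build_lead_field(system, layout)
            pairs = el.enumerate_pairs(layout)
            log.info("lead field: %d basis solves, %d pairs", basis.n_electrodes, len(pairs))
            for c in pairs:
                i, j = c.electrodes[0].id, c.electrodes[1].id
                unit_mags[c.name] = basis.unit_pair_magnitude(i, j)[roi.element_ids]
        np.savez_compressed(field_cache, **unit_mags)
    log.info("fields: %d configurations [%.1fs]", len(unit_mags), time.time() - t0)

    # -- stage: sweeps, curves, selection ------------------------------------
    sweeps: List[SweepResult] = []
    for name, mag in unit_mags.items():
        for crit in criteria:
            sweeps.append(
                optimize.sweep_coverage(mag, roi, crit, grid, poly, config_name=name)
            )
    curves = optimize.build_pareto_curves(sweeps)
    try:
        selection = optimize.select_optimal(
            sweeps,
            target_percent=config.coverage_target_percent,
            criterion_name=TER_ARREST.name,
            top_k=config.top_k,
        )
    except optimize.OptimizationError as exc:
        log.warning("selection: %s", exc)
        selection = None

    _write_artifacts(out_dir, config, curves, selection)
    log.info("pipeline done [%.1fs]", time.time() - t0)
    return RunResult(
        config=config,
        mesh=mesh,
        roi=roi,
        sweeps=sweeps,
        curves=curves,
        selection=selection,
        unit_magnitudes=unit_mags,
        out_dir=out_dir,
    )


def _write_artifacts(
    out_dir: Path,
    config: RunConfig,
    curves: Dict[str, optimize.CoverageCurve],
    selection: Optional[optimize.OptimalSelection],
) -> None:
    rows = []
    for crit, curve in sorted(curves.items()):
        for p, c, name in zip(curve.percents, curve.min_currents, curve.config_names):
            rows.append(
                {
                    "criterion": crit,
                    "percent": int(p),
                    "min_current_a": c,
                    "config": name if name is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "pareto_curves.csv", index=False)

    summary = {
        "mode": config.mode,
        "tumor": config.tumor if isinstance(config.tumor, str) else asdict(config.tumor),
        "coverage_target_percent": config.coverage_target_percent,
    }
    if selection is not None:
        summary["optimal"] = {
            "criterion": selection.criterion,
            "winner": selection.winner,
            "required_current_a": selection.required_current,
            "near_optimal": [
                {"config": n, "required_current_a": c} for n, c in selection.ranking
            ],
            "first_to_last_spread_percent": selection.relative_spread_percent,
        }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------

def _best_coverage_at(run: RunResult, current: float, criterion_name: str) -> float:
    cov = run.coverage_at(current, criterion_name)
    return max(cov.values()) if cov else 0.0


def histogram_roi(
    run: RunResult,
    config_name: str,
    current: float,
    bins: np.ndarray,
    kind: str = "field",
) -> Tuple[np.ndarray, np.ndarray]:
    """Volume-weighted ROI histogram (percent of ROI volume per bin) of
    field strength (V/cm) or TER at the given current."""
    mag = run.unit_magnitudes[config_name] * current
    values = mag if kind == "field" else TERPolynomial().ter_of_field(mag)
    weights = 100.0 * run.roi.volumes / run.roi.total_volume
    hist, edges = np.histogram(values, bins=bins, weights=weights)
    return hist, edges


def compare_report(
    transcranial: RunResult,
    intracranial: RunResult,
    current: float = CONVENTIONAL_CURRENT_A,
    coverage_percent: float = 50.0,
    out_path: Optional[Union[str, Path]] = None,
) -> Dict:
    """Side-by-side comparison of a transcranial and an intracranial run on
    the same tumor: best coverage at the conventional current, and the ratio
    of required currents at the coverage level ``coverage_percent``."""
    t_spec, i_spec = transcranial.config.tumor_spec(), intracranial.config.tumor_spec()
    if t_spec != i_spec:
        raise ValueError("runs must share the same tumor specification")

    report: Dict = {"current_a": current, "coverage_percent": coverage_percent}
    for crit in (TER_POSITIVE.name, TER_ARREST.name):
        entry: Dict = {}
        entry["transcranial_best_coverage_at_current"] = _best_coverage_at(
            transcranial, current, crit
        )
        entry["intracranial_best_coverage_at_current"] = _best_coverage_at(
            intracranial, current, crit
        )
        req_t = transcranial.curves[crit].required_current(coverage_percent)
        req_i = intracranial.curves[crit].required_current(coverage_percent)
        entry["transcranial_required_current_a"] = req_t
        entry["intracranial_required_current_a"] = req_i
        entry["current_ratio_trans_over_intra"] = (
            req_t / req_i if np.isfinite(req_t) and np.isfinite(req_i) and req_i > 0
            else np.nan
        )
        report[crit] = entry

    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=1, default=float))
    return report
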