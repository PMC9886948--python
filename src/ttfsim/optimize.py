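"""Coverage statistics and current/coverage Pareto optimization.

For each electrode configuration, coverage is the volume-weighted
percentage of the tumor ROI meeting a criterion (TER > t, or field
strength E > tau V/cm) at a given injected current. Because the field is
linear in the current, every criterion reduces to a per-element threshold
current I_e = tau_field / |E_unit|_e, so a full sweep over the current grid
is a cumulative-volume sort rather than repeated field solves.

The Pareto front ("coverage curve") records, for each integer coverage bin
p in 0..100, the minimum current over all configurations that achieves
coverage >= p, and which configuration achieves it. The optimal montage is
the one needing the least current for TER > 1 in at least 90% of the ROI;
near-optimal alternatives are the next-cheapest configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .solver import LeadFieldBasis
from .ter import TERPolynomial

#: The paper-standard current grid: 2000 values linearly spaced on [0, 2] A,
#: endpoints included.
DEFAULT_CURRENT_GRID = np.linspace(0.0, 2.0, 2000)

DEFAULT_COVERAGE_TARGET = 90.0
DEFAULT_TOP_K = 5


class OptimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Criterion:
    """Coverage criterion: either ('ter', t) or ('field', tau V/cm).

    Strict inequality (value > threshold). TER criteria are converted to
    equivalent field-strength thresholds through the monotone dose-response:
    TER > 0 corresponds to E >= the lower cap, TER > 1 to the arrest field.
    """

    kind: str  # "ter" | "field"
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in ("ter", "field"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "ter":
            return f"TER>{self.threshold:g}"
        return f"E>{self.threshold:g}V/cm"

    def field_threshold(self, poly: Optional[TERPolynomial] = None) -> float:
        """Equivalent field-strength threshold in V/cm (may be inf if the
        TER level is unreachable under the cap)."""
        if self.kind == "field":
            return self.threshold
        poly = poly or TERPolynomial()
        if self.threshold < 0:
            return 0.0
        if self.threshold >= poly.cap:
            return np.inf
        if self.threshold == 0.0:
            # TER > 0 exactly when E >= e_low (the cubic is positive there)
            return poly.e_low
        return poly.field_for_ter(self.threshold)


TER_POSITIVE = Criterion("ter", 0.0)
TER_ARREST = Criterion("ter", 1.0)


@dataclass
class ROIDefinition:
    """Region of interest: element ids and their volumes (mm^3).

    The ROI is all tumor tissue — shell plus core where present (the
    CSF-filled resection cavity is not tumor)."""

    element_ids: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.element_ids = np.asarray(self.element_ids, dtype=np.int64)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.element_ids.size == 0:
            raise ValueError("ROI must be non-empty")
        if self.element_ids.shape != self.volumes.shape:
            raise ValueError("one volume per ROI element required")
        if (self.volumes <= 0).any():
            raise ValueError("ROI element volumes must be positive")

    @classmethod
    def from_mesh(cls, mesh, labels: Sequence[str] = ("tumor_shell", "tumor_core")):
        from .tissues import TISSUE_IDS

        ids = np.flatnonzero(np.isin(mesh.labels, [TISSUE_IDS[l] for l in labels]))
        if ids.size == 0:
            raise ValueError(f"mesh has no elements labeled {list(labels)}")
        return cls(ids, mesh.element_volumes()[ids])

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())


@dataclass(frozen=True)
class CoverageResult:
    """Coverage of one configuration at one current for one criterion."""

    config_name: str
    current: float
    criterion: str
    percent: float


def roi_coverage(
    values: np.ndarray,
    roi: ROIDefinition,
    criterion: Criterion,
    value_kind: str = "field",
    poly: Optional[TERPolynomial] = None,
    config_name: str = "",
    current: float = np.nan,
) -> CoverageResult:
    """Volume-weighted percent of the ROI where the map exceeds the criterion.

    ``values`` is a per-element map over the whole mesh (field magnitudes in
    V/cm or TER values, stated by ``value_kind``); it must cover every ROI
    element.
    """
    values = np.asarray(values)
    if roi.element_ids.max() >= len(values):
        raise OptimizationError("ROI element missing from the supplied map")
    v = values[roi.element_ids]
    if criterion.kind == value_kind:
        meets = v > criterion.threshold
    elif criterion.kind == "ter" and value_kind == "field":
        tau = criterion.field_threshold(poly)
        # TER > 0 includes the closed lower boundary E = e_low
        meets = v >= tau if criterion.threshold == 0.0 else v > tau
    else:
        raise OptimizationError(
            f"cannot evaluate {criterion.kind!r} criterion on {value_kind!r} map"
        )
    pct = 100.0 * float(roi.volumes[meets].sum()) / roi.total_volume
    return CoverageResult(config_name, current, criterion.name, pct)


# ---------------------------------------------------------------------------
# current sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Coverage as a function of current for one configuration/criterion."""

    config_name: str
    criterion: str
    currents: np.ndarray
    percents: np.ndarray  # same length, non-decreasing

    def required_current(self, percent: float) -> float:
        """Smallest grid current achieving coverage >= percent (nan if none)."""
        ok = np.flatnonzero(self.percents >= percent)
        if ok.size == 0:
            return np.nan
        return float(self.currents[ok[0]])


def _threshold_currents(unit_magnitude_roi: np.ndarray, field_threshold: float) -> np.ndarray:
    """Per-element current (A) at which the element crosses the threshold."""
    with np.errstate(divide="ignore"):
        return np.where(
            unit_magnitude_roi > 0, field_threshold / unit_magnitude_roi, np.inf
        )


def sweep_coverage(
    unit_magnitude_roi: np.ndarray,
    roi: ROIDefinition,
    criterion: Criterion,
    currents: np.ndarray = DEFAULT_CURRENT_GRID,
    poly: Optional[TERPolynomial] = None,
    config_name: str = "",
) -> SweepResult:
    """Coverage vs current for one configuration, by threshold-current sort.

    ``unit_magnitude_roi`` is |E| per ROI element at 1 A (V/cm). For each
    element the crossing current is tau/|E_unit|; sorting elements by
    crossing current makes coverage at any I a cumulative volume lookup.
    """
    tau = criterion.field_threshold(poly)
    if not np.isfinite(tau):
        pct = np.zeros(len(currents))
        return SweepResult(config_name, criterion.name, np.asarray(currents), pct)
    thr = _threshold_currents(unit_magnitude_roi, tau)
    order = np.argsort(thr)
    thr_sorted = thr[order]
    cumvol = np.cumsum(roi.volumes[order])
    # coverage(I) = cumulative volume of elements with threshold current <= I
    # (strict vs non-strict differs on a measure-zero set of currents; the
    # TER>0 closed boundary is handled by its threshold field, not here)
    counts = np.searchsorted(thr_sorted, np.asarray(currents), side="right")
    covered = np.where(counts > 0, cumvol[np.maximum(counts - 1, 0)], 0.0)
    pct = 100.0 * covered / roi.total_volume
    pct[np.asarray(currents) <= 0.0] = 0.0
    return SweepResult(config_name, criterion.name, np.asarray(currents), pct)


def sweep_currents(
    basis: LeadFieldBasis,
    pair: Tuple[int, int],
    roi: ROIDefinition,
    criteria: Sequence[Criterion],
    currents: np.ndarray = DEFAULT_CURRENT_GRID,
    poly: Optional[TERPolynomial] = None,
) -> List[SweepResult]:
    """Sweep the current grid for one electrode pair and several criteria."""
    i, j = pair
    unit_mag = basis.unit_pair_magnitude(i, j)[roi.element_ids]
    name = f"pair_{i}_{j}"
    return [
        sweep_coverage(unit_mag, roi, c, currents, poly, config_name=name)
        for c in criteria
    ]


# ---------------------------------------------------------------------------
# Pareto curves and selection
# ---------------------------------------------------------------------------

@dataclass
class CoverageCurve:
    """Per integer coverage bin p (0..100): minimum current over all
    configurations achieving coverage >= p, and the achieving configuration.
    Unreachable bins hold nan / None."""

    criterion: str
    percents: np.ndarray  # 0..100
    min_currents: np.ndarray  # (101,) A, nan where unreachable
    config_names: List[Optional[str]]

    def required_current(self, percent: float) -> float:
        p = int(np.ceil(percent))
        return float(self.min_currents[p])


def build_pareto_curves(
    sweeps: Sequence[SweepResult],
) -> Dict[str, CoverageCurve]:
    """Bin all configuration sweeps into per-criterion Pareto curves.

    Ties on minimum current are broken by the order configurations appear
    in ``sweeps`` (ascending configuration id when produced in id order).
    """
    if not sweeps:
        raise OptimizationError("no sweep results to bin")
    by_crit: Dict[str, List[SweepResult]] = {}
    for s in sweeps:
        by_crit.setdefault(s.criterion, []).append(s)

    percents = np.arange(101)
    curves: Dict[str, CoverageCurve] = {}
    for crit, group in by_crit.items():
        best = np.full(101, np.nan)
        names: List[Optional[str]] = [None] * 101
        for s in group:
            # required current per bin for this configuration
            idx = np.searchsorted(s.percents, percents, side="left")
            reach = idx < len(s.currents)
            req = np.where(reach, s.currents[np.minimum(idx, len(s.currents) - 1)], np.nan)
            better = np.isnan(best) | (req < best)
            better &= ~np.isnan(req)
            for p in np.flatnonzero(better):
                names[p] = s.config_name
            best = np.where(better, req, best)
        # coverage >= p is monotone in p, so the curve must be non-decreasing
        if not _non_decreasing_ignoring_nan(best):
            raise OptimizationError("Pareto curve not monotone; inconsistent sweeps")
        curves[crit] = CoverageCurve(crit, percents, best, names)
    return curves


def _non_decreasing_ignoring_nan(a: np.ndarray) -> bool:
    vals = a[~np.isnan(a)]
    return bool((np.diff(vals) >= -1e-12).all())


@dataclass
class OptimalSelection:
    """Winner and near-optimal alternatives at a coverage target."""

    criterion: str
    target_percent: float
    winner: str
    required_current: float
    ranking: List[Tuple[str, float]]  # (config, required current), ascending

    @property
    def relative_spread_percent(self) -> float:
        """Current difference between first and last ranked solution, as a
        percentage of the winner's current."""
        if len(self.ranking) < 2:
            return 0.0
        first, last = self.ranking[0][1], self.ranking[-1][1]
        return 100.0 * (last - first) / first


def select_optimal(
    sweeps: Sequence[SweepResult],
    target_percent: float = DEFAULT_COVERAGE_TARGET,
    criterion_name: Optional[str] = None,
    top_k: int = DEFAULT_TOP_K,
) -> OptimalSelection:
    """Rank configurations by the current required to reach the coverage
    target; return the winner and the top-k near-optimal list."""
    group = [
        s
        for s in sweeps
        if criterion_name is None or s.criterion == criterion_name
    ]
    if not group:
        raise OptimizationError("no sweeps for the requested criterion")
    crit = group[0].criterion
    reqs = []
    for s in group:
        r = s.required_current(target_percent)
        if not np.isnan(r):
            reqs.append((s.config_name, r))
    if not reqs:
        max_cov = max(float(s.percents.max()) for s in group)
        raise OptimizationError(
            f"coverage target {target_percent}% unreachable; maximum achieved "
            f"coverage is {max_cov:.1f}%"
        )
    reqs.sort(key=lambda t: (t[1], t[0]))
    top = reqs[:top_k]
    return OptimalSelection(
        criterion=crit,
        target_percent=target_percent,
        winner=top[0][0],
        required_current=top[0][1],
        ranking=top,
    )


def field_threshold_analysis(
    basis: LeadFieldBasis,
    pairs: Sequence[Tuple[int, int]],
    roi: ROIDefinition,
    thresholds: Optional[Sequence[float]] = None,
    currents: np.ndarray = DEFAULT_CURRENT_GRID,
) -> Dict[str, CoverageCurve]:
    """Pareto curves for field-strength criteria E > tau, tau = 1.0..3.0 V/cm
    in 0.1 steps by default."""
    if thresholds is None:
        thresholds = np.round(np.arange(1.0, 3.0 + 1e-9, 0.1), 10)
    criteria = [Criterion("field", float(t)) for t in thresholds]
    sweeps: List[SweepResult] = []
    for i, j in pairs:
        unit_mag = basis.unit_pair_magnitude(i, j)[roi.element_ids]
        for c in criteria:
            sweeps.append(
                sweep_coverage(unit_mag, roi, c, currents, config_name=f"pair_{i}_{j}")
            )
    return build_pareto_curves(sweeps)
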