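"""Coverage, current sweeps, Pareto binning: checked against brute force."""

import numpy as np
import pytest

from ttfsim import optimize as opt
from ttfsim.optimize import (
    Criterion,
    ROIDefinition,
    SweepResult,
    TER_ARREST,
    TER_POSITIVE,
    build_pareto_curves,
    roi_coverage,
    select_optimal,
    sweep_coverage,
)
from ttfsim.ter import TERPolynomial

POLY = TERPolynomial()


def toy_roi(volumes=(1.0, 2.0, 3.0, 4.0)):
    return ROIDefinition(np.arange(len(volumes)), np.asarray(volumes))


def naive_sweep(unit_mag, roi, criterion, currents, poly=POLY):
    """Oracle: recompute the criterion map at every current from scratch."""
    pcts = []
    for i_amp in currents:
        field = unit_mag * i_amp
        if criterion.kind == "ter":
            vals = poly.ter_of_field(field)
            meets = vals > criterion.threshold
        else:
            meets = field > criterion.threshold
        pcts.append(100.0 * roi.volumes[meets].sum() / roi.volumes.sum())
    return np.asarray(pcts)


class TestROICoverage:
    def test_uniform_cap_field_fully_covered(self):
        roi = toy_roi()
        res = roi_coverage(np.full(4, 2.40), roi, TER_ARREST, value_kind="field")
        assert res.percent == 100.0

    def test_zero_field_no_coverage(self):
        roi = toy_roi()
        for crit in (TER_POSITIVE, TER_ARREST, Criterion("field", 1.0)):
            assert roi_coverage(np.zeros(4), roi, crit).percent == 0.0

    def test_half_volume_above_threshold(self):
        # elements 2, 3 (volumes 3 + 4 = 7 of 10) above 2 V/cm
        roi = toy_roi((3.0, 7.0, 4.0, 6.0))  # first two below -> 10/20 = 50%
        field = np.array([1.0, 1.5, 2.5, 3.0])
        res = roi_coverage(field, roi, Criterion("field", 2.0))
        assert res.percent == 50.0

    def test_volume_weighting_matters(self):
        roi = ROIDefinition(np.array([0, 1]), np.array([1.0, 9.0]))
        field = np.array([3.0, 0.0])
        res = roi_coverage(field, roi, Criterion("field", 2.0))
        assert res.percent == 10.0

    def test_missing_element_rejected(self):
        roi = ROIDefinition(np.array([5]), np.array([1.0]))
        with pytest.raises(opt.OptimizationError):
            roi_coverage(np.zeros(3), roi, TER_POSITIVE)

    def test_ter_map_input(self):
        roi = toy_roi((1.0, 1.0, 1.0, 1.0))
        ter_vals = np.array([0.0, 0.5, 1.1, 1.2])
        res = roi_coverage(ter_vals, roi, TER_ARREST, value_kind="ter")
        assert res.percent == 50.0


class TestCriterion:
    def test_ter_positive_threshold_is_lower_cap(self):
        assert TER_POSITIVE.field_threshold(POLY) == POLY.e_low

    def test_ter_arrest_threshold_is_growth_arrest_field(self):
        assert TER_ARREST.field_threshold(POLY) == pytest.approx(2.2322, abs=1e-3)

    def test_unreachable_ter_gives_infinite_threshold(self):
        assert Criterion("ter", 5.0).field_threshold(POLY) == np.inf

    def test_field_criterion_passthrough(self):
        assert Criterion("field", 2.25).field_threshold() == 2.25


class TestSweep:
    def test_matches_naive_recalculation(self):
        rng = np.random.default_rng(0)
        roi = toy_roi()
        unit_mag = rng.uniform(0.5, 4.0, 4)
        currents = np.linspace(0.0, 2.0, 10)
        for crit in (TER_POSITIVE, TER_ARREST, Criterion("field", 2.25)):
            fast = sweep_coverage(unit_mag, roi, crit, currents, POLY)
            naive = naive_sweep(unit_mag, roi, crit, currents)
            assert np.allclose(fast.percents, naive), crit.name

    def test_coverage_non_decreasing_in_current(self):
        rng = np.random.default_rng(1)
        roi = toy_roi((2.0, 1.0, 4.0, 3.0))
        unit_mag = rng.uniform(0.1, 5.0, 4)
        sweep = sweep_coverage(unit_mag, roi, TER_ARREST, np.linspace(0, 2, 200), POLY)
        assert (np.diff(sweep.percents) >= 0).all()
        assert sweep.percents[-1] == max(sweep.percents)

    def test_zero_current_zero_coverage(self):
        roi = toy_roi()
        sweep = sweep_coverage(np.full(4, 10.0), roi, TER_POSITIVE, np.linspace(0, 2, 5), POLY)
        assert sweep.percents[0] == 0.0

    def test_required_current(self):
        roi = toy_roi((1.0, 1.0, 1.0, 1.0))
        unit_mag = np.array([4.0, 2.0, 1.0, 0.5])  # V/cm per A
        currents = np.linspace(0.0, 2.0, 2001)  # grid step 1 mA
        sweep = sweep_coverage(unit_mag, roi, Criterion("field", 2.0), currents)
        # thresholds: 0.5, 1.0, 2.0, 4.0 A -> 75% reachable at 2 A
        assert sweep.required_current(50.0) == pytest.approx(1.0, abs=1e-3)
        assert sweep.required_current(75.0) == pytest.approx(2.0, abs=1e-3)
        assert np.isnan(sweep.required_current(80.0))


class TestPareto:
    def _sweeps(self, mags, currents, criteria=(TER_POSITIVE, TER_ARREST)):
        roi = toy_roi((1.0, 1.0, 2.0, 2.0))
        out = []
        for name, mag in mags.items():
            for crit in criteria:
                out.append(
                    sweep_coverage(np.asarray(mag), roi, crit, currents, POLY, config_name=name)
                )
        return roi, out

    def test_single_config_curve_is_its_own(self):
        currents = np.linspace(0.0, 2.0, 50)
        roi, sweeps = self._sweeps({"a": [2.0, 2.0, 2.0, 2.0]}, currents)
        curves = build_pareto_curves(sweeps)
        s = next(s for s in sweeps if s.criterion == TER_ARREST.name)
        curve = curves[TER_ARREST.name]
        for p in (10, 50, 100):
            assert curve.min_currents[p] == s.required_current(p)
            assert curve.config_names[p] == "a"

    def test_adding_config_never_hurts(self):
        currents = np.linspace(0.0, 2.0, 100)
        _, s1 = self._sweeps({"a": [2.0, 1.0, 3.0, 0.8]}, currents)
        _, s2 = self._sweeps({"a": [2.0, 1.0, 3.0, 0.8], "b": [4.0, 0.5, 1.0, 2.0]}, currents)
        c1 = build_pareto_curves(s1)
        c2 = build_pareto_curves(s2)
        for crit in c1:
            a = c1[crit].min_currents
            b = c2[crit].min_currents
            both = ~np.isnan(a) & ~np.isnan(b)
            assert (b[both] <= a[both] + 1e-12).all()
            assert (~np.isnan(b) | np.isnan(a)).all()

    def test_three_config_toy_matches_brute_force(self):
        rng = np.random.default_rng(7)
        currents = np.linspace(0.0, 2.0, 9)
        mags = {f"c{k}": rng.uniform(0.3, 4.0, 4) for k in range(3)}
        roi, sweeps = self._sweeps(mags, currents)
        curves = build_pareto_curves(sweeps)
        for crit in (TER_POSITIVE, TER_ARREST):
            tau = crit.field_threshold(POLY)
            for p in range(101):
                # brute force over configs x currents
                best, best_name = np.inf, None
                for name in sorted(mags):
                    mag = np.asarray(mags[name])
                    for i_amp in currents:
                        field = mag * i_amp
                        meets = (
                            field >= tau if crit.threshold == 0.0 else field > tau
                        )
                        cov = 100.0 * roi.volumes[meets].sum() / roi.volumes.sum()
                        if i_amp == 0.0:
                            cov = 0.0
                        if cov >= p and i_amp < best:
                            best, best_name = i_amp, name
                curve = curves[crit.name]
                if np.isinf(best):
                    assert np.isnan(curve.min_currents[p])
                else:
                    assert curve.min_currents[p] == pytest.approx(best)
                    assert curve.config_names[p] == best_name

    def test_curve_monotone(self):
        rng = np.random.default_rng(3)
        currents = np.linspace(0.0, 2.0, 64)
        mags = {f"c{k}": rng.uniform(0.2, 5.0, 4) for k in range(4)}
        _, sweeps = self._sweeps(mags, currents)
        for curve in build_pareto_curves(sweeps).values():
            vals = curve.min_currents[~np.isnan(curve.min_currents)]
            assert (np.diff(vals) >= -1e-12).all()

    def test_arrest_curve_at_or_above_positive_curve(self):
        rng = np.random.default_rng(5)
        currents = np.linspace(0.0, 2.0, 128)
        mags = {f"c{k}": rng.uniform(0.2, 5.0, 4) for k in range(3)}
        _, sweeps = self._sweeps(mags, currents)
        curves = build_pareto_curves(sweeps)
        pos, arr = curves[TER_POSITIVE.name], curves[TER_ARREST.name]
        both = ~np.isnan(pos.min_currents) & ~np.isnan(arr.min_currents)
        assert (arr.min_currents[both] >= pos.min_currents[both] - 1e-12).all()

    def test_empty_sweeps_rejected(self):
        with pytest.raises(opt.OptimizationError):
            build_pareto_curves([])


class TestSelection:
    def _sweeps(self, mags, currents=np.linspace(0.0, 2.0, 201)):
        roi = toy_roi((1.0, 1.0, 1.0, 1.0))
        return [
            sweep_coverage(np.asarray(m), roi, TER_ARREST, currents, POLY, config_name=n)
            for n, m in mags.items()
        ]

    def test_dominant_pair_selected(self):
        sweeps = self._sweeps({"weak": [1.0, 1.0, 1.0, 1.0], "strong": [9.0, 9.0, 9.0, 9.0]})
        sel = select_optimal(sweeps, target_percent=90.0)
        assert sel.winner == "strong"

    def test_top_k_1_returns_only_winner(self):
        sweeps = self._sweeps({"a": [3.0] * 4, "b": [4.0] * 4})
        sel = select_optimal(sweeps, target_percent=90.0, top_k=1)
        assert len(sel.ranking) == 1
        assert sel.winner == "b"

    def test_topk_matches_exhaustive_sort(self):
        rng = np.random.default_rng(11)
        mags = {f"c{k}": list(rng.uniform(1.5, 6.0, 4)) for k in range(8)}
        sweeps = self._sweeps(mags)
        sel = select_optimal(sweeps, target_percent=90.0, top_k=5)
        brute = sorted(
            (s.required_current(90.0), s.config_name)
            for s in sweeps
            if not np.isnan(s.required_current(90.0))
        )[:5]
        assert [(n, c) for c, n in brute] == sel.ranking

    def test_relative_spread(self):
        sweeps = self._sweeps({"a": [3.0] * 4, "b": [2.0] * 4})
        sel = select_optimal(sweeps, target_percent=90.0, top_k=2)
        first, last = sel.ranking[0][1], sel.ranking[1][1]
        assert sel.relative_spread_percent == pytest.approx(100 * (last - first) / first)

    def test_unreachable_target_reports_max_coverage(self):
        sweeps = self._sweeps({"weak": [0.1, 0.1, 0.1, 0.1]})
        with pytest.raises(opt.OptimizationError, match="maximum achieved"):
            select_optimal(sweeps, target_percent=90.0)


class TestFieldThresholdAnalysis:
    def test_threshold_scaling_identity(self):
        """Doubling tau doubles the whole required-current curve (linearity)."""
        roi = toy_roi()
        rng = np.random.default_rng(2)
        unit_mag = rng.uniform(0.5, 4.0, 4)
        # use an exact dyadic grid so scaled currents land on grid points
        currents = np.linspace(0.0, 4.0, 4097)
        s1 = sweep_coverage(unit_mag, roi, Criterion("field", 1.0), currents)
        s2 = sweep_coverage(unit_mag, roi, Criterion("field", 2.0), currents)
        for p in (25, 50, 75, 100):
            r1, r2 = s1.required_current(p), s2.required_current(p)
            if not (np.isnan(r1) or np.isnan(r2)):
                assert r2 == pytest.approx(2.0 * r1, abs=2e-3)

    def test_default_thresholds_include_benchmark(self, coarse_intracranial, coarse_intracranial_system):
        from ttfsim import electrodes as el
        from ttfsim import solver as sv

        layout = el.place_intracranial_electrodes(coarse_intracranial)
        ref = next(e for e in layout if e.role == "reference")
        subset = [e for e in layout if e.role == "stimulation"][:3] + [ref]
        basis = sv.build_lead_field(coarse_intracranial_system, subset)
        ids = basis.electrode_ids
        roi = ROIDefinition(
            np.arange(100), coarse_intracranial.element_volumes()[:100]
        )
        curves = opt.field_threshold_analysis(
            basis, [(ids[0], ids[1])], roi, currents=np.linspace(0, 2, 50)
        )
        names = set(curves)
        assert "E>2.25V/cm" not in names  # default grid is 1.0..3.0 by 0.1
        assert {"E>1V/cm", "E>2V/cm", "E>3V/cm"} <= names
        custom = opt.field_threshold_analysis(
            basis, [(ids[0], ids[1])], roi, thresholds=[2.25],
            currents=np.linspace(0, 2, 50),
        )
        assert "E>2.25V/cm" in custom

    def test_sweep_currents_over_lead_field_pair(
        self, coarse_intracranial, coarse_intracranial_system
    ):
        from ttfsim import electrodes as el
        from ttfsim import solver as sv

        layout = el.place_intracranial_electrodes(coarse_intracranial)
        ref = next(e for e in layout if e.role == "reference")
        subset = [e for e in layout if e.role == "stimulation"][:2] + [ref]
        basis = sv.build_lead_field(coarse_intracranial_system, subset)
        i, j = basis.electrode_ids[:2]
        roi = ROIDefinition(np.arange(50), coarse_intracranial.element_volumes()[:50])
        currents = np.linspace(0.0, 2.0, 30)
        sweeps = opt.sweep_currents(
            basis, (i, j), roi, (TER_POSITIVE, TER_ARREST), currents, POLY
        )
        assert [s.criterion for s in sweeps] == ["TER>0", "TER>1"]
        unit_mag = basis.unit_pair_magnitude(i, j)[roi.element_ids]
        for s, crit in zip(sweeps, (TER_POSITIVE, TER_ARREST)):
            assert np.allclose(s.percents, naive_sweep(unit_mag, roi, crit, currents))

    def test_lower_threshold_curve_dominates(self):
        roi = toy_roi()
        rng = np.random.default_rng(9)
        unit_mag = rng.uniform(0.5, 4.0, 4)
        currents = np.linspace(0.0, 2.0, 500)
        lo = sweep_coverage(unit_mag, roi, Criterion("field", 1.0), currents)
        hi = sweep_coverage(unit_mag, roi, Criterion("field", 3.0), currents)
        assert (lo.percents >= hi.percents).all()


def test_count_equals_volume_weighting_on_uniform_mesh():
    roi_u = ROIDefinition(np.arange(6), np.full(6, 2.5))
    field = np.array([0.5, 1.2, 2.0, 2.5, 3.0, 0.1])
    res = roi_coverage(field, roi_u, Criterion("field", 1.5))
    assert res.percent == pytest.approx(100.0 * 3 / 6)
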