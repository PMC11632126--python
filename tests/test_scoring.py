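"""Plan scoring, dose renormalization, and prescription scaling."""

import numpy as np
import pytest

from dvhscore import (
    DoseGrid,
    MissingStructure,
    PlanRecord,
    Scorecard,
    ScoreFunction,
    ScoreMetric,
    StructureMask,
    StructureSet,
    builtin_scorecard,
    compute_dvh,
    dose_at_volume,
    evaluate_metric,
    homogeneity_index,
    normalize_to_max,
    parse_metric_text,
    scale_prescription,
    score_plan,
    volume_at_dose,
)
from dvhscore.scorecard import MEAN_DOSE
from conftest import dense_grid_max
from dvhscore.scoring import _build_objective


def _uniform_plan(value=20.0, rx=20.0, name="PTV_WB"):
    dose = DoseGrid(np.full((4, 4, 4), value), (2, 2, 2))
    s = StructureSet()
    s.add(StructureMask(name, np.ones((4, 4, 4)), (2, 2, 2)))
    s.add(StructureMask("BODY", np.ones((4, 4, 4)), (2, 2, 2)))
    return PlanRecord(plan_id="u", rx_gy=rx, dose=dose, structures=s)


def _card(metrics, rx=20.0, name="test", scalable=True):
    return Scorecard(name=name, rx_gy=rx, metrics=tuple(metrics), scalable=scalable)


class TestEvaluateMetric:
    def test_uniform_rx_coverage_is_100(self):
        plan = _uniform_plan()
        spec = parse_metric_text("Volume at 100% [%]", structure="PTV_WB")
        assert evaluate_metric(plan, spec) == pytest.approx(100.0)

    def test_max_dose_percent_of_rx(self):
        plan = _uniform_plan(value=33.0, rx=30.0)
        spec = parse_metric_text("MaxDose [%]", structure="PTV_WB")
        assert evaluate_metric(plan, spec) == pytest.approx(110.0)

    def test_every_card_metric_matches_direct_dvh_calls(self, phantom_plan):
        """The dispatch layer agrees with direct metric computation."""
        from dvhscore import conformation_number
        from dvhscore.scorecard import (
            CONFORMATION_NUMBER, DOSE_AT_VOLUME_CC, DOSE_AT_VOLUME_PCT,
            HOMOGENEITY_INDEX, MAX_DOSE, MEAN_DOSE, MIN_DOSE, UNIT_CC,
            UNIT_PERCENT_RX, VOLUME_AT_DOSE_ABS, VOLUME_AT_DOSE_REL,
        )
        plan = phantom_plan
        card = builtin_scorecard("HLS-EC-WB")
        plan.prepare(card)
        for m in card.metrics:
            spec = m.spec
            got = evaluate_metric(plan, spec)
            if spec.kind == CONFORMATION_NUMBER:
                expected = conformation_number(
                    plan.dose, plan.mask(spec.structure), plan.mask("BODY"),
                    spec.parameter)
            else:
                curve = plan.dvh(spec.structure)
                if spec.kind == DOSE_AT_VOLUME_PCT:
                    expected = dose_at_volume(curve, spec.parameter)
                elif spec.kind == DOSE_AT_VOLUME_CC:
                    expected = dose_at_volume(curve, spec.parameter, "cc")
                elif spec.kind == MIN_DOSE:
                    expected = curve.min_dose
                elif spec.kind == MEAN_DOSE:
                    expected = curve.mean_dose
                elif spec.kind == MAX_DOSE:
                    expected = curve.max_dose
                    if spec.value_unit == UNIT_PERCENT_RX:
                        expected = 100.0 * expected / plan.rx_gy
                elif spec.kind == HOMOGENEITY_INDEX:
                    expected = homogeneity_index(curve, spec.parameter)
                elif spec.kind in (VOLUME_AT_DOSE_ABS, VOLUME_AT_DOSE_REL):
                    level = spec.parameter
                    if spec.kind == VOLUME_AT_DOSE_REL:
                        level = level / 100.0 * plan.rx_gy
                    unit = "cc" if spec.value_unit == UNIT_CC else "percent"
                    expected = volume_at_dose(curve, level, unit)
            assert got == pytest.approx(expected, abs=1e-12), spec.metric_text

    def test_missing_structure(self):
        plan = _uniform_plan()
        with pytest.raises(MissingStructure):
            evaluate_metric(plan, parse_metric_text("MeanDose [Gy]", structure="Liver"))

    def test_ptv_alias_fallback(self):
        plan = _uniform_plan(name="PTV_WB")
        spec = parse_metric_text("MeanDose [Gy]", structure="PTV_3000")
        assert evaluate_metric(plan, spec) == pytest.approx(20.0)


class TestScorePlan:
    def test_perfect_plan_reaches_card_total(self):
        plan = _uniform_plan(value=20.0)
        metrics = (
            ScoreMetric(0, parse_metric_text("MeanDose [Gy]", structure="PTV_WB"),
                        ScoreFunction(((18.0, 0.0), (20.0, 10.0))), 10.0),
            ScoreMetric(1, parse_metric_text("Volume at 100% [%]", structure="PTV_WB"),
                        ScoreFunction(((95.0, 0.0), (100.0, 5.0))), 5.0),
        )
        res = score_plan(plan, _card(metrics))
        assert res.total_points == pytest.approx(15.0)
        assert res.percent_of_max == pytest.approx(100.0)

    def test_lenient_vs_strict_differ_by_missing_metric(self, phantom_plan):
        card = builtin_scorecard("HLS-EC-WB")
        full = score_plan(phantom_plan, card)
        # drop one OAR from a copy of the structure set
        s2 = StructureSet(dict(phantom_plan.structures.masks))
        del s2.masks["OpticChiasm"]
        plan2 = PlanRecord(plan_id="p2", rx_gy=phantom_plan.rx_gy,
                           dose=phantom_plan.dose, structures=s2)
        with pytest.raises(MissingStructure):
            score_plan(plan2, card)
        lenient = score_plan(plan2, card, lenient=True)
        chiasm_pts = sum(m.points for m in full.per_metric
                         if m.structure == "OpticChiasm")
        assert full.total_points - lenient.total_points == pytest.approx(chiasm_pts)
        assert any(m.flag == "missing" for m in lenient.per_metric)

    def test_invariant_under_metric_reordering(self, phantom_plan):
        card = builtin_scorecard("HSWBv2").scaled_to(phantom_plan.rx_gy)
        shuffled = Scorecard(
            name=card.name, rx_gy=card.rx_gy, metrics=tuple(card.metrics[::-1]),
            scalable=card.scalable, derived_structures=card.derived_structures,
        )
        a = score_plan(phantom_plan, card)
        b = score_plan(phantom_plan, shuffled)
        assert a.total_points == pytest.approx(b.total_points, abs=1e-9)

    def test_invariant_under_dvh_half_split(self):
        """Halving a structure's volume at fixed dose distribution leaves
        percent-based metrics, hence the score, unchanged."""
        plan = _uniform_plan(value=19.0)
        curve = compute_dvh(plan.dose, plan.structures["PTV_WB"])
        half = type(curve)(
            curve.dose_edges, curve.cum_volume_cc / 2, curve.total_volume_cc / 2,
            curve.bin_width, curve.min_dose_gy, curve.mean_dose_gy,
            curve.max_dose_gy, curve.structure)
        metrics = (
            ScoreMetric(0, parse_metric_text("Dose at 98% [Gy]", structure="PTV_WB"),
                        ScoreFunction(((17.0, 0.0), (20.0, 10.0))), 10.0),
            ScoreMetric(1, parse_metric_text("Volume at 90% [%]", structure="PTV_WB"),
                        ScoreFunction(((90.0, 0.0), (100.0, 5.0))), 5.0),
        )
        card = _card(metrics)
        full = score_plan(PlanRecord("a", 20.0, dvhs={"PTV_WB": curve}), card)
        halved = score_plan(PlanRecord("b", 20.0, dvhs={"PTV_WB": half}), card)
        assert full.total_points == pytest.approx(halved.total_points, abs=1e-9)


class TestNormalizeToMax:
    def test_already_optimal_keeps_factor_one(self):
        plan = _uniform_plan(value=20.0)
        m = ScoreMetric(0, parse_metric_text("MeanDose [Gy]", structure="PTV_WB"),
                        ScoreFunction(((18.0, 0.0), (20.0, 5.0), (22.0, 0.0))), 5.0)
        factor, res = normalize_to_max(plan, _card((m,)))
        assert factor == pytest.approx(1.0, abs=1e-9)
        assert res.total_points == pytest.approx(5.0)

    def test_analytically_forced_factor(self):
        # one dose metric at 10 Gy, function peaking uniquely at 9 Gy
        plan = _uniform_plan(value=10.0, rx=10.0)
        m = ScoreMetric(0, parse_metric_text("MeanDose [Gy]", structure="PTV_WB"),
                        ScoreFunction(((8.0, 0.0), (9.0, 12.0), (10.0, 0.0))), 12.0)
        factor, res = normalize_to_max(plan, _card((m,), rx=10.0))
        assert factor == pytest.approx(0.9, abs=1e-9)
        assert res.total_points == pytest.approx(12.0)

    def test_window_must_contain_one(self):
        plan = _uniform_plan()
        card = builtin_scorecard("HLS-EC-WB")
        with pytest.raises(ValueError):
            normalize_to_max(plan, card, window=(1.01, 1.1))

    def test_never_below_unnormalized_score(self, phantom_plan):
        card = builtin_scorecard("HMS-EC-WB").scaled_to(phantom_plan.rx_gy)
        off = score_plan(phantom_plan, card, normalization="off")
        _, res = normalize_to_max(phantom_plan, card)
        assert res.total_points >= off.total_points - 1e-9

    def test_matches_dense_grid_oracle(self, phantom_plan):
        card = builtin_scorecard("HSWBv2").scaled_to(phantom_plan.rx_gy)
        _, res = normalize_to_max(phantom_plan, card)
        _, total = _build_objective(phantom_plan, card, lenient=False)
        oracle = dense_grid_max(total)
        assert res.total_points >= oracle - 5e-9
        assert res.total_points == pytest.approx(oracle, abs=1e-6)


class TestScalePrescription:
    def test_identity(self, phantom_plan):
        assert scale_prescription(phantom_plan, phantom_plan.rx_gy) is phantom_plan

    def test_doses_scale_linearly(self):
        plan = _uniform_plan(value=18.0, rx=20.0)
        plan.dvh("PTV_WB")  # populate the cache so curves get scaled too
        scaled = scale_prescription(plan, 30.0)
        assert scaled.rx_gy == 30.0
        assert np.allclose(scaled.dose.values, 27.0)
        assert scaled.dvh("PTV_WB").mean_dose == pytest.approx(27.0)

    def test_relative_volume_level_invariant(self, phantom_plan):
        """V at 105% of Rx tracks the prescription under rescaling."""
        spec = parse_metric_text("Volume at 105% [%]", structure="PTV_WB")
        before = evaluate_metric(phantom_plan, spec)
        after = evaluate_metric(scale_prescription(phantom_plan, 30.0), spec)
        assert after == pytest.approx(before, abs=1e-9)


class TestTradeoffMonotonicity:
    def test_deeper_dip_shifts_points_toward_sparing(self):
        """Deepening the hippocampal dip (all else fixed) never decreases
        the hippocampus subtotal and never increases the coverage subtotal."""
        from dataclasses import replace
        from dvhscore import PhantomConfig, build_phantom, simulate_dose
        card = builtin_scorecard("HLS-EC-WB")
        hippo_prev, cov_prev = None, None
        for dip in (0.0, 0.3, 0.5, 0.7):
            cfg = replace(PhantomConfig(seed=5, noise_sd=0.0), dip_depth=dip)
            structures = build_phantom(cfg)
            plan = PlanRecord("p", rx_gy=cfg.rx_gy,
                              dose=simulate_dose(structures, cfg),
                              structures=structures)
            res = score_plan(plan, card)
            hippo = sum(m.points for m in res.per_metric
                        if m.structure == "Hippocampi")
            cov = sum(m.points for m in res.per_metric
                      if m.structure.startswith("PTV") and "Volume at" in m.metric_text)
            if hippo_prev is not None:
                assert hippo >= hippo_prev - 1e-9
                assert cov <= cov_prev + 1e-9
            hippo_prev, cov_prev = hippo, cov
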