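"""Metric-text grammar, score functions, scorecard files, built-in cards."""

import numpy as np
import pytest

from dvhscore import (
    SchemaError,
    Scorecard,
    ScoreFunction,
    ScoreMetric,
    UnknownScorecard,
    UnrecognizedMetricText,
    builtin_scorecard,
    evaluate_score_function,
    load_scorecard,
    parse_metric_text,
    save_scorecard,
    scorecard_from_csv_text,
    scorecard_to_csv_text,
)
from dvhscore.scorecard import (
    DOSE_AT_VOLUME_CC,
    DOSE_AT_VOLUME_PCT,
    HOMOGENEITY_INDEX,
    CONFORMATION_NUMBER,
    MAX_DOSE,
    MEAN_DOSE,
    MIN_DOSE,
    UNIT_CC,
    UNIT_GY,
    UNIT_PERCENT_RX,
    UNIT_PERCENT_STRUCTURE,
    VOLUME_AT_DOSE_ABS,
    VOLUME_AT_DOSE_REL,
)

# every metric-text form used by the built-in whole-brain cards
ALL_CARD_TEXTS = [
    "Volume at 20Gy [%]", "Volume at 30Gy [%]", "Dose at 98% [Gy]",
    "Dose at 95% [Gy]", "Dose at 2% [Gy]", "Volume at 105% [%]",
    "Dose at 0.03CC [Gy]", "MaxDose [Gy]", "MaxDose [%]", "HI [1 - 99]/20]",
    "HI [1 - 99]/30]", "Conformation No. at [12.7Gy]",
    "Conformation No. at [28.5Gy]", "MeanDose [Gy]", "Dose at 100% [Gy]",
    "Volume at 99.5% [CC]",
]


class TestMetricTextGrammar:
    @pytest.mark.parametrize("text", ALL_CARD_TEXTS)
    def test_accepts_every_card_text(self, text):
        spec = parse_metric_text(text, rx_gy=30.0)
        assert spec.kind

    @pytest.mark.parametrize(
        "text,kind,param,unit",
        [
            ("Dose at 0.03CC [Gy]", DOSE_AT_VOLUME_CC, 0.03, UNIT_GY),
            ("Dose at 98% [Gy]", DOSE_AT_VOLUME_PCT, 98.0, UNIT_GY),
            ("Dose at 100% [Gy]", MIN_DOSE, None, UNIT_GY),
            ("Volume at 105% [%]", VOLUME_AT_DOSE_REL, 105.0, UNIT_PERCENT_STRUCTURE),
            ("Volume at 99.5% [CC]", VOLUME_AT_DOSE_REL, 99.5, UNIT_CC),
            ("Volume at 20Gy [%]", VOLUME_AT_DOSE_ABS, 20.0, UNIT_PERCENT_STRUCTURE),
            ("MeanDose [Gy]", MEAN_DOSE, None, UNIT_GY),
            ("MaxDose [%]", MAX_DOSE, None, UNIT_PERCENT_RX),
            ("HI [1 - 99]/30]", HOMOGENEITY_INDEX, 30.0, "ratio"),
            ("Conformation No. at [28.5Gy]", CONFORMATION_NUMBER, 28.5, "ratio"),
        ],
    )
    def test_resolution(self, text, kind, param, unit):
        spec = parse_metric_text(text, rx_gy=20.0)
        assert spec.kind == kind
        assert spec.parameter == param
        assert spec.value_unit == unit

    def test_case_and_whitespace_tolerant(self):
        assert parse_metric_text("dose at 98% [GY]").kind == DOSE_AT_VOLUME_PCT
        assert parse_metric_text("  MAXDOSE [ Gy ]  ").kind == MAX_DOSE

    def test_canonical_round_trip(self):
        for text in ALL_CARD_TEXTS:
            spec = parse_metric_text(text)
            again = parse_metric_text(spec.metric_text)
            assert again == type(again)(
                structure=spec.structure, kind=spec.kind,
                parameter=spec.parameter, value_unit=spec.value_unit,
            )

    def test_rejects_garbage(self):
        for bad in ("Dose near 98%", "Volume at [Gy]", "D98%", ""):
            with pytest.raises(UnrecognizedMetricText):
                parse_metric_text(bad)


class TestScoreFunction:
    def test_knot_values_and_midpoint(self):
        fn = ScoreFunction(((10.0, 12.0), (16.0, 0.0)))
        assert evaluate_score_function(fn, 10.0) == 12.0
        assert evaluate_score_function(fn, 16.0) == 0.0
        assert evaluate_score_function(fn, 13.0) == pytest.approx(6.0)

    def test_clamps_beyond_fail_end(self):
        # a value past the failing knot is a protocol violation: 0 points
        fn = ScoreFunction(((10.0, 12.0), (16.0, 0.0)))
        assert evaluate_score_function(fn, 25.0) == 0.0
        assert evaluate_score_function(fn, 1.0) == 12.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ScoreFunction(((1.0, 1.0),))  # too few knots
        with pytest.raises(ValueError):
            ScoreFunction(((2.0, 1.0), (2.0, 0.0)))  # non-increasing values

    def test_intermediate_knots_shape_the_function(self):
        fn = ScoreFunction(((0.0, 5.0), (1.0, 4.0), (2.0, 0.0)))
        assert fn(0.5) == pytest.approx(4.5)
        assert fn(1.5) == pytest.approx(2.0)


class TestBuiltinCards:
    @pytest.mark.parametrize(
        "name,total,n_metrics,rx,scalable",
        [
            ("HLS-EC-WB", 158.5, 29, 20.0, False),
            ("HMS-EC-WB", 158.5, 29, 30.0, True),
            ("HSWBv2", 142.0, 25, 30.0, True),
        ],
    )
    def test_totals_and_shape(self, name, total, n_metrics, rx, scalable):
        card = builtin_scorecard(name)
        assert card.total_points == pytest.approx(total, abs=1e-9)
        assert len(card) == n_metrics
        assert card.rx_gy == rx
        assert card.scalable is scalable

    def test_unknown_name(self):
        with pytest.raises(UnknownScorecard):
            builtin_scorecard("nope")

    def test_hippocampus_protocol_fail_anchors(self):
        """Zero-point knots sit at the protocol-violation thresholds."""
        def zero_knot(card, structure, kind):
            m = next(m for m in card.metrics
                     if m.spec.structure == structure and m.spec.kind == kind)
            return next(v for v, p in m.function.knots if p == 0.0)

        hls = builtin_scorecard("HLS-EC-WB")
        assert zero_knot(hls, "Hippocampi", MIN_DOSE) == pytest.approx(7.6)
        assert zero_knot(hls, "Hippocampi", DOSE_AT_VOLUME_CC) == pytest.approx(13.0)
        for name in ("HMS-EC-WB", "HSWBv2"):
            card = builtin_scorecard(name)
            assert zero_knot(card, "Hippocampi", MIN_DOSE) == pytest.approx(9.0)
            assert zero_knot(card, "Hippocampi", DOSE_AT_VOLUME_CC) == pytest.approx(
                16.0, abs=0.01
            )

    def test_functions_monotone_between_extreme_knots(self):
        for name in ("HLS-EC-WB", "HMS-EC-WB", "HSWBv2"):
            for m in builtin_scorecard(name).metrics:
                pts = [p for _, p in m.function.knots]
                diffs = np.diff(pts)
                assert np.all(diffs >= 0) or np.all(diffs <= 0), m.spec.metric_text

    def test_metric_ids_unique_and_ordered(self):
        for name in ("HLS-EC-WB", "HMS-EC-WB", "HSWBv2"):
            ids = [m.id for m in builtin_scorecard(name).metrics]
            assert ids == sorted(set(ids))


class TestScalingCards:
    def test_non_scalable_raises(self):
        with pytest.raises(ValueError, match="not scalable"):
            builtin_scorecard("HLS-EC-WB").scaled_to(30.0)

    def test_scale_30_to_20(self):
        card = builtin_scorecard("HMS-EC-WB").scaled_to(20.0)
        assert card.rx_gy == 20.0
        by_kind = {}
        for m in card.metrics:
            by_kind.setdefault(m.spec.kind, m)
        # absolute Gy levels and HI denominator scale by 2/3
        assert by_kind[VOLUME_AT_DOSE_ABS].spec.parameter == pytest.approx(20.0)
        assert by_kind[CONFORMATION_NUMBER].spec.parameter == pytest.approx(19.0)
        assert by_kind[HOMOGENEITY_INDEX].spec.parameter == pytest.approx(20.0)
        # Gy-valued knots scale; the hippocampus D0.03cc fail moves 16 -> 10.67
        hippo = next(m for m in card.metrics
                     if m.spec.structure == "Hippocampi"
                     and m.spec.kind == DOSE_AT_VOLUME_CC)
        fail = max(v for v, p in hippo.function.knots)
        assert fail == pytest.approx(16.0 * 2 / 3, abs=0.01)

    def test_scaling_round_trip(self):
        card = builtin_scorecard("HSWBv2")
        back = card.scaled_to(20.0).scaled_to(30.0)
        for a, b in zip(card.metrics, back.metrics):
            assert a.spec.kind == b.spec.kind
            assert np.allclose([v for v, _ in a.function.knots],
                               [v for v, _ in b.function.knots])


class TestFileFormat:
    @pytest.mark.parametrize("name", ["HLS-EC-WB", "HMS-EC-WB", "HSWBv2"])
    def test_json_round_trip_identity_and_byte_stability(self, name, tmp_path):
        card = builtin_scorecard(name)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_scorecard(card, p1)
        loaded = load_scorecard(p1)
        assert loaded == card
        save_scorecard(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_knots_names_metric(self, tmp_path):
        import json
        card = builtin_scorecard("HSWBv2")
        save_scorecard(card, tmp_path / "c.json")
        data = json.loads((tmp_path / "c.json").read_text())
        del data["metrics"][3]["knots"]
        (tmp_path / "broken.json").write_text(json.dumps(data))
        with pytest.raises(SchemaError, match="/metrics/3"):
            load_scorecard(tmp_path / "broken.json")

    def test_csv_dialect_round_trip(self):
        card = builtin_scorecard("HMS-EC-WB")
        text = scorecard_to_csv_text(card)
        again = scorecard_from_csv_text(text)
        assert again.name == card.name
        assert again.total_points == pytest.approx(card.total_points)
        assert len(again) == len(card)
        for a, b in zip(card.metrics, again.metrics):
            assert a.spec == b.spec
            assert np.allclose(a.function.knots, b.function.knots)

    def test_hand_written_card_equals_in_memory(self, tmp_path):
        from dvhscore import MetricSpec
        text = """{
          "name": "mini", "rx_gy": 20.0, "scalable": true,
          "metrics": [
            {"id": 0, "structure": "PTV", "metric_text": "MeanDose [Gy]",
             "max_points": 10, "knots": [[18.0, 0.0], [20.0, 10.0]]}
          ]
        }"""
        (tmp_path / "mini.json").write_text(text)
        loaded = load_scorecard(tmp_path / "mini.json")
        built = Scorecard(
            name="mini", rx_gy=20.0,
            metrics=(ScoreMetric(0, MetricSpec("PTV", MEAN_DOSE),
                                 ScoreFunction(((18.0, 0.0), (20.0, 10.0))), 10.0),),
        )
        assert loaded == built
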