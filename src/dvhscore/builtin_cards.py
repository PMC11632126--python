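"""The three built-in hippocampal-sparing whole-brain scorecards.

``HLS-EC-WB`` (hippocampal limited-sparing, enhanced coverage, 20 Gy/5 fx,
not scalable), ``HMS-EC-WB`` (moderate sparing, enhanced coverage, 30 Gy/10
fx, scalable) and ``HSWBv2`` (aggressive/maximal sparing, 30 Gy/10 fx,
scalable). The metric lists — structures, metric texts, ordering and
maximum point values (totals 158.5 / 158.5 / 142) — follow the published
cards row for row.

The exact knot coordinates of the published score functions are not public.
The knots shipped here are RECONSTRUCTED three-knot functions with the
canonical fail / variation / aspirational shape: the zero-point sits at the
protocol-violation value where one is published (NRG-CC001 / protocol
thresholds: hippocampus Dmin fail at 7.6 Gy for the limited-sparing 20 Gy
card and 9 Gy for the 30 Gy cards; hippocampus D0.03cc fail at 13 Gy
resp. 16 Gy), a steep variation segment follows, and a shallow ALARA
segment reaches max points at an aspirational value. Dose-valued knots are
placed as fractions of the card prescription so prescription scaling is
exact. They reproduce each card's *intent* (relative weighting and
direction), not the published per-metric point values; override them via a
scorecard file for anything quantitative about the published functions.
"""

from __future__ import annotations

from .errors import UnknownScorecard
from .scorecard import (
    Scorecard,
    ScoreFunction,
    ScoreMetric,
    parse_metric_text,
)
from .structures import DEFAULT_RECIPES

BUILTIN_NAMES = ("HLS-EC-WB", "HMS-EC-WB", "HSWBv2")

_ALIASES = {
    "hls-ec-wb": "HLS-EC-WB",
    "hls": "HLS-EC-WB",
    "hms-ec-wb": "HMS-EC-WB",
    "hms": "HMS-EC-WB",
    "hswbv2": "HSWBv2",
    "v2": "HSWBv2",
    "v2.0": "HSWBv2",
}

_MID = 0.72  # points fraction awarded at the variation knot


def _lo(goal: float, var: float, fail: float, pts: float) -> tuple:
    """Lower-is-better (OAR / hotspot): max points at ``goal``, zero at ``fail``."""
    assert goal < var < fail
    return ((goal, pts), (var, _MID * pts), (fail, 0.0))


def _hi(fail: float, var: float, goal: float, pts: float) -> tuple:
    """Higher-is-better (coverage): zero at ``fail``, max points at ``goal``."""
    assert fail < var < goal
    return ((fail, 0.0), (var, _MID * pts), (goal, pts))


def _rows_hls(rx: float) -> list[tuple]:
    """29 rows of the limited-sparing enhanced-coverage 20 Gy card."""
    r = rx
    return [
        (0, "PTV_2000", f"Volume at {r:g}Gy [%]", 20, _hi(90, 98, 99, 20)),
        (1, "PTV_2000", "Dose at 98% [Gy]", 14, _hi(0.90 * r, 0.98 * r, 0.995 * r, 14)),
        (2, "PTV_2000", "Dose at 95% [Gy]", 2, _hi(0.92 * r, 0.985 * r, 1.0 * r, 2)),
        (3, "PTV_2000", "Dose at 2% [Gy]", 11, _lo(1.02 * r, 1.05 * r, 1.10 * r, 11)),
        (4, "PTV_2000", "Volume at 105% [%]", 5.5, _lo(0.5, 5, 20, 5.5)),
        (5, "PTV_2000", "Dose at 0.03CC [Gy]", 8, _lo(1.03 * r, 1.07 * r, 1.12 * r, 8)),
        (6, "PTV_2000", "MaxDose [Gy]", 5, _lo(1.04 * r, 1.08 * r, 1.15 * r, 5)),
        (7, "PTV_2000", f"HI [1 - 99]/{r:g}]", 2, _lo(0.05, 0.12, 0.25, 2)),
        (8, "PTV_2000", f"Conformation No. at [{0.635 * r:g}Gy]", 1, _hi(0.25, 0.55, 0.85, 1)),
        (9, "Hippocampi", "Dose at 0.03CC [Gy]", 7.5, _lo(0.40 * r, 0.55 * r, 0.65 * r, 7.5)),
        (10, "Hippocampi", "MeanDose [Gy]", 12, _lo(0.30 * r, 0.48 * r, 0.62 * r, 12)),
        (11, "Hippocampi", "Dose at 100% [Gy]", 17, _lo(0.175 * r, 0.30 * r, 0.38 * r, 17)),
        (12, "OpticChiasm", "Dose at 0.03CC [Gy]", 3.5, _lo(0.95 * r, 1.02 * r, 1.08 * r, 3.5)),
        (13, "BrainStem", "Dose at 0.03CC [Gy]", 3, _lo(0.95 * r, 1.03 * r, 1.09 * r, 3)),
        (14, "SpinalCord", "Dose at 0.03CC [Gy]", 3.5, _lo(0.60 * r, 0.90 * r, 1.08 * r, 3.5)),
        (15, "OpticNerve_L", "Dose at 0.03CC [Gy]", 3.5, _lo(0.85 * r, 1.00 * r, 1.10 * r, 3.5)),
        (16, "OpticNerve_R", "Dose at 0.03CC [Gy]", 3.5, _lo(0.85 * r, 1.00 * r, 1.10 * r, 3.5)),
        (17, "Eye_L", "MaxDose [Gy]", 2, _lo(0.30 * r, 0.60 * r, 1.00 * r, 2)),
        (18, "Eye_L", "MeanDose [Gy]", 2, _lo(0.15 * r, 0.35 * r, 0.70 * r, 2)),
        (19, "Eye_R", "MaxDose [Gy]", 2, _lo(0.30 * r, 0.60 * r, 1.00 * r, 2)),
        (20, "Eye_R", "MeanDose [Gy]", 2, _lo(0.15 * r, 0.35 * r, 0.70 * r, 2)),
        (21, "LacrimalGland_L", "MeanDose [Gy]", 3.5, _lo(0.20 * r, 0.45 * r, 0.90 * r, 3.5)),
        (22, "LacrimalGland_R", "MeanDose [Gy]", 3.5, _lo(0.20 * r, 0.45 * r, 0.90 * r, 3.5)),
        (23, "Lens_L", "Dose at 0.03CC [Gy]", 2.25, _lo(0.10 * r, 0.25 * r, 0.50 * r, 2.25)),
        (24, "Lens_R", "Dose at 0.03CC [Gy]", 2.25, _lo(0.10 * r, 0.25 * r, 0.50 * r, 2.25)),
        (25, "_Brain&BODY", "Volume at 99.5% [CC]", 5, _hi(200, 330, 370, 5)),
        (26, "_Brain&BODY", "MaxDose [%]", 5, _lo(104, 108, 115, 5)),
        (27, "_BrainStem#Hi", "Dose at 95% [Gy]", 2, _hi(0.85 * r, 0.95 * r, 0.99 * r, 2)),
        (28, "_Eyes&BODY", "MeanDose [Gy]", 5, _lo(0.15 * r, 0.35 * r, 0.70 * r, 5)),
    ]


def _rows_hms(rx: float) -> list[tuple]:
    """29 rows of the moderate-sparing enhanced-coverage 30 Gy card."""
    r = rx
    return [
        (0, "PTV_3000", f"Volume at {r:g}Gy [%]", 20, _hi(90, 98, 99, 20)),
        (1, "PTV_3000", "Dose at 98% [Gy]", 14, _hi(0.90 * r, 0.98 * r, 0.995 * r, 14)),
        (2, "PTV_3000", "Dose at 95% [Gy]", 2, _hi(0.92 * r, 0.985 * r, 1.0 * r, 2)),
        (3, "PTV_3000", "Dose at 2% [Gy]", 11, _lo(1.03 * r, 1.06 * r, 1.11 * r, 11)),
        (4, "PTV_3000", "Volume at 105% [%]", 5, _lo(1, 8, 25, 5)),
        (5, "PTV_3000", "Dose at 0.03CC [Gy]", 2.5, _lo(1.04 * r, 1.08 * r, 1.13 * r, 2.5)),
        (6, "PTV_3000", "MaxDose [Gy]", 2.5, _lo(1.05 * r, 1.09 * r, 1.16 * r, 2.5)),
        (7, "PTV_3000", f"HI [1 - 99]/{r:g}]", 2, _lo(0.06, 0.14, 0.28, 2)),
        (8, "PTV_3000", f"Conformation No. at [{0.95 * r:g}Gy]", 1, _hi(0.30, 0.60, 0.88, 1)),
        (9, "Hippocampi", "Dose at 0.03CC [Gy]", 12, _lo(0.35 * r, 0.4667 * r, 0.5333 * r, 12)),
        (10, "Hippocampi", "MeanDose [Gy]", 16, _lo(0.28 * r, 0.43 * r, 0.55 * r, 16)),
        (11, "Hippocampi", "Dose at 100% [Gy]", 17, _lo(0.15 * r, 0.26 * r, 0.30 * r, 17)),
        (12, "OpticChiasm", "Dose at 0.03CC [Gy]", 3.5, _lo(0.95 * r, 1.02 * r, 1.08 * r, 3.5)),
        (13, "BrainStem", "Dose at 0.03CC [Gy]", 3, _lo(0.95 * r, 1.03 * r, 1.09 * r, 3)),
        (14, "SpinalCord", "Dose at 0.03CC [Gy]", 3.5, _lo(0.60 * r, 0.90 * r, 1.08 * r, 3.5)),
        (15, "OpticNerve_L", "Dose at 0.03CC [Gy]", 3.5, _lo(0.85 * r, 1.00 * r, 1.10 * r, 3.5)),
        (16, "OpticNerve_R", "Dose at 0.03CC [Gy]", 3.5, _lo(0.85 * r, 1.00 * r, 1.10 * r, 3.5)),
        (17, "Eye_L", "MaxDose [Gy]", 2, _lo(0.30 * r, 0.60 * r, 1.00 * r, 2)),
        (18, "Eye_L", "MeanDose [Gy]", 2, _lo(0.15 * r, 0.35 * r, 0.70 * r, 2)),
        (19, "Eye_R", "MaxDose [Gy]", 2, _lo(0.30 * r, 0.60 * r, 1.00 * r, 2)),
        (20, "Eye_R", "MeanDose [Gy]", 2, _lo(0.15 * r, 0.35 * r, 0.70 * r, 2)),
        (21, "LacrimalGland_L", "MeanDose [Gy]", 3.5, _lo(0.20 * r, 0.45 * r, 0.90 * r, 3.5)),
        (22, "LacrimalGland_R", "MeanDose [Gy]", 3.5, _lo(0.20 * r, 0.45 * r, 0.90 * r, 3.5)),
        (23, "Lens_L", "Dose at 0.03CC [Gy]", 2.25, _lo(0.10 * r, 0.25 * r, 0.50 * r, 2.25)),
        (24, "Lens_R", "Dose at 0.03CC [Gy]", 2.25, _lo(0.10 * r, 0.25 * r, 0.50 * r, 2.25)),
        (25, "_Brain&BODY", "Volume at 99.5% [CC]", 5, _hi(200, 330, 370, 5)),
        (26, "_Brain&BODY", "MaxDose [%]", 5, _lo(104, 108, 115, 5)),
        (27, "_BrainStem#Hi", "Dose at 95% [Gy]", 2, _hi(0.85 * r, 0.95 * r, 0.99 * r, 2)),
        (28, "_Eyes&BODY", "MeanDose [Gy]", 5, _lo(0.15 * r, 0.35 * r, 0.70 * r, 5)),
    ]


def _rows_v2(rx: float) -> list[tuple]:
    """25 rows of the 2022 aggressive-sparing card (coverage goal >95%)."""
    r = rx
    return [
        (0, "PTV_3000", f"Volume at {r:g}Gy [%]", 15, _hi(90, 93, 95.5, 15)),
        (1, "PTV_3000", "Dose at 98% [Gy]", 14, _hi(0.85 * r, 0.93 * r, 0.97 * r, 14)),
        (2, "PTV_3000", "Dose at 2% [Gy]", 11, _lo(1.03 * r, 1.07 * r, 1.12 * r, 11)),
        (3, "PTV_3000", "Volume at 105% [%]", 5.5, _lo(0.5, 5, 20, 5.5)),
        (4, "PTV_3000", "Dose at 0.03CC [Gy]", 4.5, _lo(1.05 * r, 1.09 * r, 1.14 * r, 4.5)),
        (5, "PTV_3000", f"HI [1 - 99]/{r:g}]", 2, _lo(0.07, 0.16, 0.30, 2)),
        (6, "PTV_3000", f"Conformation No. at [{0.95 * r:g}Gy]", 1, _hi(0.30, 0.60, 0.88, 1)),
        (7, "Hippocampi", "Dose at 0.03CC [Gy]", 7.5, _lo(0.20 * r, 0.40 * r, 0.5333 * r, 7.5)),
        (8, "Hippocampi", "MeanDose [Gy]", 12, _lo(0.17 * r, 0.33 * r, 0.50 * r, 12)),
        (9, "Hippocampi", "Dose at 100% [Gy]", 17, _lo(0.12 * r, 0.23 * r, 0.30 * r, 17)),
        (10, "OpticChiasm", "Dose at 0.03CC [Gy]", 3.5, _lo(0.95 * r, 1.02 * r, 1.08 * r, 3.5)),
        (11, "BrainStem", "Dose at 0.03CC [Gy]", 3, _lo(0.95 * r, 1.03 * r, 1.09 * r, 3)),
        (12, "SpinalCord", "Dose at 0.03CC [Gy]", 3.5, _lo(0.60 * r, 0.90 * r, 1.08 * r, 3.5)),
        (13, "OpticNerve_L", "Dose at 0.03CC [Gy]", 3.5, _lo(0.85 * r, 1.00 * r, 1.10 * r, 3.5)),
        (14, "OpticNerve_R", "Dose at 0.03CC [Gy]", 3.5, _lo(0.85 * r, 1.00 * r, 1.10 * r, 3.5)),
        (15, "Eye_L", "MeanDose [Gy]", 3.5, _lo(0.15 * r, 0.35 * r, 0.70 * r, 3.5)),
        (16, "Eye_R", "MeanDose [Gy]", 3.5, _lo(0.15 * r, 0.35 * r, 0.70 * r, 3.5)),
        (17, "LacrimalGland_L", "MeanDose [Gy]", 3.5, _lo(0.20 * r, 0.45 * r, 0.90 * r, 3.5)),
        (18, "LacrimalGland_R", "MeanDose [Gy]", 3.5, _lo(0.20 * r, 0.45 * r, 0.90 * r, 3.5)),
        (19, "Lens_L", "Dose at 0.03CC [Gy]", 2.25, _lo(0.10 * r, 0.25 * r, 0.50 * r, 2.25)),
        (20, "Lens_R", "Dose at 0.03CC [Gy]", 2.25, _lo(0.10 * r, 0.25 * r, 0.50 * r, 2.25)),
        (21, "_Brain&BODY", "Volume at 99.5% [CC]", 5, _hi(200, 330, 370, 5)),
        (22, "_Brain&BODY", "MaxDose [%]", 5, _lo(104, 108, 115, 5)),
        (23, "_BrainStem#Hi", "Dose at 95% [Gy]", 2, _hi(0.85 * r, 0.95 * r, 0.99 * r, 2)),
        (24, "_Eyes&BODY", "MeanDose [Gy]", 5, _lo(0.15 * r, 0.35 * r, 0.70 * r, 5)),
    ]


_CARDS = {
    "HLS-EC-WB": (20.0, False, _rows_hls),
    "HMS-EC-WB": (30.0, True, _rows_hms),
    "HSWBv2": (30.0, True, _rows_v2),
}

_NOTES = (
    "Knot coordinates are reconstructed defaults (fail/variation/ALARA shape "
    "anchored on published protocol thresholds), not the published functions."
)


def builtin_scorecard(name: str) -> Scorecard:
    """One of the built-in cards: ``HLS-EC-WB``, ``HMS-EC-WB`` or ``HSWBv2``.

    Raises :class:`UnknownScorecard` for anything else. Common aliases
    (``hls``, ``v2`` ...) are accepted case-insensitively.
    """
    canonical = _ALIASES.get(name.strip().lower())
    if canonical is None:
        raise UnknownScorecard(
            f"{name!r}; available: {', '.join(BUILTIN_NAMES)}"
        )
    rx, scalable, rows = _CARDS[canonical]
    metrics = tuple(
        ScoreMetric(
            id=mid,
            spec=parse_metric_text(text, rx, structure),
            function=ScoreFunction(knots),
            max_points=float(pts),
        )
        for mid, structure, text, pts, knots in rows(rx)
    )
    return Scorecard(
        name=canonical,
        rx_gy=rx,
        metrics=metrics,
        scalable=scalable,
        derived_structures=DEFAULT_RECIPES,
        notes=_NOTES,
    )
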