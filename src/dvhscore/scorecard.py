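"""Dosimetric scorecards: metric specs, piecewise-linear score functions,
and the scorecard file format.

A dosimetric scorecard is an ordered list of plan-quality metrics, each
mapped to points by a piecewise-linear function of the metric value. The
function typically spans from a failing value (0 points, a protocol
violation) through a steep "variation acceptable" segment to a shallow
aspirational (ALARA) segment ending at the metric's maximum point value.
The total over all metrics quantifies how well a plan realizes one precise
clinical intent; different cards over the same metrics express different
intents purely through point allocations and knot placement.

Metric-text grammar (the human-readable metric vocabulary)::

    Dose at <x>% [Gy]          D_x%   (x = 100 -> minimum dose)
    Dose at <x>CC [Gy]         D_xcc  (near-max dose for small x)
    Volume at <x>Gy [%|CC]     V at an absolute dose level
    Volume at <x>% [%|CC]      V at a level relative to the prescription
    MeanDose [Gy]
    MaxDose [Gy|%]             % means percent of prescription
    HI [1 - 99]/<rx>]          (D1% - D99%) / <rx>
    Conformation No. at [<x>Gy]

Parsing is case-insensitive on keywords and whitespace-tolerant.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import SchemaError, UnrecognizedMetricText
from .structures import StructureRecipe

POINTS_TOL = 1e-9

# metric kinds
DOSE_AT_VOLUME_PCT = "dose_at_volume_pct"
DOSE_AT_VOLUME_CC = "dose_at_volume_cc"
VOLUME_AT_DOSE_ABS = "volume_at_dose_abs"
VOLUME_AT_DOSE_REL = "volume_at_dose_rel"
MEAN_DOSE = "mean_dose"
MAX_DOSE = "max_dose"
MIN_DOSE = "min_dose"
HOMOGENEITY_INDEX = "homogeneity_index"
CONFORMATION_NUMBER = "conformation_number"

#: kinds whose value is a dose and scales with a global dose renormalization
DOSE_LIKE_KINDS = frozenset(
    {DOSE_AT_VOLUME_PCT, DOSE_AT_VOLUME_CC, MEAN_DOSE, MAX_DOSE, MIN_DOSE,
     HOMOGENEITY_INDEX}
)
#: kinds evaluated as a volume at some dose level
VOLUME_LIKE_KINDS = frozenset({VOLUME_AT_DOSE_ABS, VOLUME_AT_DOSE_REL})

# value units
UNIT_GY = "Gy"
UNIT_PERCENT_RX = "percent_rx"
UNIT_PERCENT_STRUCTURE = "percent_structure"
UNIT_CC = "cc"
UNIT_RATIO = "ratio"


@dataclass(frozen=True)
class MetricSpec:
    """One fully-resolved plan metric.

    ``parameter`` is the %, cc or Gy argument of the metric kind (None for
    mean/max/min dose); ``value_unit`` is the unit the metric value — and
    hence the score-function knots — are expressed in. For
    ``volume_at_dose_rel`` the parameter stays in percent-of-Rx so that
    prescription rescaling re-resolves the absolute level automatically.
    """

    structure: str
    kind: str
    parameter: float | None = None
    value_unit: str = UNIT_GY

    def __post_init__(self):
        needs_param = self.kind not in (MEAN_DOSE, MAX_DOSE, MIN_DOSE)
        if needs_param and self.parameter is None:
            raise ValueError(f"metric kind {self.kind} requires a parameter")
        if not needs_param and self.parameter is not None:
            raise ValueError(f"metric kind {self.kind} takes no parameter")

    @property
    def metric_text(self) -> str:
        """The canonical metric-text rendering of this spec."""
        p = self.parameter
        if self.kind == DOSE_AT_VOLUME_PCT:
            return f"Dose at {p:g}% [Gy]"
        if self.kind == MIN_DOSE:
            return "Dose at 100% [Gy]"
        if self.kind == DOSE_AT_VOLUME_CC:
            return f"Dose at {p:g}CC [Gy]"
        if self.kind == VOLUME_AT_DOSE_ABS:
            u = "%" if self.value_unit == UNIT_PERCENT_STRUCTURE else "CC"
            return f"Volume at {p:g}Gy [{u}]"
        if self.kind == VOLUME_AT_DOSE_REL:
            u = "%" if self.value_unit == UNIT_PERCENT_STRUCTURE else "CC"
            return f"Volume at {p:g}% [{u}]"
        if self.kind == MEAN_DOSE:
            return "MeanDose [Gy]"
        if self.kind == MAX_DOSE:
            u = "%" if self.value_unit == UNIT_PERCENT_RX else "Gy"
            return f"MaxDose [{u}]"
        if self.kind == HOMOGENEITY_INDEX:
            return f"HI [1 - 99]/{p:g}]"
        if self.kind == CONFORMATION_NUMBER:
            return f"Conformation No. at [{p:g}Gy]"
        raise ValueError(f"unknown metric kind {self.kind!r}")


_NUM = r"(\d+(?:\.\d+)?)"
_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(rf"^dose\s+at\s+{_NUM}\s*%\s*\[\s*gy\s*\]$", re.I), "dose_pct"),
    (re.compile(rf"^dose\s+at\s+{_NUM}\s*cc\s*\[\s*gy\s*\]$", re.I), "dose_cc"),
    (re.compile(rf"^volume\s+at\s+{_NUM}\s*gy\s*\[\s*(%|cc)\s*\]$", re.I), "vol_abs"),
    (re.compile(rf"^volume\s+at\s+{_NUM}\s*%\s*\[\s*(%|cc)\s*\]$", re.I), "vol_rel"),
    (re.compile(r"^meandose\s*\[\s*gy\s*\]$", re.I), "mean"),
    (re.compile(r"^maxdose\s*\[\s*(gy|%)\s*\]$", re.I), "max"),
    (re.compile(rf"^hi\s*\[\s*1\s*-\s*99\s*\]\s*/\s*{_NUM}\s*\]?$", re.I), "hi"),
    (re.compile(rf"^conformation\s+no\.?\s+at\s*\[\s*{_NUM}\s*gy\s*\]$", re.I), "cn"),
]


def parse_metric_text(text: str, rx_gy: float | None = None, structure: str = "") -> MetricSpec:
    """Parse a metric-text string into a :class:`MetricSpec`.

    ``rx_gy`` is accepted for interface symmetry with callers that resolve
    relative levels eagerly; relative levels are kept symbolic (percent of
    Rx) so rescaling re-resolves them.
    """
    s = text.strip()
    for pat, tag in _PATTERNS:
        m = pat.match(s)
        if not m:
            continue
        if tag == "dose_pct":
            p = float(m.group(1))
            if p == 100:
                return MetricSpec(structure, MIN_DOSE, None, UNIT_GY)
            return MetricSpec(structure, DOSE_AT_VOLUME_PCT, p, UNIT_GY)
        if tag == "dose_cc":
            return MetricSpec(structure, DOSE_AT_VOLUME_CC, float(m.group(1)), UNIT_GY)
        if tag == "vol_abs":
            unit = UNIT_PERCENT_STRUCTURE if m.group(2) == "%" else UNIT_CC
            return MetricSpec(structure, VOLUME_AT_DOSE_ABS, float(m.group(1)), unit)
        if tag == "vol_rel":
            unit = UNIT_PERCENT_STRUCTURE if m.group(2) == "%" else UNIT_CC
            return MetricSpec(structure, VOLUME_AT_DOSE_REL, float(m.group(1)), unit)
        if tag == "mean":
            return MetricSpec(structure, MEAN_DOSE, None, UNIT_GY)
        if tag == "max":
            unit = UNIT_GY if m.group(1).lower() == "gy" else UNIT_PERCENT_RX
            return MetricSpec(structure, MAX_DOSE, None, unit)
        if tag == "hi":
            return MetricSpec(structure, HOMOGENEITY_INDEX, float(m.group(1)), UNIT_RATIO)
        if tag == "cn":
            return MetricSpec(structure, CONFORMATION_NUMBER, float(m.group(1)), UNIT_RATIO)
    raise UnrecognizedMetricText(text)


@dataclass(frozen=True)
class ScoreFunction:
    """Piecewise-linear map from metric value to points.

    ``knots`` are (metric_value, points) pairs with strictly increasing
    values; evaluation interpolates linearly between bracketing knots and
    clamps to the terminal knot's points outside the covered range (so a
    value beyond the failing end scores the failing knot's points — usually
    0, a protocol violation).
    """

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self):
        knots = tuple((float(v), float(p)) for v, p in self.knots)
        if len(knots) < 2:
            raise ValueError("a score function needs at least 2 knots")
        values = [v for v, _ in knots]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("knot values must be strictly increasing")
        if any(p < -POINTS_TOL for _, p in knots):
            raise ValueError("knot points must be non-negative")
        object.__setattr__(self, "knots", knots)

    @property
    def max_points(self) -> float:
        return max(p for _, p in self.knots)

    def __call__(self, value: float) -> float:
        xs = np.array([v for v, _ in self.knots])
        ps = np.array([p for _, p in self.knots])
        return float(np.interp(value, xs, ps))

    def scaled_values(self, factor: float) -> "ScoreFunction":
        """Knot values multiplied by ``factor`` (points unchanged)."""
        return ScoreFunction(tuple((v * factor, p) for v, p in self.knots))


def evaluate_score_function(fn: ScoreFunction, value: float) -> float:
    """Points awarded by ``fn`` for a metric ``value`` (clamped outside range)."""
    return fn(value)


@dataclass(frozen=True)
class ScoreMetric:
    """One scorecard row: a metric spec, its score function and max points."""

    id: int
    spec: MetricSpec
    function: ScoreFunction
    max_points: float

    def __post_init__(self):
        if self.max_points <= 0:
            raise ValueError("max_points must be positive")
        if abs(self.function.max_points - self.max_points) > POINTS_TOL:
            raise ValueError(
                f"metric {self.id}: max over knots ({self.function.max_points}) "
                f"!= max_points ({self.max_points})"
            )


@dataclass(frozen=True)
class Scorecard:
    """A named, ordered set of scored metrics with its reference prescription.

    ``scalable`` marks cards whose dose-valued knots and levels may be
    rescaled to another prescription (``scaled_to``); protocol cards tied to
    one institutional prescription are not scalable.
    """

    name: str
    rx_gy: float
    metrics: tuple[ScoreMetric, ...]
    scalable: bool = True
    derived_structures: tuple[StructureRecipe, ...] = ()
    notes: str = ""

    def __post_init__(self):
        if self.rx_gy <= 0:
            raise ValueError("rx_gy must be positive")
        ids = [m.id for m in self.metrics]
        if len(set(ids)) != len(ids):
            raise ValueError("metric ids must be unique")
        object.__setattr__(self, "metrics", tuple(self.metrics))
        object.__setattr__(self, "derived_structures", tuple(self.derived_structures))

    @property
    def total_points(self) -> float:
        return float(sum(m.max_points for m in self.metrics))

    def __len__(self) -> int:
        return len(self.metrics)

    def scaled_to(self, new_rx: float, force: bool = False) -> "Scorecard":
        """The same intent re-expressed at another prescription.

        Dose-valued knots and absolute Gy metric parameters (volume levels,
        conformation-number isodose levels, the HI denominator) are
        multiplied by ``new_rx / rx_gy``; relative (percent-of-Rx) levels
        and dimensionless knots are untouched. Raises for non-scalable
        cards unless ``force``.
        """
        if new_rx <= 0:
            raise ValueError("new_rx must be positive")
        if not self.scalable and not force:
            raise ValueError(
                f"scorecard '{self.name}' is bound to Rx {self.rx_gy:g} Gy "
                "and is not scalable (pass force=True to override)"
            )
        ratio = new_rx / self.rx_gy
        if ratio == 1.0:
            return self
        new_metrics = []
        for m in self.metrics:
            spec = m.spec
            if spec.kind in (VOLUME_AT_DOSE_ABS, CONFORMATION_NUMBER, HOMOGENEITY_INDEX):
                spec = replace(spec, parameter=spec.parameter * ratio)
            fn = m.function
            if spec.value_unit == UNIT_GY:
                fn = fn.scaled_values(ratio)
            new_metrics.append(ScoreMetric(m.id, spec, fn, m.max_points))
        return Scorecard(
            self.name, float(new_rx), tuple(new_metrics), self.scalable,
            self.derived_structures, self.notes,
        )


# ---------------------------------------------------------------------------
# file format


def _card_to_dict(card: Scorecard) -> dict:
    return {
        "format": "dvhscore-scorecard",
        "version": 1,
        "name": card.name,
        "rx_gy": card.rx_gy,
        "scalable": card.scalable,
        "notes": card.notes,
        "derived_structures": [r.to_dict() for r in card.derived_structures],
        "metrics": [
            {
                "id": m.id,
                "structure": m.spec.structure,
                "metric_text": m.spec.metric_text,
                "max_points": m.max_points,
                "knots": [[v, p] for v, p in m.function.knots],
            }
            for m in card.metrics
        ],
    }


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise SchemaError(f"{where}: missing required key '{key}'")
    return d[key]


def _card_from_dict(data: dict, where: str = "") -> Scorecard:
    if not isinstance(data, dict):
        raise SchemaError(f"{where or '/'}: scorecard document must be an object")
    name = _require(data, "name", where or "/")
    rx = _require(data, "rx_gy", where or "/")
    recipes = tuple(
        StructureRecipe.from_dict(r) for r in data.get("derived_structures", [])
    )
    raw_metrics = _require(data, "metrics", where or "/")
    metrics = []
    for i, md in enumerate(raw_metrics):
        loc = f"{where}/metrics/{i}"
        mid = int(_require(md, "id", loc))
        loc = f"{where}/metrics/{mid}"
        structure = _require(md, "structure", loc)
        text = _require(md, "metric_text", loc)
        max_points = float(_require(md, "max_points", loc))
        knots = _require(md, "knots", loc)
        try:
            spec = parse_metric_text(text, rx, structure)
        except UnrecognizedMetricText as exc:
            raise SchemaError(f"{loc}/metric_text: {exc}") from None
        try:
            fn = ScoreFunction(tuple((float(v), float(p)) for v, p in knots))
            metrics.append(ScoreMetric(mid, spec, fn, max_points))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{loc}/knots: {exc}") from None
    try:
        return Scorecard(
            name=name,
            rx_gy=float(rx),
            metrics=tuple(metrics),
            scalable=bool(data.get("scalable", True)),
            derived_structures=recipes,
            notes=str(data.get("notes", "")),
        )
    except ValueError as exc:
        raise SchemaError(f"{where or '/'}: {exc}") from None


def save_scorecard(card: Scorecard, path) -> None:
    """Write ``card`` as canonical JSON (sorted keys, 2-space indent)."""
    Path(path).write_text(
        json.dumps(_card_to_dict(card), indent=2, sort_keys=True) + "\n"
    )


def load_scorecard(path) -> Scorecard:
    """Load a scorecard from JSON (or the one-metric-per-row CSV dialect)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".csv":
        return scorecard_from_csv_text(text, name=path.stem)
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"/: not valid JSON: {exc}") from None
    return _card_from_dict(data)


# CSV dialect: one metric per row; card-level fields in '#key=value' header
# comments (name, rx_gy, scalable).

def scorecard_to_csv_text(card: Scorecard) -> str:
    buf = io.StringIO()
    buf.write(f"#name={card.name}\n#rx_gy={card.rx_gy:g}\n#scalable={int(card.scalable)}\n")
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["id", "structure", "metric_text", "max_points", "knots"])
    for m in card.metrics:
        knots = ";".join(f"{v:g}:{p:g}" for v, p in m.function.knots)
        w.writerow([m.id, m.spec.structure, m.spec.metric_text, f"{m.max_points:g}", knots])
    return buf.getvalue()


def scorecard_from_csv_text(
    text: str, name: str = "scorecard", rx_gy: float = 1.0, scalable: bool = True
) -> Scorecard:
    lines = text.splitlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition("=")
            key = key.strip()
            if key == "name":
                name = val.strip()
            elif key == "rx_gy":
                rx_gy = float(val)
            elif key == "scalable":
                scalable = bool(int(val))
        elif ln.strip():
            body.append(ln)
    metrics = []
    for row in csv.DictReader(body):
        try:
            knots = tuple(
                tuple(float(x) for x in pair.split(":"))
                for pair in row["knots"].split(";")
            )
            spec = parse_metric_text(row["metric_text"], rx_gy, row["structure"])
            metrics.append(
                ScoreMetric(int(row["id"]), spec, ScoreFunction(knots),
                            float(row["max_points"]))
            )
        except UnrecognizedMetricText as exc:
            raise SchemaError(f"/metrics/{row.get('id')}/metric_text: {exc}") from None
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"/metrics/{row.get('id')}: {exc}") from None
    return Scorecard(name=name, rx_gy=rx_gy, metrics=tuple(metrics), scalable=scalable)
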