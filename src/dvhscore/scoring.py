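"""Scoring plans against scorecards; dose renormalization; Rx scaling.

``score_plan`` evaluates every metric of a card on a plan and maps values
to points through the card's piecewise-linear functions. With
``normalization="max_score"`` the plan dose is first globally rescaled by
the factor r* that maximizes the total score — the "normalize to max
score" step: because exact target-coverage goals are rarely stated, the
steep coverage functions and the sparing functions together define the
best trade-off point, and reporting at r* removes the arbitrary
normalization noise of the optimizer output.

Under a global dose rescaling by r:

* dose-valued metrics (D_x%, D_xcc, mean/max/min, HI, MaxDose[%]) scale
  exactly as r * value;
* a volume metric at absolute level d becomes V(d / r) on the unscaled
  cumulative curve (a level relative to Rx is first resolved to Gy with the
  plan prescription, which renormalization does not change);
* the conformation number at level L is re-evaluated at L / r.

The total S(r) is therefore piecewise smooth in r with breakpoints where
r * value crosses a score-function knot, where d / r crosses a DVH bin
edge, and where an interpolated volume crosses a knot. The exact search
enumerates all those breakpoints inside the window, and polishes each
bracket with a bounded scalar optimization (between breakpoints S has the
form A + B r + C / r, which can peak in the interior). Ties within 1e-9
points resolve toward the factor closest to 1, then the smaller factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .dvh import (
    DEFAULT_BIN_WIDTH_GY,
    DoseGrid,
    DVHCurve,
    compute_dvh,
    conformation_number,
    dose_at_volume,
    homogeneity_index,
    volume_at_dose,
)
from .errors import MissingStructure, NeedsDoseGrid
from .scorecard import (
    CONFORMATION_NUMBER,
    DOSE_AT_VOLUME_CC,
    DOSE_AT_VOLUME_PCT,
    HOMOGENEITY_INDEX,
    MAX_DOSE,
    MEAN_DOSE,
    MIN_DOSE,
    POINTS_TOL,
    UNIT_CC,
    UNIT_PERCENT_RX,
    VOLUME_AT_DOSE_ABS,
    VOLUME_AT_DOSE_REL,
    MetricSpec,
    Scorecard,
)
from .structures import StructureSet

log = logging.getLogger(__name__)

#: structure name used as the irradiated-volume denominator of the
#: conformation number
BODY_STRUCTURE = "BODY"

DEFAULT_WINDOW = (0.90, 1.10)


@dataclass
class PlanRecord:
    """One plan to be scored: prescription, dose and/or DVHs, structures.

    A plan may be *dose-grid backed* (``dose`` + ``structures``; DVHs are
    computed and cached on demand) or *DVH-only* (``dvhs`` imported from a
    TPS export; conformation-number metrics are then unavailable).

    ``aliases`` maps scorecard structure names to plan structure names;
    additionally any unresolved ``PTV_*`` reference falls back to the
    generic ``PTV_WB`` when the plan has one, since protocol cards encode
    the prescription in the target name.
    """

    plan_id: str
    rx_gy: float
    fractions: int = 0
    dose: DoseGrid | None = None
    structures: StructureSet | None = None
    dvhs: dict[str, DVHCurve] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    bin_width: float = DEFAULT_BIN_WIDTH_GY

    def __post_init__(self):
        if self.rx_gy <= 0:
            raise ValueError("rx_gy must be positive")

    # -- structure resolution -------------------------------------------

    def resolve(self, name: str) -> str:
        """Map a scorecard structure name to a plan structure name."""
        have = set(self.dvhs)
        if self.structures is not None:
            have |= set(self.structures.names())
        if name in have:
            return name
        if name in self.aliases and self.aliases[name] in have:
            return self.aliases[name]
        if name.startswith("PTV") and "PTV_WB" in have:
            return "PTV_WB"
        raise MissingStructure(name)

    def dvh(self, name: str) -> DVHCurve:
        """The cumulative DVH of ``name`` (computed from the grid if needed)."""
        resolved = self.resolve(name)
        if resolved not in self.dvhs:
            if self.dose is None or self.structures is None:
                raise MissingStructure(name)
            self.dvhs[resolved] = compute_dvh(
                self.dose, self.structures[resolved], self.bin_width
            )
        return self.dvhs[resolved]

    def mask(self, name: str):
        if self.structures is None:
            raise NeedsDoseGrid(f"plan '{self.plan_id}' has no structure masks")
        return self.structures[self.resolve(name)]

    def prepare(self, card: Scorecard) -> "PlanRecord":
        """Materialize the card's derived structures on this plan (in place)."""
        if self.structures is not None and card.derived_structures:
            self.structures.apply_recipes(card.derived_structures)
        return self


def scale_prescription(plan: PlanRecord, new_rx: float) -> PlanRecord:
    """The same plan re-prescribed to ``new_rx`` Gy.

    Every dose (grid voxels and DVH edges) is multiplied by
    ``new_rx / rx_gy``; percent-of-Rx metric levels re-resolve automatically
    against the new prescription.
    """
    if new_rx <= 0:
        raise ValueError("new_rx must be positive")
    k = new_rx / plan.rx_gy
    if k == 1.0:
        return plan
    return replace(
        plan,
        rx_gy=float(new_rx),
        dose=None if plan.dose is None else plan.dose.scaled(k),
        dvhs={n: c.scaled(k) for n, c in plan.dvhs.items()},
        bin_width=plan.bin_width * k,
    )


# ---------------------------------------------------------------------------
# metric evaluation


def _resolve_level_gy(spec: MetricSpec, rx_gy: float) -> float:
    """Absolute dose level (Gy) of a volume-type metric."""
    if spec.kind == VOLUME_AT_DOSE_ABS:
        return spec.parameter
    return spec.parameter / 100.0 * rx_gy


def evaluate_metric(plan: PlanRecord, spec: MetricSpec) -> float:
    """The raw value of one metric on a plan, in the spec's value unit.

    Conformation-number metrics are evaluated voxel-exactly and require the
    dose grid (:class:`NeedsDoseGrid` on DVH-only plans); everything else
    comes from the cumulative DVH.
    """
    kind = spec.kind
    if kind == CONFORMATION_NUMBER:
        if plan.dose is None or plan.structures is None:
            raise NeedsDoseGrid(
                f"conformation number on DVH-only plan '{plan.plan_id}'"
            )
        target = plan.mask(spec.structure)
        body = plan.mask(BODY_STRUCTURE)
        return conformation_number(plan.dose, target, body, spec.parameter)

    curve = plan.dvh(spec.structure)
    if kind == DOSE_AT_VOLUME_PCT:
        return dose_at_volume(curve, spec.parameter, "percent")
    if kind == DOSE_AT_VOLUME_CC:
        return dose_at_volume(curve, spec.parameter, "cc")
    if kind == MIN_DOSE:
        return curve.min_dose
    if kind == MEAN_DOSE:
        return curve.mean_dose
    if kind == MAX_DOSE:
        v = curve.max_dose
        return 100.0 * v / plan.rx_gy if spec.value_unit == UNIT_PERCENT_RX else v
    if kind == HOMOGENEITY_INDEX:
        return homogeneity_index(curve, spec.parameter)
    if kind in (VOLUME_AT_DOSE_ABS, VOLUME_AT_DOSE_REL):
        level = _resolve_level_gy(spec, plan.rx_gy)
        unit = "cc" if spec.value_unit == UNIT_CC else "percent"
        return volume_at_dose(curve, level, unit)
    raise ValueError(f"unknown metric kind {kind!r}")


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class MetricResult:
    id: int
    structure: str
    metric_text: str
    value: float | None
    points: float
    max_points: float
    flag: str = ""  # "", "missing", "needs_dose_grid"


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one plan on one card."""

    plan_id: str
    card_name: str
    per_metric: tuple[MetricResult, ...]
    max_points: float
    normalization_factor: float = 1.0

    @property
    def total_points(self) -> float:
        return float(sum(m.points for m in self.per_metric))

    @property
    def percent_of_max(self) -> float:
        return 100.0 * self.total_points / self.max_points


# ---------------------------------------------------------------------------
# renormalization objective

_DEGENERATE = object()


class _RenormValue:
    """value(r) of one metric under global dose rescaling by r."""

    def __init__(self, plan: PlanRecord, spec: MetricSpec):
        self.spec = spec
        kind = spec.kind
        if kind == CONFORMATION_NUMBER:
            # interpolated-curve approximation of CN so the objective is
            # piecewise smooth (the voxel-exact CN is a step function of r)
            target_curve = plan.dvh(spec.structure)
            body_curve = plan.dvh(BODY_STRUCTURE)
            self.mode = "cn"
            self.level = spec.parameter
            self._t_edges = target_curve.dose_edges
            self._t_cum = target_curve.cum_volume_cc
            self._tv = target_curve.total_volume_cc
            self._b_edges = body_curve.dose_edges
            self._b_cum = body_curve.cum_volume_cc
        elif kind in (VOLUME_AT_DOSE_ABS, VOLUME_AT_DOSE_REL):
            curve = plan.dvh(spec.structure)
            self.mode = "volume"
            self.level = _resolve_level_gy(spec, plan.rx_gy)
            self._edges = curve.dose_edges
            self._cum = curve.cum_volume_cc
            self._total = curve.total_volume_cc
            self._as_cc = spec.value_unit == UNIT_CC
        else:
            self.mode = "dose"
            self.v0 = evaluate_metric(plan, spec)

    def __call__(self, r: float) -> float:
        if self.mode == "dose":
            return r * self.v0
        if self.mode == "volume":
            v_cc = float(np.interp(self.level / r, self._edges, self._cum,
                                   right=0.0))
            if self._as_cc:
                return v_cc
            return 100.0 * v_cc / self._total if self._total > 0 else 0.0
        # cn
        x = self.level / r
        tv_d = float(np.interp(x, self._t_edges, self._t_cum, right=0.0))
        v_d = float(np.interp(x, self._b_edges, self._b_cum, right=0.0))
        if v_d <= 0 or self._tv <= 0:
            return 0.0
        return (tv_d / self._tv) * (tv_d / v_d)

    # -- candidate breakpoints inside [lo, hi] ---------------------------

    def _level_candidates(self, edges, lo, hi):
        cands = []
        d_hi, d_lo = self.level / lo, self.level / hi
        for e in edges:
            if e > 0 and d_lo <= e <= d_hi:
                cands.append(self.level / e)
        return cands

    def candidates(self, fn, lo: float, hi: float) -> list[float]:
        out = []
        if self.mode == "dose":
            if abs(self.v0) <= 1e-12:
                log.debug("degenerate metric %s: value 0, no candidates",
                          self.spec.metric_text)
                return out
            for k, _ in fn.knots:
                r = k / self.v0
                if lo <= r <= hi:
                    out.append(r)
            return out
        if self.mode == "volume":
            out += self._level_candidates(self._edges, lo, hi)
            # radii where the interpolated volume crosses a knot value
            scale = 1.0 if self._as_cc else (self._total / 100.0 or 1.0)
            for kv, _ in fn.knots:
                v_cc = kv * scale
                c = self._cum
                for i in range(len(c) - 1):
                    c0, c1 = c[i], c[i + 1]
                    if c0 == c1:
                        continue
                    t = (v_cc - c0) / (c1 - c0)
                    if 0.0 <= t <= 1.0:
                        x = self._edges[i] + t * (self._edges[i + 1] - self._edges[i])
                        if x > 0:
                            r = self.level / x
                            if lo <= r <= hi:
                                out.append(r)
            return out
        # cn
        out += self._level_candidates(self._t_edges, lo, hi)
        out += self._level_candidates(self._b_edges, lo, hi)
        return out


def _build_objective(plan: PlanRecord, card: Scorecard, lenient: bool):
    """Per-metric value functions + total-score callable S(r)."""
    terms = []  # (ScoreMetric, _RenormValue | None)
    for m in card.metrics:
        try:
            terms.append((m, _RenormValue(plan, m.spec)))
        except (MissingStructure, NeedsDoseGrid):
            if not lenient:
                raise
            terms.append((m, None))

    def total(r: float) -> float:
        return sum(m.function(v(r)) for m, v in terms if v is not None)

    return terms, total


def normalize_to_max(
    plan: PlanRecord,
    card: Scorecard,
    window: tuple[float, float] = DEFAULT_WINDOW,
    grid: float = 1e-3,
    lenient: bool = False,
) -> tuple[float, "ScoreResult"]:
    """Find the dose renormalization factor with the highest total score.

    ``window`` must contain 1.0. ``grid`` adds a coarse uniform sweep to the
    breakpoint candidate set (a safety net for the stepwise parts of the
    objective); the exact breakpoints and per-bracket polish do the real
    work. Returns ``(factor, ScoreResult at that factor)``.
    """
    lo, hi = window
    if not (0 < lo <= 1.0 <= hi):
        raise ValueError("normalization window must contain 1.0")
    plan.prepare(card)
    terms, total = _build_objective(plan, card, lenient)

    cands = {lo, hi, 1.0}
    cands.update(np.arange(lo, hi, grid).tolist())
    for m, v in terms:
        if v is not None:
            cands.update(v.candidates(m.function, lo, hi))
    grid_r = np.array(sorted(cands))

    evals: list[tuple[float, float]] = [(float(r), total(float(r))) for r in grid_r]
    # midpoints + bounded polish per bracket
    for a, b in zip(grid_r[:-1], grid_r[1:]):
        if b - a < 1e-12:
            continue
        mid = 0.5 * (a + b)
        evals.append((float(mid), total(float(mid))))
        res = minimize_scalar(
            lambda r: -total(r), bounds=(float(a), float(b)), method="bounded",
            options={"xatol": 1e-12},
        )
        evals.append((float(res.x), total(float(res.x))))

    best_score = max(s for _, s in evals)
    near = [(r, s) for r, s in evals if s >= best_score - POINTS_TOL]
    r_star = min(near, key=lambda rs: (abs(rs[0] - 1.0), rs[0]))[0]

    result = _result_at_factor(plan, card, terms, r_star, lenient)
    return r_star, result


def _result_at_factor(plan, card, terms, r, lenient) -> ScoreResult:
    rows = []
    for m, v in terms:
        if v is None:
            rows.append(
                MetricResult(m.id, m.spec.structure, m.spec.metric_text,
                             None, 0.0, m.max_points, "missing")
            )
            continue
        value = v(r)
        rows.append(
            MetricResult(m.id, m.spec.structure, m.spec.metric_text,
                         value, m.function(value), m.max_points)
        )
    return ScoreResult(plan.plan_id, card.name, tuple(rows),
                       card.total_points, normalization_factor=r)


def score_plan(
    plan: PlanRecord,
    card: Scorecard,
    normalization: str = "off",
    lenient: bool = False,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> ScoreResult:
    """Score ``plan`` on ``card``.

    The card is rescaled to the plan prescription first when they differ
    (an error for non-scalable cards). ``normalization`` is ``"off"`` or
    ``"max_score"``. In lenient mode unresolvable metrics score 0 points
    and are flagged instead of raising.
    """
    if abs(card.rx_gy - plan.rx_gy) > 1e-9:
        card = card.scaled_to(plan.rx_gy)
        log.info("scorecard '%s' rescaled to plan Rx %g Gy", card.name, plan.rx_gy)
    if normalization == "max_score":
        _, result = normalize_to_max(plan, card, window=window, lenient=lenient)
        return result
    if normalization != "off":
        raise ValueError(f"unknown normalization mode {normalization!r}")

    plan.prepare(card)
    rows = []
    for m in card.metrics:
        try:
            value = evaluate_metric(plan, m.spec)
        except MissingStructure:
            if not lenient:
                raise
            rows.append(MetricResult(m.id, m.spec.structure, m.spec.metric_text,
                                     None, 0.0, m.max_points, "missing"))
            continue
        except NeedsDoseGrid:
            if not lenient:
                raise
            rows.append(MetricResult(m.id, m.spec.structure, m.spec.metric_text,
                                     None, 0.0, m.max_points, "needs_dose_grid"))
            continue
        rows.append(MetricResult(m.id, m.spec.structure, m.spec.metric_text,
                                 value, m.function(value), m.max_points))
    return ScoreResult(plan.plan_id, card.name, tuple(rows), card.total_points)
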