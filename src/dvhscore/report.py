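"""Batch scoring, comparison tables, and CSV reports.

The comparison table mirrors the published report layout: one row per
plan, one column group per scorecard (total points and percent of the
card maximum), and a final row with the arithmetic mean of the plan rows.
Numbers are kept at full precision internally and rounded to two decimals
only at serialization.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyBatch
from .scorecard import Scorecard
from .scoring import PlanRecord, ScoreResult, score_plan

AVERAGE_LABEL = "average"


@dataclass(frozen=True)
class ComparisonTable:
    """Totals and percents of every plan on every card, plus the average row."""

    plan_ids: tuple[str, ...]
    card_names: tuple[str, ...]
    card_max_points: tuple[float, ...]
    totals: np.ndarray  # shape (n_plans, n_cards)
    results: tuple = field(default=(), compare=False)  # optional ScoreResult grid
    flags: tuple = field(default=(), compare=False)

    def __post_init__(self):
        totals = np.asarray(self.totals, dtype=float)
        if totals.shape != (len(self.plan_ids), len(self.card_names)):
            raise ValueError("totals shape must be (n_plans, n_cards)")
        object.__setattr__(self, "totals", totals)

    @property
    def percents(self) -> np.ndarray:
        return 100.0 * self.totals / np.asarray(self.card_max_points)

    @property
    def average_totals(self) -> np.ndarray:
        return self.totals.mean(axis=0)

    @property
    def average_percents(self) -> np.ndarray:
        return self.percents.mean(axis=0)

    def to_dataframe(self, round_decimals: int | None = 2) -> pd.DataFrame:
        """The table with the average row appended; rounded for output."""
        rows = []
        for i, pid in enumerate(self.plan_ids):
            row: dict = {"plan": pid}
            for j, card in enumerate(self.card_names):
                row[f"{card} total"] = self.totals[i, j]
                row[f"{card} %"] = self.percents[i, j]
            rows.append(row)
        avg: dict = {"plan": AVERAGE_LABEL}
        for j, card in enumerate(self.card_names):
            avg[f"{card} total"] = self.average_totals[j]
            avg[f"{card} %"] = self.average_percents[j]
        rows.append(avg)
        df = pd.DataFrame(rows)
        if round_decimals is not None:
            num = df.select_dtypes(include=[float]).columns
            df[num] = df[num].round(round_decimals)
        return df


def batch_score(
    plans: list[PlanRecord],
    cards: list[Scorecard],
    normalization: str = "off",
    lenient: bool = False,
) -> ComparisonTable:
    """Score every plan on every card, in input order, plus an average row."""
    if not plans or not cards:
        raise EmptyBatch("batch scoring needs at least one plan and one card")
    grid: list[list[ScoreResult]] = []
    for plan in plans:
        grid.append([
            score_plan(plan, card, normalization=normalization, lenient=lenient)
            for card in cards
        ])
    totals = np.array([[r.total_points for r in row] for row in grid])
    flags = tuple(
        tuple(",".join(sorted({m.flag for m in r.per_metric if m.flag})) for r in row)
        for row in grid
    )
    return ComparisonTable(
        plan_ids=tuple(p.plan_id for p in plans),
        card_names=tuple(c.name for c in cards),
        card_max_points=tuple(c.total_points for c in cards),
        totals=totals,
        results=tuple(tuple(row) for row in grid),
        flags=flags,
    )


def write_report_csv(
    table: ComparisonTable,
    path,
    detail_path=None,
    timestamp: bool = True,
) -> None:
    """Write the comparison table as RFC-4180 CSV (two-decimal rounding).

    With ``detail_path``, a second file carries one row per plan x metric
    (id, structure, metric text, value, points, max). ``timestamp=False``
    omits the generation-time comment for byte-reproducible output.
    """
    df = table.to_dataframe(round_decimals=2)
    with open(path, "w", newline="") as fh:
        if timestamp:
            fh.write(f"# generated {_dt.datetime.now().isoformat(timespec='seconds')}\n")
        df.to_csv(fh, index=False)
    if detail_path is not None:
        if not table.results:
            raise ValueError("detail output needs a table built by batch_score")
        rows = []
        for row in table.results:
            for res in row:
                for m in res.per_metric:
                    rows.append(
                        {
                            "plan": res.plan_id,
                            "card": res.card_name,
                            "metric_id": m.id,
                            "structure": m.structure,
                            "metric_text": m.metric_text,
                            "value": None if m.value is None else round(m.value, 2),
                            "points": round(m.points, 2),
                            "max_points": m.max_points,
                            "flag": m.flag,
                        }
                    )
        pd.DataFrame(rows).to_csv(detail_path, index=False)
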