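"""Score a TPS DVH export (no dose grid) and rescale a prescription.

DVH-only plans support every metric except the conformation number (which
needs the 3-D dose); prescription scaling multiplies all doses by the Rx
ratio, so protocol limits expressed at another prescription become directly
checkable.
"""

import tempfile
from pathlib import Path

from dvhscore import (
    builtin_scorecard,
    dose_at_volume,
    export_dvh_csv,
    plan_from_dvh_csv,
    scale_prescription,
    score_plan,
    study_plan,
)

src = study_plan("limited_sparing", seed=7)
card = builtin_scorecard("HLS-EC-WB")
src.prepare(card)
for m in card.metrics:
    try:
        src.dvh(m.spec.structure)
    except Exception:
        pass

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "dvh.csv"
    export_dvh_csv(src.dvhs, path)
    plan = plan_from_dvh_csv(path, "tps-export", rx_gy=src.rx_gy)

res = score_plan(plan, card, lenient=True)
skipped = [m.metric_text for m in res.per_metric if m.flag]
print(f"DVH-only score: {res.total_points:.2f} / {res.max_points:g} "
      f"(skipped without a dose grid: {skipped})")

# 20 -> 30 Gy prescription scaling: the hippocampal near-max dose scales
# by 1.5 and can cross the 16 Gy limit of the 30 Gy protocols.
d003_20 = dose_at_volume(plan.dvh("Hippocampi"), 0.03, "cc")
scaled = scale_prescription(plan, 30.0)
d003_30 = dose_at_volume(scaled.dvh("Hippocampi"), 0.03, "cc")
verdict = "VIOLATES" if d003_30 > 16.0 else "meets"
print(f"hippocampus D0.03cc: {d003_20:.2f} Gy @ 20 Gy -> {d003_30:.2f} Gy @ 30 Gy "
      f"({verdict} the 16 Gy limit)")
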