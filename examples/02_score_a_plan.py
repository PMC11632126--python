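"""Score one plan on a built-in dosimetric scorecard.

Each scorecard metric maps a DVH value to points through a piecewise-linear
function (0 points = protocol violation, maximum = aspirational); the total
quantifies how well the plan realizes that card's clinical intent.
"""

from dvhscore import builtin_scorecard, score_plan, study_plan

plan = study_plan("limited_sparing", seed=7)
card = builtin_scorecard("HLS-EC-WB")  # limited-sparing enhanced-coverage, 20 Gy

res = score_plan(plan, card)
print(f"{'id':>3} {'structure':16} {'metric':28} {'value':>8} {'points':>7} {'max':>6}")
for m in res.per_metric:
    print(f"{m.id:>3} {m.structure:16} {m.metric_text:28} "
          f"{m.value:8.2f} {m.points:7.2f} {m.max_points:6.2f}")
print(f"\ntotal: {res.total_points:.2f} / {res.max_points:g} "
      f"({res.percent_of_max:.2f}% of the card maximum)")
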