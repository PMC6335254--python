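"""Recompute the comparison tables behind the study's two analyses.

Loads the packaged per-posture summary tables (13 posture groups, 1,583
images), evaluates the allometric space-allowance formulas and the EU
loading-density minimum at each group's mean live weight, and prints the
signed deviations from the measured covered areas.
"""

from pigplanim import comparison_table, packaged_study_tables, standing_deviation_summary
from pigplanim.rounding import round_half_up

rows = comparison_table(packaged_study_tables())

print(f"{'posture':>8} {'W (kg)':>8} {'measured':>9} {'allometric':>10} "
      f"{'deviation':>9} {'legal min':>9} {'free':>7}")
for r in rows:
    print(f"{r.posture:>8} {r.weight_mean_kg:8.2f} {r.measured_area:9.3f} "
          f"{round_half_up(r.allometric_area, 3):10.3f} "
          f"{round_half_up(r.allometric_deviation, 3):+9.3f} "
          f"{round_half_up(r.legal_min_area, 3):9.3f} "
          f"{round_half_up(r.free_space, 3):+7.3f}")

s = standing_deviation_summary(rows)
print(f"\nstanding allometric deviations: mean {round_half_up(s.mean, 3):.3f} "
      f"± {round_half_up(s.sd, 3):.3f} m², "
      f"max {round_half_up(s.max, 3):.3f} ({s.argmax}), "
      f"min {round_half_up(s.min, 3):.3f} ({s.argmin})")

ll = next(r for r in rows if r.posture == "LL")
print(f"\nA fully recumbent pig covers {ll.measured_area:.3f} m² but the legal"
      f" minimum allots only {round_half_up(ll.legal_min_area, 3):.3f} m²:"
      f" free space {round_half_up(ll.free_space, 3):+.3f} m² — the legal"
      " floor area is smaller than the animal itself.")
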