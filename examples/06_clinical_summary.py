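"""Clinical outcome arithmetic from the packaged group tables.

Two nursing groups of 50 laparoscopic-cystectomy patients each: a
control arm (conventional care) and an experimental arm (perioperative
management).  Everything is computed from printed summary statistics —
complication counts, satisfaction percentages, and (mean, sd) pairs —
via the complication-rate and total-satisfaction formulas and the
two-sample t-test from summaries.
"""

import json

from usdenoise import (complication_rate, load_group_tables,
                       total_satisfaction, two_sample_t)
from usdenoise.clinical import summary_report

groups = load_group_tables()
for key, g in groups.items():
    print(f"{key:13s} complication rate {complication_rate(g):5.1f}%   "
          f"total satisfaction {total_satisfaction(g):5.1f}%")
# experimental: 8% / 98%;  control: 16% / 93%.

me, se = groups["experimental"].continuous_outcomes["hospital_stay_days"]
mc, sc = groups["control"].continuous_outcomes["hospital_stay_days"]
cmp = two_sample_t((me, se, 50), (mc, sc, 50), variant="pooled",
                   outcome="hospital_stay_days")
print(f"\nhospital stay: {me} +/- {se} vs {mc} +/- {sc} days  ->  "
      f"t = {cmp.t_statistic:.3f}, p = {cmp.p_value:.2e} "
      f"({cmp.variant}, df = {cmp.df:.0f})")

print("\nfull report:")
print(json.dumps(summary_report(groups), indent=2)[:600], "...")
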