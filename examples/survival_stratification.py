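"""Median-split survival analysis of a prognostic marker.

Simulates follow-up tied to a lncRNA's expression (higher expression ->
higher hazard), stratifies subjects at the median, and compares the
strata with Kaplan-Meier curves and the log-rank test.
"""

import numpy as np
import pandas as pd

from cernascreen import (
    SimulationConfig,
    generate_cerna_dataset,
    generate_survival_data,
    kaplan_meier,
    logrank,
)

config = SimulationConfig(seed=1234, survival_beta=1.0)
expr_lnc, *_ = generate_cerna_dataset(config)
marker = expr_lnc.feature_ids[0]
expression = pd.Series(expr_lnc.feature_vector(marker), index=expr_lnc.sample_ids)
records = generate_survival_data(expression, config)

high = [r for r in records if r.group == "high"]
low = [r for r in records if r.group == "low"]
print(f"marker {marker}: {len(high)} high / {len(low)} low subjects "
      f"(log hazard ratio per SD = {config.survival_beta})")
for name, group in (("high", high), ("low", low)):
    med = np.median([r.time for r in group])
    events = sum(r.event for r in group)
    print(f"  {name}: median follow-up {med:.1f} months, {events} events")
    curve = kaplan_meier(group)
    print(f"    S(t) at first three event times: "
          + ", ".join(f"{s:.3f}" for s in curve['survival'].iloc[1:4]))

chi2, p = logrank(high, low)
print(f"log-rank: chi2 = {chi2:.2f}, p = {p:.3g}")
# p < 0.05 means the two expression strata have detectably different
# survival, i.e. the marker is prognostic in this cohort.
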