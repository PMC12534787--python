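"""Quantify the protein -> tunnel -> cofactor pathogenicity gradient.

Runs the full in-memory analysis on a synthetic cohort with a planted
gradient: per-protein region means, cohort adherence to the monotone
pattern, and paired t-tests with significance tiers.
"""

import numpy as np

from tunnelgrad import ProteinData, run_cohort
from tunnelgrad.synthetic import CohortSpec, make_cohort_in_memory

spec = CohortSpec(n_proteins=10, seed=42)
proteins = {
    structure.id: ProteinData(structure, tunnels, {"planted": table})
    for structure, tunnels, table in make_cohort_in_memory(spec)
}
report = run_cohort(proteins, {"planted": spec.orientation})

by_region = {}
for s in report.summaries["planted"]:
    by_region.setdefault(s.region, []).append(s.mean_score)
for region in ("protein", "tunnel", "cofactor"):
    vals = by_region[region]
    print(f"{region:8s}: mean score {np.mean(vals):.3f} "
          f"(+/- {np.std(vals, ddof=1):.3f} across proteins)")

adh = report.adherence["planted"]
print(f"adherence: {adh.rate:.1f}% ({adh.n_adhering}/{adh.n_total} proteins "
      "show protein < tunnel < cofactor)")
for t in report.tests["planted"]:
    print(f"{t.comparison[0]} vs {t.comparison[1]}: "
          f"t = {t.t_statistic:.2f}, p = {t.p_value:.2e}, tier {t.stars!r}")

# With the default planted gradient the region means rise toward the
# cofactor, nearly all proteins adhere to the monotone pattern, and both
# paired comparisons are significant at the strictest tier (****).
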