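"""Compare the kNN model's idea of assessment with a reference-value cutoff.

Scalar reflex biomarkers (receptive-field-area-like values) are commonly
judged against an empirical percentile of a healthy reference sample: a
subject above the p95/p90/p75 critical value is flagged as hyperexcitable.
With heavily overlapping class distributions this catches few patients —
the motivation for the histogram/kNN model.
"""

import numpy as np

from nwrpredict import (
    ClassSignalParams,
    CohortSpec,
    biomarker_scalar,
    generate_cohort,
    percentile_baseline,
)

params = ClassSignalParams()  # default: heavy biomarker overlap
cohort = generate_cohort(CohortSpec(n_per_cell=25, sites=(1,), seed=3))
rng = np.random.default_rng(3)
values = {s.subject_id: biomarker_scalar(s, params, rng) for s in cohort}

subjects = list(cohort)
healthy = [s for s in subjects if s.group == "h"]
patients = [s for s in subjects if s.group == "p"]
reference = [values[s.subject_id] for s in healthy[:50]]
queries = [(values[s.subject_id], s.group) for s in healthy[50:] + patients]

for pct in (95, 90, 75):
    rt = percentile_baseline(reference, queries, pct)
    print(f"p{pct}: r_h = {rt.r_h:5.1f}%  r_p = {rt.r_p:5.1f}%  r = {rt.r:5.1f}%")
print("(extreme cutoffs keep nearly all healthy subjects but miss most "
      "patients; relaxing the percentile trades one error for the other)")
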