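"""Translate MRD performance into expected adjuvant-chemotherapy benefit.

About 5.8% of resected stage II-III patients benefit from adjuvant
chemotherapy. If the MRD test concentrates likely recurrences in the
positive group, the expected benefit in the MRD-negative group falls —
the quantity that matters when debating withholding chemotherapy.
"""

import numpy as np

import fragmrd as fm

cohort = fm.sample_cohort(fm.SyntheticCohortConfig(seed=11))
recurrence = np.array([p.recurrence for p in cohort.patients])

cv = fm.run_ttfcv(cohort.patients, cohort.controls, n_repeats=20, n_folds=10, seed=0, n_boot=100)
probs = cv.positive_prob("combined")

result = fm.simulate_benefit(recurrence, probs, benefit_rate=0.058, n_iter=10_000, seed=1)
print("baseline benefit everywhere: 5.8%")
print(
    f"MRD-negative group: median {result.negative.median:.1%} "
    f"(95% interval {result.negative.ci_low:.1%}-{result.negative.ci_high:.1%})"
)
print(
    f"MRD-positive group: median {result.positive.median:.1%} "
    f"(95% interval {result.positive.ci_low:.1%}-{result.positive.ci_high:.1%})"
)
print(
    "\nBenefit is redistributed towards the MRD-positive group in proportion to the\n"
    "per-iteration sensitivity for recurrence; a near-perfect classifier drives the\n"
    "negative group's expected benefit towards zero."
)
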