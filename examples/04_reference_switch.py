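"""The reference-switch experiment.

Eight synthetic subjects of Chinese ancestry are scored twice: first
against a European-ancestry reference ("before"), then against their own
ancestry's reference ("after").  The printed medians show how an
ancestry-mismatched reference inflates the number of apparently atypical
traits per subject — the motivation for population-specific norms.
"""

import numpy as np

from facenorms import ReferenceConfig, compare_references, fit_reference_set, make_cohort_spec
from facenorms.synthetic import records_from_frame, simulate_cohort

cfg = ReferenceConfig(compute_ci=False)
chinese_ref = fit_reference_set(
    records_from_frame(simulate_cohort(make_cohort_spec("chinese", n=760, seed=101))),
    "chinese", config=cfg)
european_ref = fit_reference_set(
    records_from_frame(simulate_cohort(make_cohort_spec("european", n=760, seed=202))),
    "european", config=cfg)

eight = simulate_cohort(make_cohort_spec("chinese", n=8, seed=5))
cmp = compare_references(records_from_frame(eight), european_ref, chinese_ref)

print("subject   flags vs european   flags vs chinese")
for sid, a, b in zip(cmp.subject_ids, cmp.flags_a, cmp.flags_b):
    print(f"  {sid}            {a}                  {b}")
print(f"median flags: {cmp.median_before:.1f} (range {cmp.range_before[0]}-"
      f"{cmp.range_before[1]}) -> {cmp.median_after:.1f} "
      f"(range {cmp.range_after[0]}-{cmp.range_after[1]})")
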