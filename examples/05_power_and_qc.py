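"""Sample-size planning and landmark-placement quality control.

First prints the recruits needed per age/sex band to resolve a half-SD
mean shift under the normal approximation (one-sided 5%, 80% power, 15%
fall-out -> 30 recruits; variants show how sidedness and fall-out move
the number).  Then demonstrates the 5 mm placement-QC rule: a trainee's
landmark set with one point displaced 6 mm fails QC on that landmark.
"""

import numpy as np

from facenorms import DEFAULT_REGISTRY, make_cohort_spec, qc_landmarks, required_sample_size
from facenorms.synthetic import simulate_landmarks

for kwargs in ({}, {"sided": "two"}, {"fallout": 0.0}):
    n = required_sample_size(**kwargs)
    print(f"required recruits per band {kwargs or '(defaults)'}: {n}")

spec = make_cohort_spec("chinese")
targets = {d.name: float(spec.mean(d.name, "F", 8.0)) for d in DEFAULT_REGISTRY}
truth = simulate_landmarks(targets, subject_id="trainee-check")
candidate = simulate_landmarks(targets, subject_id="trainee-check")
candidate.points[("prn", None)] = candidate.points[("prn", None)] + np.array([0.0, 0.0, 6.0])

report = qc_landmarks(candidate, truth)
print(f"QC passed: {report.passed}; landmarks beyond 5 mm: {report.failed_keys}")
print(f"pronasale discrepancy: {report.discrepancies[('prn', None)]:.1f} mm")
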