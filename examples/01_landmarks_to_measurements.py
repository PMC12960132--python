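"""From 3D landmarks to facial measurements.

Builds a synthetic landmark set realising the age-10 male mean of the
Chinese-ancestry preset, then computes the eight shipped measurements.
Each line prints the measurement and its value in mm; because the face
was constructed to hit the preset means exactly, the values equal the
preset's age-10 male growth-curve values.
"""

from facenorms import DEFAULT_REGISTRY, measure_subject, make_cohort_spec
from facenorms.synthetic import simulate_landmarks

spec = make_cohort_spec("chinese")
targets = {d.name: float(spec.mean(d.name, "M", 10.0)) for d in DEFAULT_REGISTRY}
face = simulate_landmarks(targets, subject_id="demo-M-10y")

print(f"subject {face.subject_id}: {len(face.points)} landmarks placed")
for record in measure_subject(face, metadata={"age": 10.0, "sex": "M"}):
    print(f"  {record.measurement:26s} {record.value:7.2f} {record.units}"
          f"  (usable={record.usable})")
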