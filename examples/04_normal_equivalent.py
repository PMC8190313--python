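"""Synthesize a patient's normal equivalent.

Regions of the face outside the span of normal variation are interpolated
from the regions that fit, by an iteratively reweighted projection onto the
age-specific SSM bounded at the Mahalanobis distance whose chi-square tail
probability is 0.05.  The demonstration assesses a juvenile face against an
adult model: characteristically juvenile features are replaced with adult
ones, because the adult SSM codes only adult variation.
"""

from pathlib import Path

import numpy as np

from facegrowth import GenerativeSpec, load_growth_model, simulate_patient
from facegrowth.assess import align_to_expected, normal_equivalent

model_dir = Path("scratch/examples/model")
if not model_dir.exists():
    raise SystemExit("run examples/02_build_growth_curves.py first")

spec = GenerativeSpec()
model = load_growth_model(model_dir)
entry = model.at_age(30.0)  # oldest grid age of the example model

juvenile = simulate_patient(spec, age=2.0, seed=3)
aligned = align_to_expected(juvenile.vertices, entry.expected)
ne = normal_equivalent(aligned, entry.ssm, entry.expected, normals=entry.normals)

rms_in = np.sqrt(np.mean((aligned - entry.expected) ** 2))
rms_ne = np.sqrt(np.mean((ne.vertices - entry.expected) ** 2))
print(f"a {juvenile.age:.0f}-year-old face assessed with the age-"
      f"{entry.age:.0f} model, {ne.iterations} reweighting iterations")
print(f"Mahalanobis D^2 = {ne.mahalanobis_sq:.2f}, tail probability "
      f"{ne.tail_probability:.3f} (never below the 0.05 constraint)")
print(f"RMS distance to the adult expected face: patient {rms_in:.2f} mm -> "
      f"normal equivalent {rms_ne:.2f} mm")
print(f"largest |patient - equivalent| along the surface normal: "
      f"{np.abs(ne.normal_difference).max():.2f} mm -- the juvenile features "
      "the adult model cannot represent")
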