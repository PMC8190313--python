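"""Average a few faces into a 'morph'.

Morphs summarize the typical facies of a small patient group: faces are
co-aligned by GPA with unit-size scaling (so shapes average independently of
size), averaged vertex-wise, then rescaled to the members' mean centroid
size.  The morph's age is the members' mean age.
"""

import numpy as np

from facegrowth import GenerativeSpec, make_morph, simulate_patient

spec = GenerativeSpec()
ages = (2.5, 5.2, 0.4)
members = [simulate_patient(spec, age=a, seed=10 + i, pose=True)
           for i, a in enumerate(ages)]

morph = make_morph(members)

sizes = [m.centroid_size for m in members]
print(f"member ages {ages} -> morph age {morph.age:.1f} years (their mean)")
print(f"member centroid sizes {np.round(sizes, 1)} mm -> morph size "
      f"{morph.size:.1f} mm (their mean)")
print("the morph averages the members' shapes after removing pose and size, "
      "damping individual variation while keeping the shared features")
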