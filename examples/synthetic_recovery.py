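"""Planted-signal validation of the whole field-QSAR pipeline.

Generates a synthetic congeneric series whose activity is, by
construction, a linear function of the steric similarity-index field in a
small lattice region near one substituent site, then checks that the
pipeline (fields -> PLS -> contour map) recovers the planted relationship:
a high cross-validated q2, the correct coefficient sign at the planted
site, and the planted region inside the top decile of |stdev*coeff|.
"""

import numpy as np

from gridqsar import pipeline
from gridqsar.synthetic import SyntheticSpec

print("Noise-free series (signal fully recoverable):")
truth, loo, model, cmap, rep = pipeline.run_synthetic_model(
    SyntheticSpec(n_molecules=40, seed=1, noise_sd=0.0)
)
print(f"  q2 = {rep.q2:.3f} (1.0 means every left-out compound predicted exactly)")
print(f"  sign agreement = {rep.sign_agreement:.0%} (recovered vs planted weight signs)")
print(f"  region overlap = {rep.region_overlap:.0%} of planted points in the top decile")

print("\nEffect of activity noise (median q2 over 5 seeds):")
for noise in (0.0, 0.3, 1.0):
    q2s = [
        pipeline.run_synthetic_model(SyntheticSpec(seed=s, noise_sd=noise))[4].q2
        for s in range(50, 55)
    ]
    print(f"  noise_sd = {noise:.1f} log units -> median q2 = {np.median(q2s):.3f}")
print("q2 degrades as noise drowns the planted structure-activity signal.")
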