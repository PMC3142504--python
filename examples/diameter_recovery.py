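"""Estimate the particle core diameter from a noisy harmonic scan.

The shape of the harmonic profiles depends on the particle moment through
alpha ~ d^3, so scans at different diameters are distinguishable.  A
noiseless model scan is fit to a synthetic noisy observation by grid
search, mirroring how a measured scan brackets the effective core size.
"""

import numpy as np

from acoustic_mpi import FieldConfig, ParticleModel, fit_diameter, simulate_scan

field = FieldConfig(5.0, 2.5e-3, 700.0)
truth = ParticleModel(diameter_m=16e-9)

observed = simulate_scan(field, truth, noise_sigma_rel=0.01, rng=42)
print("synthetic observation: 16 nm particles, 1%-of-peak additive noise")

candidates = np.arange(14, 20) * 1e-9
best = fit_diameter(observed, candidates, field)
print(f"candidates: {[f'{d*1e9:.0f} nm' for d in candidates]}")
print(f"least-squares best fit: {best*1e9:.0f} nm")
print(
    "\nThe grid search minimizes the summed squared magnitude misfit over\n"
    "all three harmonics; at this noise level the true diameter is\n"
    "recovered unambiguously."
)
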