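"""Simulate the vertical scan of a 2 mm tracer sample through the FFP.

Reproduces the simulated counterpart of the bench experiment: the sample
is stepped from +3.25 mm to -3.25 mm in 0.125 mm increments while the
first three harmonic amplitudes of the force signal are recorded, with the
system function averaged over the 2 mm sample extent.
"""

import numpy as np

from acoustic_mpi import FieldConfig, ParticleModel, simulate_scan

field = FieldConfig(gradient_T_per_m=5.0, drive_amplitude_T=2.5e-3,
                    drive_frequency_Hz=700.0)
particle = ParticleModel(diameter_m=17e-9)

profile = simulate_scan(field, particle)
pos_mm = profile.positions_m * 1e3
print(f"{profile.positions_m.size} positions from {pos_mm[0]:+.2f} to "
      f"{pos_mm[-1]:+.2f} mm, sample length {profile.sample_length_m*1e3:.0f} mm")

for h in range(profile.n_harmonics):
    mags = profile.magnitudes[:, h]
    peaks = pos_mm[np.argmax(mags)]
    print(f"harmonic {h+1}: peak magnitude {mags.max():.4f} (a.u.) "
          f"at {peaks:+.3f} mm, value at center {mags[26]:.4f}")

print(
    "\nThe fundamental peaks where the FFP sweeps the sample center; even\n"
    "harmonics vanish there by symmetry and peak off-center, which is the\n"
    "spatial signature used to localize tracer along the scan axis."
)
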