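"""Compare the magnetization and force response curves of a 17 nm tracer.

Acoustic detection senses the force term s(alpha*B) = L + u*L', which rises
twice as steeply at zero field as the magnetization term L(alpha*B) picked
up by a receive coil -- the origin of the doubled spatial resolution.
"""

import numpy as np

from acoustic_mpi import ParticleModel, acoustic_response, magnetic_response

particle = ParticleModel(diameter_m=17e-9)
print(f"particle: 17 nm magnetite core, alpha = {particle.alpha_per_T:.1f} /T")

B = 1e-9
ratio = acoustic_response(B, particle) / magnetic_response(B, particle)
print(f"zero-field slope ratio (acoustic / magnetic): {ratio:.6f}")

for level in (0.5, 0.9):
    grid = np.linspace(1e-6, 0.1, 200_000)
    b_ac = grid[np.searchsorted(acoustic_response(grid, particle), level)]
    b_mag = grid[np.searchsorted(magnetic_response(grid, particle), level)]
    print(
        f"field for {level:.0%} saturation: acoustic {b_ac*1e3:.2f} mT "
        f"vs magnetic {b_mag*1e3:.2f} mT"
    )

print(
    "\nThe force response saturates at roughly half the field of the\n"
    "magnetization response, so the same selection-field gradient localizes\n"
    "the signal about twice as sharply."
)
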