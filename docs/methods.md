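# Methods

## Model

The simulator treats a monodisperse ensemble of single-domain magnetite
nanoparticles in instantaneous thermal equilibrium. The particle moment is
μ = Ms·(π/6)d³ with d the core diameter and Ms the core magnetization
(default: bulk magnetite); the field-scaling parameter is α = μ/(kB·T).
Magnetization follows the Langevin law L(u) = coth(u) − 1/u evaluated at
u = αB, with all "fields" B carried as μ0·H in tesla so that printed
millitesla values can be used verbatim.

Acoustic detection senses the force of the selection-field gradient on the
magnetized sample rather than the magnetization itself. For the 1D case
the normalized force-response term is taken as

    s(u) = d/du [u·L(u)] = L(u) + u·L′(u).

This functional form is a reconstruction: it is the unique term consistent
with the two defining properties of the force channel — zero-field slope
exactly twice that of L (2/3 vs 1/3) and the common saturation limit of 1 —
and both properties are asserted in the test suite. s is odd, monotone
nondecreasing, and dominates L pointwise for u > 0 (s − L = u·L′ ≥ 0), so
the force channel saturates at roughly half the field of the magnetization
channel.

**Assumptions.** Equilibrium (no Néel/Brown relaxation dynamics), a single
particle diameter per run, a strictly 1D field geometry, negligible
acoustic damping, and a rigid sample (no membrane compliance). Size sweeps
are repeated runs, not a polydisperse model.

## System function and scan

A point sample at x in gradient Gx under drive A·sin(ω₀t) sees
B(t) = Gx·x + A·sin(ω₀t). One drive period is sampled at n_samples = 1024
equidistant points (any power of two ≥ 16 is accepted) and Fourier
transformed; harmonic n keeps the one-sided complex amplitude
(2/n_samples)·DFT[n], so a pure unit sinusoid at n·f₀ has magnitude 1.
The signal is smooth and periodic, so the DFT converges spectrally: the
test suite checks that doubling n_samples moves no magnitude by more than
1e-9, and a spot harmonic agrees with an adaptive-quadrature Fourier
integral of the continuous-time signal to 1e-6 relative.

A sample of finite length l integrates force coherently over its extent,
so the boxcar average of width l acts on **complex** amplitudes, not
magnitudes; magnitudes are taken afterwards. The scan simulator evaluates
the system function on an internal grid (default 0.025 mm spacing, ≥ 10
samples per FFP excursion A/Gx = 0.5 mm; a 2 mm window is 81 samples)
enlarged by l/2 on each side, so window averaging never truncates the
reported range. The default protocol reports 53 positions from +3.25 mm
down to −3.25 mm in 0.125 mm steps; data are stored on an ascending grid
with the top-down acquisition order recorded alongside.

An optional additive complex Gaussian perturbation (seeded; standard
deviation expressed as a fraction of the peak magnitude) emulates
measurement noise for the diameter-recovery workflow. This synthetic noise
is white across positions and harmonics; real measurements additionally
show a coherent background with position-dependent phase, broken symmetry
from sample tilt and membrane stiffness, and partial saturation of a
polydisperse tracer — none of which the generator emulates. Passing the
recovery test therefore demonstrates identifiability of the core diameter
under idealized noise, not under experimental systematics.

## Noise floor and sensitivity chain

The thermal acoustic noise floor at a detector of area A in a medium with
impedance ρc is p_noise = sqrt(4·kB·T·ρc·Δf/A) (rms). A measuring time of
1 s is mapped to Δf = 1 Hz; a separate `analyzer_bandwidth_Hz` default of
2 Hz is provided for experiment-style estimates. Water at 310 K uses
ρ = 993 kg/m³ and c = 1523 m/s (ρc ≈ 1.51 MPa·s/m); both are ordinary
config parameters.

The sensitivity chain assumes the drive swings the sample fully between
the saturated branches, so the drive amplitude deliberately does not enter
the estimate: concentration → μ0·M (via Fe₃O₄ stoichiometry: 3 mol Fe per
formula unit, molar mass 231.53 g/mol, density 5200 kg/m³, bulk
Ms = 476 kA/m) → F = M·V·G → p = F/A → SNR = p/p_noise → detection limit
= concentration·n_sigma/SNR (default n_sigma = 5). The chain closes
exactly: detection_limit·SNR/n_sigma reproduces the input concentration.
The bench-geometry estimate spreads the saturated force on the cylindrical
bore sample over the tube cross-section.

## Numerical choices

- **Langevin branches.** coth(u) − 1/u and 1/u² − 1/sinh²(u) cancel
  catastrophically near 0 (absolute error ~ε/u and ~ε/u²). Below
  |u| = 1e-3 truncated Taylor series are used (u/3 − u³/45 + 2u⁵/945 and
  1/3 − u²/15 + 2u⁴/189); at the switchover the branches agree to ≤ 1e-12
  and the series truncation error is ~1e-18. For |u| large enough to
  overflow sinh, 1/sinh² is exactly 0 in floating point, which is the
  correct limit.
- **Degenerate inputs.** Non-finite fields are rejected; zero sample
  length is the identity window; zero bandwidth yields zero noise; zero
  concentration yields zero magnetization. Windows wider than the grid,
  non-positive steps, non-power-of-two sample counts and unknown config
  keys raise typed errors.
- **Determinism.** All file output uses shortest round-trip float
  formatting, LF endings and fixed row order (ascending position, then
  harmonic), so identical inputs produce byte-identical files; the only
  randomness is the optional scan noise, driven by an explicit seed.
- **Problem sizes.** The default scan evaluates 341 internal positions ×
  1024 time samples — well under a second — and the whole test suite,
  including the quadrature cross-checks and the 6-candidate diameter grid
  search, runs in a few seconds.

## Design choices on genuinely open points

- The vertical axis of the simulated harmonic maps is in normalized force
  units (the response term is dimensionless); only shapes and ratios are
  compared, so no absolute acoustic calibration is applied.
- Whether finite-sample averaging acts on complex amplitudes or magnitudes
  is not dictated by the scan protocol itself; the coherent (complex)
  choice follows from linearity of force superposition and is used
  throughout.
- The nanoparticle core magnetization defaults to the bulk magnetite
  value; reduced effective moments of real tracers can be expressed through
  the `core_magnetization_kA_per_m` parameter.

## Known limitations

Single 1D FFP trajectory only; no image reconstruction; no membrane
mechanics, tube acoustics or frequency-dependent microphone response; no
tissue attenuation. The simulator reproduces idealized saturated-sample
estimates, which real polydisperse tracers under a 2.5 mT drive do not
reach — measured pressures fall orders of magnitude below the saturated
estimate, and this gap is outside the model's scope.
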