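"""1D acoustic MPI system function and scan simulation.

The selection field creates a field-free point (FFP); a sinusoidal drive
field sweeps it along x, so a point sample at position x sees the field
B(t) = Gx*x + A*sin(omega0*t).  The periodic force response
s(alpha*B(t)) is decomposed into harmonics of the drive frequency; the map
of the complex harmonic amplitudes over x is the system function.  A
finite sample of length l averages the complex amplitudes over a centered
boxcar of width l (the force superposes coherently over the sample
extent), which is how the simulated curves for a real 2 mm sample are
obtained from the point-sample system function.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError
from .physics import ParticleModel, acoustic_response

__all__ = [
    "FieldConfig",
    "SystemFunctionGrid",
    "HarmonicProfile",
    "time_signal",
    "compute_system_function",
    "convolve_sample",
    "simulate_scan",
    "fit_diameter",
    "write_profile_csv",
    "read_profile_csv",
]


@dataclass(frozen=True)
class FieldConfig:
    """1D selection-field gradient plus sinusoidal drive field.

    gradient_T_per_m is Gx (field carried as mu0*H, tesla per meter);
    drive_amplitude_T is A; drive_frequency_Hz is f0 with
    omega0 = 2*pi*f0.
    """

    gradient_T_per_m: float
    drive_amplitude_T: float
    drive_frequency_Hz: float

    def __post_init__(self) -> None:
        for name in ("gradient_T_per_m", "drive_amplitude_T", "drive_frequency_Hz"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise DomainError(f"{name} must be finite and > 0, got {value!r}")

    @property
    def omega0_rad_per_s(self) -> float:
        return 2.0 * math.pi * self.drive_frequency_Hz


@dataclass(frozen=True)
class SystemFunctionGrid:
    """Complex harmonic amplitudes of the force signal on a spatial grid.

    ``complex_amplitudes[i, n-1]`` is the one-sided complex Fourier
    amplitude of harmonic n (fundamental = 1) at ``positions_m[i]``,
    normalized so a unit-amplitude sinusoid at n*f0 has magnitude 1.
    """

    positions_m: np.ndarray
    complex_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_m, dtype=float)
        amp = np.asarray(self.complex_amplitudes)
        object.__setattr__(self, "positions_m", pos)
        object.__setattr__(self, "complex_amplitudes", amp)
        if pos.ndim != 1 or np.any(np.diff(pos) <= 0):
            raise DomainError("positions_m must be 1D and strictly increasing")
        if amp.shape[0] != pos.size:
            raise DomainError("complex_amplitudes rows must match positions")

    @property
    def n_harmonics(self) -> int:
        return self.complex_amplitudes.shape[1]

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.complex_amplitudes)


@dataclass(frozen=True)
class HarmonicProfile:
    """Per-harmonic traces after finite-sample averaging.

    ``acquisition_order`` records the order in which positions would be
    visited by the scanner (top down); data are stored ascending in x.
    """

    positions_m: np.ndarray
    complex_amplitudes: np.ndarray
    sample_length_m: float
    acquisition_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_m, dtype=float)
        amp = np.asarray(self.complex_amplitudes)
        object.__setattr__(self, "positions_m", pos)
        object.__setattr__(self, "complex_amplitudes", amp)
        if pos.ndim != 1 or np.any(np.diff(pos) <= 0):
            raise DomainError("positions_m must be 1D and strictly increasing")
        if amp.shape[0] != pos.size:
            raise DomainError("complex_amplitudes rows must match positions")
        if self.sample_length_m < 0:
            raise DomainError("sample_length_m must be >= 0")

    @property
    def n_harmonics(self) -> int:
        return self.complex_amplitudes.shape[1]

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.complex_amplitudes)


def _check_n_samples(n_samples: int) -> None:
    if n_samples < 16 or (n_samples & (n_samples - 1)) != 0:
        raise ConfigError(f"n_samples must be a power of two >= 16, got {n_samples}")


def time_signal(
    x: float, field: FieldConfig, particle: ParticleModel, n_samples: int = 1024
) -> np.ndarray:
    """Normalized force signal over one drive period at position x.

    Samples s(alpha*(Gx*x + A*sin(omega0*t))) at t_k = k*T0/n_samples,
    k = 0..n_samples-1; periodic by construction.
    """
    _check_n_samples(n_samples)
    if not math.isfinite(x):
        raise DomainError("x must be finite")
    phase = 2.0 * math.pi * np.arange(n_samples) / n_samples
    B = field.gradient_T_per_m * x + field.drive_amplitude_T * np.sin(phase)
    return np.asarray(acoustic_response(B, particle))


def compute_system_function(
    x_grid,
    field: FieldConfig,
    particle: ParticleModel,
    n_harmonics: int = 3,
    n_samples: int = 1024,
) -> SystemFunctionGrid:
    """Harmonic decomposition of the force signal at each grid position.

    For each x the signal over exactly one period is Fourier transformed;
    harmonic n keeps the one-sided complex amplitude 2/n_samples * DFT[n].
    """
    _check_n_samples(n_samples)
    if not 1 <= n_harmonics < n_samples // 2:
        raise ConfigError(
            f"n_harmonics must satisfy 1 <= n < n_samples/2, got {n_harmonics}"
        )
    pos = np.asarray(x_grid, dtype=float)
    phase = 2.0 * math.pi * np.arange(n_samples) / n_samples
    B = field.gradient_T_per_m * pos[:, None] + field.drive_amplitude_T * np.sin(
        phase
    )[None, :]
    signal = np.asarray(acoustic_response(B, particle))
    spectrum = np.fft.rfft(signal, axis=1) * (2.0 / n_samples)
    return SystemFunctionGrid(pos, spectrum[:, 1 : n_harmonics + 1])


def _uniform_spacing(pos: np.ndarray) -> float:
    dx = np.diff(pos)
    if dx.size == 0:
        raise DomainError("grid needs at least two positions")
    if not np.allclose(dx, dx[0], rtol=1e-9, atol=0.0):
        raise DomainError("grid spacing must be uniform")
    return float(dx[0])


def convolve_sample(
    sf: SystemFunctionGrid, sample_length_m: float
) -> HarmonicProfile:
    """Average the complex amplitudes over the finite sample extent.

    A centered boxcar of width ``sample_length_m`` is applied to the
    complex amplitudes (coherent force superposition); the output grid is
    the subgrid where the window fits entirely.  Zero width is the
    identity.
    """
    if sample_length_m < 0:
        raise DomainError("sample_length_m must be >= 0")
    if sample_length_m == 0:
        return HarmonicProfile(sf.positions_m, sf.complex_amplitudes.copy(), 0.0)
    dx = _uniform_spacing(sf.positions_m)
    half = round(sample_length_m / (2.0 * dx))
    window = 2 * half + 1
    if window > sf.positions_m.size:
        raise DomainError(
            f"averaging window ({window} samples) wider than the grid "
            f"({sf.positions_m.size} samples)"
        )
    if half == 0:
        return HarmonicProfile(
            sf.positions_m, sf.complex_amplitudes.copy(), sample_length_m
        )
    kernel = np.full(window, 1.0 / window)
    averaged = np.empty(
        (sf.positions_m.size - 2 * half, sf.n_harmonics), dtype=complex
    )
    for h in range(sf.n_harmonics):
        averaged[:, h] = np.convolve(sf.complex_amplitudes[:, h], kernel, mode="valid")
    return HarmonicProfile(
        sf.positions_m[half:-half], averaged, sample_length_m
    )


def _near_integer(value: float, name: str) -> int:
    n = round(value)
    if abs(value - n) > 1e-6 * max(1.0, abs(value)):
        raise ConfigError(f"{name} must be (near-)integer, got {value}")
    return int(n)


def simulate_scan(
    field: FieldConfig,
    particle: ParticleModel,
    sample_length_m: float = 2e-3,
    scan_halfwidth_m: float = 3.25e-3,
    step_m: float = 0.125e-3,
    n_harmonics: int = 3,
    n_samples: int = 1024,
    grid_spacing_m: float = 0.025e-3,
    noise_sigma_rel: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> HarmonicProfile:
    """Simulate the vertical point-by-point scan of a finite sample.

    The scanner starts ``scan_halfwidth_m`` above the center and steps
    downward in ``step_m`` increments (defaults: +-3.25 mm at 0.125 mm,
    i.e. 53 positions over 6.5 mm), recording the first ``n_harmonics``
    harmonic amplitudes at each stop.  The system function is evaluated on
    a finer internal grid enlarged by half the sample length on each side,
    so finite-sample averaging never truncates the reported scan range.

    ``noise_sigma_rel`` optionally adds seeded complex Gaussian noise with
    standard deviation ``noise_sigma_rel * max magnitude`` per quadrature
    component, emulating measurement noise.
    """
    if step_m <= 0:
        raise ConfigError(f"step_m must be > 0, got {step_m}")
    if grid_spacing_m <= 0:
        raise ConfigError(f"grid_spacing_m must be > 0, got {grid_spacing_m}")
    if sample_length_m < 0:
        raise DomainError("sample_length_m must be >= 0")
    k_half = _near_integer(scan_halfwidth_m / grid_spacing_m, "halfwidth/spacing")
    stride = _near_integer(step_m / grid_spacing_m, "step/spacing")
    _near_integer(2.0 * scan_halfwidth_m / step_m, "scan range/step")
    pad = round(sample_length_m / (2.0 * grid_spacing_m))
    k = np.arange(-(k_half + pad), k_half + pad + 1)
    internal_grid = k * grid_spacing_m
    sf = compute_system_function(internal_grid, field, particle, n_harmonics, n_samples)
    profile = convolve_sample(sf, sample_length_m)
    keep = np.arange(0, 2 * k_half + 1, stride)
    positions = profile.positions_m[keep]
    amplitudes = profile.complex_amplitudes[keep].copy()
    if noise_sigma_rel > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        sigma = noise_sigma_rel * float(np.max(np.abs(amplitudes)))
        amplitudes = amplitudes + sigma * (
            gen.standard_normal(amplitudes.shape)
            + 1j * gen.standard_normal(amplitudes.shape)
        )
    order = np.arange(positions.size)[::-1]  # scanned top -> down
    return HarmonicProfile(positions, amplitudes, sample_length_m, order)


def fit_diameter(
    observed: HarmonicProfile,
    candidate_diameters_m,
    field: FieldConfig,
    core_magnetization_A_per_m: float | None = None,
    temperature_K: float | None = None,
    **scan_kwargs,
) -> float:
    """Grid-search the particle diameter that best explains a scan.

    Simulates a noiseless scan on the observed grid for each candidate
    diameter and returns the one minimizing the summed squared magnitude
    misfit over all harmonics.
    """
    pos = observed.positions_m
    step = _uniform_spacing(pos)
    halfwidth = float(pos[-1])
    best_d, best_cost = None, math.inf
    for d in candidate_diameters_m:
        kwargs = {}
        if core_magnetization_A_per_m is not None:
            kwargs["core_magnetization_A_per_m"] = core_magnetization_A_per_m
        if temperature_K is not None:
            kwargs["temperature_K"] = temperature_K
        particle = ParticleModel(diameter_m=d, **kwargs)
        sim = simulate_scan(
            field,
            particle,
            sample_length_m=observed.sample_length_m,
            scan_halfwidth_m=halfwidth,
            step_m=step,
            n_harmonics=observed.n_harmonics,
            **scan_kwargs,
        )
        cost = float(np.sum((sim.magnitudes - observed.magnitudes) ** 2))
        if cost < best_cost:
            best_d, best_cost = float(d), cost
    return best_d


def write_profile_csv(profile: HarmonicProfile, path) -> None:
    """Write a harmonic profile as CSV.

    Columns: position_mm, harmonic, magnitude, real, imag.  Rows ascend by
    position, then harmonic; floats use the shortest round-trip
    representation so the file is bit-reproducible and lossless.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["position_mm", "harmonic", "magnitude", "real", "imag"])
        for i, x in enumerate(profile.positions_m):
            for h in range(profile.n_harmonics):
                c = complex(profile.complex_amplitudes[i, h])
                writer.writerow(
                    [
                        repr(float(x) * 1e3),
                        h + 1,
                        repr(abs(c)),
                        repr(c.real),
                        repr(c.imag),
                    ]
                )


def read_profile_csv(path, sample_length_m: float = 0.0) -> HarmonicProfile:
    """Read a harmonic profile written by :func:`write_profile_csv`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["position_mm", "harmonic", "magnitude", "real", "imag"]:
            raise DomainError(f"unexpected CSV header: {header}")
        rows = [(float(r[0]), int(r[1]), float(r[3]), float(r[4])) for r in reader]
    positions_mm = sorted({r[0] for r in rows})
    harmonics = sorted({r[1] for r in rows})
    if harmonics != list(range(1, len(harmonics) + 1)):
        raise DomainError("harmonic indices must run 1..n")
    index = {x: i for i, x in enumerate(positions_mm)}
    amp = np.zeros((len(positions_mm), len(harmonics)), dtype=complex)
    for x, h, re, im in rows:
        amp[index[x], h - 1] = re + 1j * im
    return HarmonicProfile(
        np.asarray(positions_mm) * 1e-3, amp, sample_length_m
    )
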