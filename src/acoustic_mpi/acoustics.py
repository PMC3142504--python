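"""Thermal acoustic noise floor and the sensitivity chain.

The smallest pressure a detector of area A can resolve is set by thermal
fluctuations of the medium:

    p_noise = sqrt(4 * kB * T * Re(Z) * df / A),   Re(Z) = rho * c,

with df the detection bandwidth (a 1 s measurement corresponds to 1 Hz)
and rho*c the real part of the specific acoustic impedance.  The
sensitivity chain for a saturated tracer sample is

    concentration -> mu0*M -> F = M*V*G -> p = F/A -> SNR = p/p_noise
    -> detection limit = concentration * n_sigma / SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    DEFAULT_TEMPERATURE_K,
    KB,
    WATER_DENSITY_310K_KG_PER_M3,
    WATER_SOUND_SPEED_310K_M_PER_S,
)
from .errors import DomainError
from .physics import (
    TracerSuspension,
    force_on_saturated_sample,
    saturation_magnetization_from_concentration,
)

__all__ = [
    "AcousticChannel",
    "ExperimentGeometry",
    "SensitivityReport",
    "thermal_noise_pressure",
    "pressure_from_force",
    "sensitivity_report",
    "expected_experiment_pressure",
]


@dataclass(frozen=True)
class AcousticChannel:
    """Acoustic detection channel: detector, medium and bandwidth.

    Bandwidth may be zero (a limit with vanishing noise); every other
    field must be strictly positive.  The acoustic impedance rho*c is
    always derived, never stored.
    """

    detector_area_m2: float
    medium_density_kg_per_m3: float = WATER_DENSITY_310K_KG_PER_M3
    speed_of_sound_m_per_s: float = WATER_SOUND_SPEED_310K_M_PER_S
    bandwidth_Hz: float = 1.0
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        for name in (
            "detector_area_m2",
            "medium_density_kg_per_m3",
            "speed_of_sound_m_per_s",
            "temperature_K",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise DomainError(f"{name} must be finite and > 0, got {value!r}")
        if not (math.isfinite(self.bandwidth_Hz) and self.bandwidth_Hz >= 0):
            raise DomainError(
                f"bandwidth_Hz must be finite and >= 0, got {self.bandwidth_Hz!r}"
            )

    @property
    def impedance_Pa_s_per_m(self) -> float:
        """Real part of the specific acoustic impedance rho*c."""
        return self.medium_density_kg_per_m3 * self.speed_of_sound_m_per_s


@dataclass(frozen=True)
class ExperimentGeometry:
    """Cylindrical sample bore glued to the mouth of a sound-guide tube."""

    sample_bore_diameter_m: float = 1.5e-3
    sample_bore_length_m: float = 2e-3
    tube_inner_diameter_m: float = 6.3e-3

    def __post_init__(self) -> None:
        for name in (
            "sample_bore_diameter_m",
            "sample_bore_length_m",
            "tube_inner_diameter_m",
        ):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise DomainError(f"{name} must be finite and > 0, got {value!r}")
        if self.sample_bore_diameter_m >= self.tube_inner_diameter_m:
            raise DomainError("sample bore must be narrower than the tube")

    @property
    def sample_volume_m3(self) -> float:
        return (
            math.pi * (self.sample_bore_diameter_m / 2.0) ** 2
            * self.sample_bore_length_m
        )

    @property
    def tube_area_m2(self) -> float:
        return math.pi * (self.tube_inner_diameter_m / 2.0) ** 2


@dataclass(frozen=True)
class SensitivityReport:
    """Chained sensitivity quantities, with units in the field names."""

    iron_concentration_mol_per_l: float
    saturation_magnetization_T: float
    force_N: float
    signal_pressure_Pa: float
    noise_pressure_Pa: float
    snr_dimensionless: float
    detection_limit_mol_per_l: float
    n_sigma: float

    def to_text(self) -> str:
        """Serialize as flat ``key = value`` lines (lossless floats)."""
        lines = [
            f"{name} = {getattr(self, name)!r}"
            for name in self.__dataclass_fields__
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SensitivityReport":
        values = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = float(raw.strip())
        return cls(**values)


def thermal_noise_pressure(channel: AcousticChannel) -> float:
    """Thermal rms noise pressure sqrt(4*kB*T*rho*c*df/A) [Pa].

    Scales as sqrt(bandwidth) and 1/sqrt(detector area).
    """
    return math.sqrt(
        4.0
        * KB
        * channel.temperature_K
        * channel.impedance_Pa_s_per_m
        * channel.bandwidth_Hz
        / channel.detector_area_m2
    )


def pressure_from_force(force_N: float, area_m2: float) -> float:
    """Pressure exerted by a force over an area [Pa]."""
    if not (math.isfinite(area_m2) and area_m2 > 0):
        raise DomainError(f"area_m2 must be finite and > 0, got {area_m2!r}")
    if not math.isfinite(force_N):
        raise DomainError("force_N must be finite")
    return force_N / area_m2


def sensitivity_report(
    suspension: TracerSuspension,
    volume_m3: float,
    gradient_T_per_m: float,
    channel: AcousticChannel,
    n_sigma: float = 5.0,
) -> SensitivityReport:
    """Full sensitivity chain for a saturated sample in a gradient field.

    Assumes the drive field swings the sample fully between the two
    saturated branches, so the signal pressure is the saturated force over
    the detector area; the detection limit is the concentration at which
    the signal equals ``n_sigma`` noise standard deviations.
    """
    if n_sigma < 1:
        raise DomainError(f"n_sigma must be >= 1, got {n_sigma!r}")
    magnetization_T = saturation_magnetization_from_concentration(suspension)
    force = force_on_saturated_sample(magnetization_T, volume_m3, gradient_T_per_m)
    signal = pressure_from_force(force, channel.detector_area_m2)
    noise = thermal_noise_pressure(channel)
    if noise <= 0:
        raise DomainError("noise pressure is zero; SNR undefined")
    snr = signal / noise
    limit = suspension.iron_concentration_mol_per_l * n_sigma / snr
    return SensitivityReport(
        iron_concentration_mol_per_l=suspension.iron_concentration_mol_per_l,
        saturation_magnetization_T=magnetization_T,
        force_N=force,
        signal_pressure_Pa=signal,
        noise_pressure_Pa=noise,
        snr_dimensionless=snr,
        detection_limit_mol_per_l=limit,
        n_sigma=float(n_sigma),
    )


def expected_experiment_pressure(
    suspension: TracerSuspension,
    geometry: ExperimentGeometry,
    gradient_T_per_m: float,
) -> float:
    """Pressure expected at the tube mouth from the saturated bore sample.

    The saturated force on the cylindrical sample is spread over the tube
    cross section: p = M*V*G / (pi*(d_tube/2)^2).
    """
    magnetization_T = saturation_magnetization_from_concentration(suspension)
    force = force_on_saturated_sample(
        magnetization_T, geometry.sample_volume_m3, gradient_T_per_m
    )
    return force / geometry.tube_area_m2
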