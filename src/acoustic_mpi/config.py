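"""Run configuration: defaults, plain-text loading and validation.

The configuration file is flat ``key = value`` text ('#' comments and
blank lines allowed).  Every key has a default equal to the reference
experiment's operating point: 5 T/m gradient, 2.5 mT drive at 700 Hz,
17 nm particles at 310 K, 0.5 mol(Fe)/l tracer, 1.5 mm x 2 mm sample bore
in a 6.3 mm tube, +-3.25 mm scan at 0.125 mm steps with a 2 mm sample.
Unknown keys are rejected so typos never silently revert to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .acoustics import AcousticChannel, ExperimentGeometry
from .errors import ConfigError, DomainError
from .physics import ParticleModel, TracerSuspension
from .system_function import FieldConfig

__all__ = ["RunConfig", "load_config", "write_config"]

_INT_KEYS = {"n_samples", "n_harmonics", "seed"}


@dataclass(frozen=True)
class RunConfig:
    # particle
    diameter_nm: float = 17.0
    core_magnetization_kA_per_m: float = 476.0
    temperature_K: float = 310.0
    # field
    gradient_T_per_m: float = 5.0
    drive_amplitude_mT: float = 2.5
    drive_frequency_Hz: float = 700.0
    # tracer
    iron_concentration_mol_per_l: float = 0.5
    # acoustic channel
    detector_area_mm2: float = 1.0
    medium_density_kg_per_m3: float = 993.0
    speed_of_sound_m_per_s: float = 1523.0
    bandwidth_Hz: float = 1.0
    analyzer_bandwidth_Hz: float = 2.0  # experiment-mode spectrum analyzer
    sensitivity_volume_mm3: float = 1.0  # reference cube for the SNR estimate
    # geometry
    bore_diameter_mm: float = 1.5
    bore_length_mm: float = 2.0
    tube_diameter_mm: float = 6.3
    # scan protocol
    scan_halfwidth_mm: float = 3.25
    scan_step_mm: float = 0.125
    sample_length_mm: float = 2.0
    # numerics
    n_samples: int = 1024
    n_harmonics: int = 3
    grid_spacing_mm: float = 0.025
    noise_sigma_rel: float = 0.0
    n_sigma: float = 5.0
    seed: int = 0

    def particle(self) -> ParticleModel:
        return ParticleModel(
            diameter_m=self.diameter_nm * 1e-9,
            core_magnetization_A_per_m=self.core_magnetization_kA_per_m * 1e3,
            temperature_K=self.temperature_K,
        )

    def field(self) -> FieldConfig:
        return FieldConfig(
            gradient_T_per_m=self.gradient_T_per_m,
            drive_amplitude_T=self.drive_amplitude_mT * 1e-3,
            drive_frequency_Hz=self.drive_frequency_Hz,
        )

    def suspension(self) -> TracerSuspension:
        return TracerSuspension(self.iron_concentration_mol_per_l)

    def channel(self) -> AcousticChannel:
        return AcousticChannel(
            detector_area_m2=self.detector_area_mm2 * 1e-6,
            medium_density_kg_per_m3=self.medium_density_kg_per_m3,
            speed_of_sound_m_per_s=self.speed_of_sound_m_per_s,
            bandwidth_Hz=self.bandwidth_Hz,
            temperature_K=self.temperature_K,
        )

    def geometry(self) -> ExperimentGeometry:
        return ExperimentGeometry(
            sample_bore_diameter_m=self.bore_diameter_mm * 1e-3,
            sample_bore_length_m=self.bore_length_mm * 1e-3,
            tube_inner_diameter_m=self.tube_diameter_mm * 1e-3,
        )

    def validate(self) -> "RunConfig":
        """Instantiate every derived object so invariants are enforced."""
        try:
            self.particle()
            self.field()
            self.suspension()
            self.channel()
            self.geometry()
        except DomainError as exc:
            raise ConfigError(str(exc)) from exc
        if self.n_samples < 16 or (self.n_samples & (self.n_samples - 1)) != 0:
            raise ConfigError(f"n_samples must be a power of two >= 16, got {self.n_samples}")
        if not 1 <= self.n_harmonics < self.n_samples // 2:
            raise ConfigError(f"n_harmonics out of range: {self.n_harmonics}")
        for key in ("scan_halfwidth_mm", "scan_step_mm", "grid_spacing_mm"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0")
        if self.sample_length_mm < 0:
            raise ConfigError("sample_length_mm must be >= 0")
        if self.n_sigma < 1:
            raise ConfigError("n_sigma must be >= 1")
        return self

    def describe(self) -> str:
        """One ``key = value`` line per setting (units live in key names)."""
        return "\n".join(
            f"{f.name} = {getattr(self, f.name)!r}"
            for f in dataclasses.fields(self)
        )


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    try:
        return int(raw) if key in _INT_KEYS else float(raw)
    except ValueError as exc:
        raise ConfigError(f"non-numeric value for {key!r}: {raw!r}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a file plus override pairs.

    Defaults apply first, then file entries, then ``overrides`` (which
    win).  Unknown keys raise :class:`ConfigError` naming the key.
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, sep, raw = line.partition("=")
                key = key.strip()
                if not sep:
                    raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
                if key not in known:
                    raise ConfigError(f"unknown configuration key: {key!r}")
                values[key] = _parse_value(key, raw)
    for key, raw in (overrides or {}).items():
        if key not in known:
            raise ConfigError(f"unknown configuration key: {key!r}")
        values[key] = _parse_value(key, str(raw))
    return RunConfig(**values).validate()


def write_config(config: RunConfig, path) -> None:
    """Write a config file that reloads to an identical RunConfig."""
    with open(path, "w") as fh:
        fh.write(config.describe() + "\n")
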