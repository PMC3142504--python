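import pytest

from acoustic_mpi import ParticleModel, FieldConfig, TracerSuspension, AcousticChannel


@pytest.fixture
def particle():
    """17 nm magnetite core at body temperature (alpha ~ 286 /T)."""
    return ParticleModel(diameter_m=17e-9)


@pytest.fixture
def field():
    """Reference operating point: 5 T/m gradient, 2.5 mT drive at 700 Hz."""
    return FieldConfig(
        gradient_T_per_m=5.0, drive_amplitude_T=2.5e-3, drive_frequency_Hz=700.0
    )


@pytest.fixture
def resovist():
    """Undiluted Resovist-like suspension, 0.5 mol(Fe)/l as magnetite."""
    return TracerSuspension(iron_concentration_mol_per_l=0.5)


@pytest.fixture
def water_channel():
    """1 mm^2 detector in water at 310 K, 1 Hz bandwidth."""
    return AcousticChannel(detector_area_m2=1e-6)
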