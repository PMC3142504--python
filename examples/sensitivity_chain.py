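"""Walk the full sensitivity chain of acoustic tracer detection.

Chains tracer concentration -> saturation magnetization -> force in the
selection-field gradient -> pressure on the detector -> thermal noise
floor -> SNR -> 5-sigma detection limit, at the default operating point.
"""

from acoustic_mpi import (
    AcousticChannel,
    ExperimentGeometry,
    TracerSuspension,
    expected_experiment_pressure,
    sensitivity_report,
)

suspension = TracerSuspension(iron_concentration_mol_per_l=0.5)
channel = AcousticChannel(detector_area_m2=1e-6)  # 1 mm^2, water, 310 K, 1 Hz

report = sensitivity_report(
    suspension, volume_m3=1e-9, gradient_T_per_m=5.0, channel=channel, n_sigma=5
)
print(f"saturation magnetization : {report.saturation_magnetization_T*1e3:.2f} mT")
print(f"force on 1 mm^3 sample   : {report.force_N*1e6:.1f} uN")
print(f"signal pressure (1 mm^2) : {report.signal_pressure_Pa:.1f} Pa")
print(f"thermal noise pressure   : {report.noise_pressure_Pa*1e6:.1f} uPa rms")
print(f"SNR (1 s measurement)    : {report.snr_dimensionless:.3g}")
print(f"5-sigma detection limit  : {report.detection_limit_mol_per_l*1e6:.1f} umol(Fe)/l")

pressure = expected_experiment_pressure(suspension, ExperimentGeometry(), 5.0)
print(f"\nbench experiment: {pressure:.2f} Pa expected at the 6.3 mm tube mouth")
print(
    "\nA fully saturated millimeter-scale sample sits ~5 orders of magnitude\n"
    "above the thermal acoustic noise floor, putting micromolar iron\n"
    "concentrations within reach of a one-second measurement."
)
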