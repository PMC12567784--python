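"""Simulate the 2 h rat inhalation study and print organ content-time values.

Builds the calibration exposure (bolus deposits: 40 ng tracheobronchial,
892 ng alveolar), integrates the 23-state model over 1500 h and prints each
organ observable at the study's sampling times, plus its peak and time to
half-peak.  Contents are whole-organ TiO2 nanoparticle masses in ng.
"""
import nanopbtk as npk

params = npk.default_parameters()
preset = npk.kreyling_preset()
result = npk.run_simulation(params, preset.scenario, t_end=1500.0,
                            observation_times=preset.observation_times)

print(f"deposited dose: {preset.scenario.delivered(0):.0f} ng")
print(f"mass-balance residual: {npk.mass_balance_audit(result, preset.scenario):.2e} ng\n")
header = "observable        " + "".join(f"{t:>10.0f} h" for t in preset.observation_times)
print(header)
for name in npk.DEFAULT_OBSERVABLES:
    series = npk.extract_observable(result, npk.DEFAULT_OBSERVABLES, name)
    row = "".join(f"{series.loc[t]:>12.3g}" for t in preset.observation_times)
    print(f"{name:<18}{row}")

print("\npeaks (value, time, first time at half peak):")
for name in ("lung", "liver", "kidney", "spleen"):
    series = npk.extract_observable(result, npk.DEFAULT_OBSERVABLES, name)
    peak = npk.peak_analysis(series)
    half = f"{peak.half_time:7.1f} h" if peak.half_time else "not reached"
    print(f"  {name:<8} {peak.value:8.3g} ng at {peak.time:6.1f} h, half at {half}")
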