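"""Scenario presets for the two published rat inhalation studies, and
synthetic observed datasets.

The calibration study (Kreyling et al.) exposed Wistar Kyoto rats to 20 nm
TiO2 aerosol for 2 h and sacrificed groups at 4, 24, 168 and 674 h; its
post-exposure state is represented here as an instantaneous deposit of
40 ng in the tracheobronchial and 892 ng in the alveolar region.  The
validation study (Gosens et al.) was a single 6 h nose-only exposure at
20 mg/m^3; its breathing rate and regional deposition fractions were not
published and must be supplied by the caller.

The real measured contents exist only as figure points, so evaluation and
calibration paths are exercised against synthetic datasets: the model is
simulated and multiplicative lognormal noise (natural for strictly positive
contents spanning orders of magnitude) is applied per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import ObservedDataset
from .model import ExposureScenario
from .parameters import ParameterSet
from .simulate import DEFAULT_OBSERVABLES, extract_observable, run_simulation

__all__ = [
    "ScenarioPreset",
    "kreyling_preset",
    "gosens_preset",
    "generate_observed",
    "mg_per_m3_to_ng_per_l",
]


def mg_per_m3_to_ng_per_l(value: float) -> float:
    """Aerosol concentration conversion: 1 mg/m^3 = 1e6 ng / 1e3 L = 1e3 ng/L."""
    return value * 1.0e3


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    scenario: ExposureScenario
    t_end: float                      # recommended simulation horizon, h
    observation_times: tuple[float, ...]  # h

    def __post_init__(self):
        if any(t < 0 or t > self.t_end for t in self.observation_times):
            raise ValueError("observation times must lie within [0, t_end]")


def kreyling_preset() -> ScenarioPreset:
    """Calibration exposure: bolus deposits 40 ng (tracheobronchial) and
    892 ng (alveolar) at t = 0; observations at 4, 24, 168 and 674 h."""
    scenario = ExposureScenario(mode="bolus",
                                deposits={"tra": 40.0, "alv": 892.0})
    return ScenarioPreset(name="kreyling", scenario=scenario, t_end=1500.0,
                          observation_times=(4.0, 24.0, 168.0, 674.0))


def gosens_preset(BR: float, FR: tuple[float, float, float],
                  t_end: float = 674.0,
                  observation_times: tuple[float, ...] = (24.0, 168.0, 674.0),
                  ) -> ScenarioPreset:
    """Validation exposure: continuous 6 h inhalation of a 20 mg/m^3 aerosol.

    ``BR`` is the breathing rate in L/min and ``FR`` the (upper airway,
    tracheobronchial, alveolar) deposition fractions; neither was published
    for this study, so both are required arguments.
    """
    if BR <= 0:
        raise ValueError("BR must be strictly positive")
    fr_upp, fr_tra, fr_alv = FR
    scenario = ExposureScenario(
        mode="continuous", EC=mg_per_m3_to_ng_per_l(20.0), BR=BR,
        duration=6.0, FR_upp=fr_upp, FR_tra=fr_tra, FR_alv=fr_alv)
    return ScenarioPreset(name="gosens", scenario=scenario, t_end=t_end,
                          observation_times=observation_times)


def generate_observed(params: ParameterSet, preset: ScenarioPreset,
                      noise_cv: float = 0.2, replicates: int = 4,
                      seed: int | None = None, *,
                      observables=None, rtol: float = 1e-8,
                      atol: float = 1e-12) -> ObservedDataset:
    """Simulate the preset and emulate a measured dataset with noise.

    Each observable is sampled at the preset's observation times; every
    replicate receives independent multiplicative lognormal noise with
    coefficient of variation ``noise_cv`` (sigma^2 = ln(1 + cv^2), unit
    mean), and per-time mean and sd across replicates are reported.  Fully
    reproducible from ``seed``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    observables = dict(observables or DEFAULT_OBSERVABLES)
    rng = np.random.default_rng(seed)
    times = np.asarray(preset.observation_times, dtype=float)
    result = run_simulation(params, preset.scenario,
                            t_end=max(preset.t_end, float(times.max())),
                            rtol=rtol, atol=atol, observation_times=times)
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    rows = []
    for name in observables:
        series = extract_observable(result, observables, name)
        truth = np.interp(times, series.index.to_numpy(), series.to_numpy())
        for t, mu in zip(times, truth):
            if noise_cv == 0:
                rows.append((name, float(t), float(mu), 0.0))
                continue
            factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma,
                                    size=replicates)
            samples = mu * factors
            rows.append((name, float(t), float(np.mean(samples)),
                         float(np.std(samples, ddof=1)) if replicates > 1 else 0.0))
    return ObservedDataset.from_records(rows)
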