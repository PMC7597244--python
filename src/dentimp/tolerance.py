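"""Robustness of the EIA-component emulator circuits.

Three practical-design analyses for the recurrent tissue emulators:

* **Temperature.** Each resistor drifts linearly with temperature at
  tc_R ppm/deg C and each capacitor at tc_C ppm/deg C (typical surface-mount
  chip components: 200 and 30).  The sign of the drift is not known per
  part, so a worst-case envelope is taken over four corners: both
  temperature extremes with both uniform tempco signs.
* **Manufacturing tolerance.** Monte-Carlo perturbation of every R and C by
  independent Gaussians; a +/-x % tolerance is interpreted as the 3-sigma
  bound (the usual SPICE convention; configurable).
* **Thermal noise.** For a passive one-port, Johnson–Nyquist noise has
  voltage spectral density sqrt(4 k T Re Z(j omega)) per unit bandwidth;
  ideal capacitors are lossless and contribute nothing, so the real part of
  the port impedance carries all of the resistors' noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple, Union

import numpy as np
from scipy.constants import k as _BOLTZMANN

from .circuits import (
    EmulatedTissueModel,
    FrequencyGrid,
    ImpedanceSpectrum,
    ValsaNetwork,
    _emulated_values,
    _valsa_values,
    circuit_impedance,
)

__all__ = [
    "ToleranceConfig",
    "TemperatureEnvelope",
    "MonteCarloSample",
    "NoiseSpectrum",
    "temperature_envelope",
    "monte_carlo",
    "thermal_noise_density",
]

Perturbable = Union[EmulatedTissueModel, ValsaNetwork]


@dataclass(frozen=True)
class ToleranceConfig:
    """Temperature, tolerance and iteration settings for robustness runs."""

    tempco_r_ppm: float = 200.0
    tempco_c_ppm: float = 30.0
    t_min_c: float = -40.0
    t_max_c: float = 125.0
    t_nominal_c: float = 27.0
    component_tolerance_pct: float = 1.0
    sigma_rule: float = 3.0
    n_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_min_c < self.t_nominal_c < self.t_max_c:
            raise ValueError("require t_min_c < t_nominal_c < t_max_c")
        if self.component_tolerance_pct < 0:
            raise ValueError("component tolerance must be non-negative")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.sigma_rule <= 0:
            raise ValueError("sigma_rule must be positive")


@dataclass(frozen=True)
class TemperatureEnvelope:
    """Per-frequency worst-case deviation from the nominal-temperature run."""

    frequencies: np.ndarray
    magnitude_deviation_pct: np.ndarray
    phase_deviation_deg: np.ndarray

    @property
    def max_magnitude_deviation_pct(self) -> float:
        return float(np.max(self.magnitude_deviation_pct))

    @property
    def max_phase_deviation_deg(self) -> float:
        return float(np.max(self.phase_deviation_deg))


@dataclass(frozen=True)
class MonteCarloSample:
    """Sampled |Z| (ohm) and phase (deg) at one query frequency."""

    frequency_hz: float
    magnitude: np.ndarray
    phase_deg: np.ndarray


@dataclass(frozen=True)
class NoiseSpectrum:
    """Thermal noise voltage density in nV/sqrt(Hz) versus frequency."""

    frequencies: np.ndarray
    density_nv: np.ndarray


# --- component bookkeeping --------------------------------------------------


def _network_values(net: ValsaNetwork) -> Tuple[np.ndarray, np.ndarray]:
    r = np.array([net.r_p] + [b[0] for b in net.branches])
    c = np.array([net.c_p] + [b[1] for b in net.branches])
    return r, c


def _network_from_values(r: np.ndarray, c: np.ndarray) -> ValsaNetwork:
    return ValsaNetwork(r_p=r[0], c_p=c[0], branches=tuple(zip(r[1:], c[1:])))


def component_values(circuit: Perturbable) -> Tuple[np.ndarray, np.ndarray]:
    """All resistor and capacitor values of a circuit, as two flat arrays."""
    if isinstance(circuit, ValsaNetwork):
        return _network_values(circuit)
    r_s, c_s = _network_values(circuit.network_s)
    r_d, c_d = _network_values(circuit.network_d)
    r = np.concatenate([[circuit.r_ss, circuit.r_s, circuit.r_d], r_s, r_d])
    return r, np.concatenate([c_s, c_d])


def circuit_from_values(
    circuit: Perturbable, r: np.ndarray, c: np.ndarray
) -> Perturbable:
    """Rebuild a circuit of the same shape from flat component arrays."""
    if isinstance(circuit, ValsaNetwork):
        return _network_from_values(r, c)
    n_s = circuit.network_s.n_branches + 1
    net_s = _network_from_values(r[3 : 3 + n_s], c[:n_s])
    net_d = _network_from_values(r[3 + n_s :], c[n_s:])
    return EmulatedTissueModel(
        r_ss=r[0], r_s=r[1], r_d=r[2], network_s=net_s, network_d=net_d
    )


def _scaled(circuit: Perturbable, r_scale: float, c_scale: float) -> Perturbable:
    r, c = component_values(circuit)
    return circuit_from_values(circuit, r * r_scale, c * c_scale)


# --- analyses ---------------------------------------------------------------


def temperature_envelope(
    circuit: Perturbable,
    config: ToleranceConfig = ToleranceConfig(),
    grid: FrequencyGrid = None,
) -> TemperatureEnvelope:
    """Worst-case 4-corner temperature drift envelope versus nominal.

    Corners are the two temperature extremes combined with both uniform
    tempco signs; every resistor scales by 1 + s*tc_R*dT*1e-6 and every
    capacitor by 1 + s*tc_C*dT*1e-6.
    """
    if grid is None:
        from .datasets import DEFAULT_GRID

        grid = DEFAULT_GRID
    nominal = circuit_impedance(circuit, grid)
    mag_dev = np.zeros(len(nominal))
    ph_dev = np.zeros(len(nominal))
    for t_c in (config.t_min_c, config.t_max_c):
        dt = t_c - config.t_nominal_c
        for sign in (+1.0, -1.0):
            r_scale = 1.0 + sign * config.tempco_r_ppm * dt * 1e-6
            c_scale = 1.0 + sign * config.tempco_c_ppm * dt * 1e-6
            z = circuit_impedance(_scaled(circuit, r_scale, c_scale), grid)
            mag_dev = np.maximum(
                mag_dev,
                100.0 * np.abs(z.magnitude - nominal.magnitude) / nominal.magnitude,
            )
            ph_dev = np.maximum(ph_dev, np.abs(z.phase_deg - nominal.phase_deg))
    return TemperatureEnvelope(nominal.frequencies, mag_dev, ph_dev)


def monte_carlo(
    circuit: Perturbable,
    config: ToleranceConfig = ToleranceConfig(),
    query_frequency: float = 1.0,
) -> MonteCarloSample:
    """Monte-Carlo component-tolerance sample of |Z| and phase at one point.

    Every R and C is perturbed independently per iteration by a Gaussian
    with sigma = tolerance / sigma_rule; deterministic under the seed.
    """
    if query_frequency <= 0:
        raise ValueError("query_frequency must be positive")
    rng = np.random.default_rng(config.seed)
    sigma = config.component_tolerance_pct / 100.0 / config.sigma_rule
    r0, c0 = component_values(circuit)
    omega = np.array([2.0 * np.pi * query_frequency])
    mags = np.empty(config.n_iterations)
    phases = np.empty(config.n_iterations)
    for i in range(config.n_iterations):
        r = r0 * (1.0 + sigma * rng.standard_normal(r0.size))
        c = c0 * (1.0 + sigma * rng.standard_normal(c0.size))
        perturbed = circuit_from_values(circuit, r, c)
        if isinstance(perturbed, ValsaNetwork):
            z = _valsa_values(perturbed, omega)[0]
        else:
            z = _emulated_values(perturbed, omega)[0]
        mags[i] = abs(z)
        phases[i] = np.angle(z, deg=True)
    return MonteCarloSample(query_frequency, mags, phases)


def thermal_noise_density(
    circuit: Union[Perturbable, ImpedanceSpectrum],
    temperature_k: float = 300.15,
    grid: FrequencyGrid = None,
) -> NoiseSpectrum:
    """Johnson–Nyquist voltage noise density of a passive one-port.

    density(omega) = sqrt(4 k T Re Z(j omega)), reported in nV/sqrt(Hz) for
    a 1 Hz bandwidth.  The default temperature is the nominal 27 deg C.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if isinstance(circuit, ImpedanceSpectrum):
        spectrum = circuit
    else:
        if grid is None:
            from .datasets import DEFAULT_GRID

            grid = DEFAULT_GRID
        spectrum = circuit_impedance(circuit, grid)
    density_v = np.sqrt(4.0 * _BOLTZMANN * temperature_k * spectrum.resistance)
    return NoiseSpectrum(spectrum.frequencies, density_v * 1e9)
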