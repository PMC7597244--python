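"""Closed-form impedance of fractional-order tissue circuits and RC emulators.

The building block is the constant phase element (CPE), a fractional-order
one-port with impedance

    Z_CPE(s) = 1 / (s^alpha * C_alpha),        0 < alpha < 1,

whose phase is frequency independent and equal to -90*alpha degrees.
``C_alpha`` is the pseudo-capacitance in F*s^(alpha-1).  Two five-element
tissue models are provided, both consisting of three resistors (saline
solution ``R_ss``, smear layer ``R_s``, dentin ``R_d``) and two CPEs:

* ``cole_parallel`` — the double-dispersion Cole model,
  ``Z = R_ss + (Z_s || R_s) + (Z_d || R_d)``;
* ``recurrent_ladder`` — a nested (bifurcation, n = 2) ladder,
  ``Z = R_ss + Z_s || (R_s + Z_d || R_d)``.

Both reduce to ``R_ss + R_s + R_d`` at DC and to ``R_ss`` at infinite
frequency.  A CPE can be emulated over a finite band by a Valsa RC network
(shunt R/C in parallel with m series-RC branches); assembling the recurrent
ladder with two such networks gives a circuit buildable from off-the-shelf
parts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple, Union

import numpy as np

__all__ = [
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "CPE",
    "TissueModelParams",
    "ValsaNetwork",
    "EmulatedTissueModel",
    "cpe_impedance",
    "model_impedance",
    "valsa_impedance",
    "emulated_impedance",
    "circuit_impedance",
    "parallel",
]

COLE_PARALLEL = "cole_parallel"
RECURRENT_LADDER = "recurrent_ladder"
_TOPOLOGIES = (COLE_PARALLEL, RECURRENT_LADDER)


@dataclass(frozen=True)
class FrequencyGrid:
    """Logarithmically spaced frequency grid, endpoints inclusive.

    Frequencies are in Hz (cyclic); ``omega`` gives angular frequencies.
    """

    f_min: float
    f_max: float
    n_points: int
    spacing: str = "log"

    def __post_init__(self) -> None:
        if self.f_min <= 0:
            raise ValueError(f"f_min must be positive, got {self.f_min}")
        if self.f_max <= self.f_min:
            raise ValueError("f_max must exceed f_min")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if self.spacing != "log":
            raise ValueError(f"unsupported spacing {self.spacing!r}")

    @property
    def frequencies(self) -> np.ndarray:
        return np.logspace(
            math.log10(self.f_min), math.log10(self.f_max), self.n_points
        )

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies


@dataclass
class ImpedanceSpectrum:
    """Complex impedance sampled on an ascending frequency grid.

    ``values`` holds Z in ohms; resistance is Re(Z), reactance Im(Z).
    """

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.frequencies.ndim != 1 or self.values.ndim != 1:
            raise ValueError("frequencies and values must be 1-D")
        if self.frequencies.size != self.values.size:
            raise ValueError("frequencies and values must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        mag = np.abs(self.values)
        if not np.all(np.isfinite(mag)) or np.any(mag <= 0):
            raise ValueError("impedance magnitudes must be finite and positive")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies

    @property
    def resistance(self) -> np.ndarray:
        return self.values.real

    @property
    def reactance(self) -> np.ndarray:
        return self.values.imag

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.angle(self.values, deg=True)

    @classmethod
    def from_polar(
        cls, frequencies: np.ndarray, magnitude: np.ndarray, phase_deg: np.ndarray
    ) -> "ImpedanceSpectrum":
        values = np.asarray(magnitude) * np.exp(1j * np.deg2rad(phase_deg))
        return cls(np.asarray(frequencies, dtype=float), values)


@dataclass(frozen=True)
class CPE:
    """Constant phase element: fractional order and pseudo-capacitance."""

    order: float
    pseudo_capacitance: float

    def __post_init__(self) -> None:
        if not 0.0 < self.order < 1.0:
            raise ValueError(f"CPE order must lie in (0, 1), got {self.order}")
        if self.pseudo_capacitance <= 0:
            raise ValueError("pseudo-capacitance must be positive")


@dataclass(frozen=True)
class TissueModelParams:
    """Five-element tissue circuit: three resistors, two CPEs, a topology tag."""

    r_ss: float
    r_s: float
    r_d: float
    cpe_s: CPE
    cpe_d: CPE
    topology: str = COLE_PARALLEL

    def __post_init__(self) -> None:
        for name in ("r_ss", "r_s", "r_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.topology not in _TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; expected one of {_TOPOLOGIES}"
            )


@dataclass(frozen=True)
class ValsaNetwork:
    """Shunt R_p/C_p in parallel with series-RC branches, emulating a CPE."""

    r_p: float
    c_p: float
    branches: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "branches", tuple((float(r), float(c)) for r, c in self.branches)
        )
        if self.r_p <= 0 or self.c_p <= 0:
            raise ValueError("shunt R_p and C_p must be positive")
        if len(self.branches) < 1:
            raise ValueError("network needs at least one series-RC branch")
        for k, (r, c) in enumerate(self.branches, start=1):
            if r <= 0 or c <= 0:
                raise ValueError(f"branch {k} has non-positive R or C")

    @property
    def n_branches(self) -> int:
        return len(self.branches)


@dataclass(frozen=True)
class EmulatedTissueModel:
    """Recurrent ladder with the two CPEs replaced by Valsa RC networks."""

    r_ss: float
    r_s: float
    r_d: float
    network_s: ValsaNetwork
    network_d: ValsaNetwork

    def __post_init__(self) -> None:
        for name in ("r_ss", "r_s", "r_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def parallel(a: Union[complex, np.ndarray], b: Union[complex, np.ndarray]):
    """Impedance of two elements in parallel, product over sum."""
    return a * b / (a + b)


def cpe_impedance(cpe: CPE, omega) -> np.ndarray:
    """Impedance of a CPE at angular frequency ``omega`` (rad/s).

    Uses the phasor substitution s^alpha -> omega^alpha *
    (cos(alpha*pi/2) + j sin(alpha*pi/2)), valid on the positive real
    frequency axis.  The phase of the result is -90*alpha degrees at every
    frequency.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    a = cpe.order
    phasor = math.cos(a * math.pi / 2.0) + 1j * math.sin(a * math.pi / 2.0)
    return 1.0 / (omega**a * cpe.pseudo_capacitance * phasor)


def _model_values(params: TissueModelParams, omega: np.ndarray) -> np.ndarray:
    z_s = cpe_impedance(params.cpe_s, omega)
    z_d = cpe_impedance(params.cpe_d, omega)
    if params.topology == COLE_PARALLEL:
        return params.r_ss + parallel(z_s, params.r_s) + parallel(z_d, params.r_d)
    # recurrent ladder: the smear-layer CPE shunts the series connection of
    # R_s with the inner dentin stage
    return params.r_ss + parallel(z_s, params.r_s + parallel(z_d, params.r_d))


def model_impedance(
    params: TissueModelParams, grid: FrequencyGrid
) -> ImpedanceSpectrum:
    """Evaluate a five-element tissue model on a frequency grid."""
    f = grid.frequencies
    return ImpedanceSpectrum(f, _model_values(params, 2.0 * np.pi * f))


def _valsa_values_raw(
    r_p: float, c_p: float, branches: Iterable[Tuple[float, float]], omega: np.ndarray
) -> np.ndarray:
    jw = 1j * omega
    y = 1.0 / r_p + jw * c_p
    for r_k, c_k in branches:
        y = y + jw * c_k / (1.0 + jw * r_k * c_k)
    return 1.0 / y


def _valsa_values(network: ValsaNetwork, omega: np.ndarray) -> np.ndarray:
    return _valsa_values_raw(network.r_p, network.c_p, network.branches, omega)


def valsa_impedance(network: ValsaNetwork, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Evaluate a Valsa RC network on a frequency grid.

    Computed as the admittance sum Y = 1/R_p + jwC_p + sum_k jwC_k /
    (1 + jw R_k C_k), then Z = 1/Y.
    """
    f = grid.frequencies
    return ImpedanceSpectrum(f, _valsa_values(network, 2.0 * np.pi * f))


def _emulated_values(model: EmulatedTissueModel, omega: np.ndarray) -> np.ndarray:
    z_s = _valsa_values(model.network_s, omega)
    z_d = _valsa_values(model.network_d, omega)
    return model.r_ss + parallel(z_s, model.r_s + parallel(z_d, model.r_d))


def emulated_impedance(
    model: EmulatedTissueModel, grid: FrequencyGrid
) -> ImpedanceSpectrum:
    """Evaluate the EIA-component recurrent ladder (Valsa networks as CPEs)."""
    f = grid.frequencies
    return ImpedanceSpectrum(f, _emulated_values(model, 2.0 * np.pi * f))


Circuit = Union[TissueModelParams, ValsaNetwork, EmulatedTissueModel]


def circuit_impedance(circuit: Circuit, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Evaluate any supported circuit object on a grid (single dispatch)."""
    if isinstance(circuit, TissueModelParams):
        return model_impedance(circuit, grid)
    if isinstance(circuit, ValsaNetwork):
        return valsa_impedance(circuit, grid)
    if isinstance(circuit, EmulatedTissueModel):
        return emulated_impedance(circuit, grid)
    raise TypeError(f"unsupported circuit type {type(circuit).__name__}")
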