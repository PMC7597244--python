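"""Reference dentin spectra and synthetic measurement noise.

The study data are fully determined by printed constants: mean double-
dispersion Cole parameters for two age groups of human teeth dentin
("young", ~20 y; "old", ~50 y) measured in physiological saline, together
with a stated reconstruction grid of 1400 log-spaced points from 10 mHz to
10 MHz.  ``reconstruct_reference`` regenerates those spectra exactly.
Recurrent-ladder re-fits of the same spectra and their EIA-snapped variants
are packaged alongside for circuit assembly and regression tests.

Real EIS measurements carry instrument noise that the noiseless
reconstruction lacks; ``add_measurement_noise`` emulates it in polar form
(multiplicative magnitude noise, additive phase noise), the way analyzer
accuracy is specified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np

from .circuits import (
    COLE_PARALLEL,
    CPE,
    FrequencyGrid,
    ImpedanceSpectrum,
    RECURRENT_LADDER,
    TissueModelParams,
    model_impedance,
)

__all__ = [
    "DEFAULT_GRID",
    "GROUPS",
    "ReferenceGroup",
    "NoiseModel",
    "reference_group",
    "cole_mean_params",
    "recurrent_fit_params",
    "eia_resistors",
    "eia_cpe_targets",
    "reconstruct_reference",
    "add_measurement_noise",
]

logger = logging.getLogger(__name__)

#: Reconstruction grid: 10 mHz to 10 MHz, 1400 logarithmic points.
DEFAULT_GRID = FrequencyGrid(10e-3, 10e6, 1400)

GROUPS = ("young", "old")

# Mean Cole parameters per age group: R_ss, CPE_T-s, R_s, CPE_T-d, R_d,
# both CPE orders 0.5.
_COLE_MEAN: Dict[str, TissueModelParams] = {
    "young": TissueModelParams(
        r_ss=71.5,
        r_s=244.0,
        r_d=43.1e3,
        cpe_s=CPE(0.5, 23.8e-6),
        cpe_d=CPE(0.5, 45.6e-6),
        topology=COLE_PARALLEL,
    ),
    "old": TissueModelParams(
        r_ss=72.1,
        r_s=128.1,
        r_d=60.9e3,
        cpe_s=CPE(0.5, 14.6e-6),
        cpe_d=CPE(0.5, 182.8e-6),
        topology=COLE_PARALLEL,
    ),
}

# Recurrent-ladder parameters obtained by CNLS re-fit of the Cole spectra.
_RECURRENT_FIT: Dict[str, TissueModelParams] = {
    "young": TissueModelParams(
        r_ss=71.5,
        r_s=564.3,
        r_d=42.78e3,
        cpe_s=CPE(0.5, 15.64e-6),
        cpe_d=CPE(0.5, 30.23e-6),
        topology=RECURRENT_LADDER,
    ),
    "old": TissueModelParams(
        r_ss=72.1,
        r_s=149.38,
        r_d=60.88e3,
        cpe_s=CPE(0.5, 13.52e-6),
        cpe_d=CPE(0.5, 169.34e-6),
        topology=RECURRENT_LADDER,
    ),
}

# EIA-standard-compliant recurrent-model resistors (R_ss, R_s, R_d) and the
# pseudo-capacitance targets of the corresponding Valsa CPE emulators.
_EIA_RESISTORS: Dict[str, tuple] = {
    "young": (71.5, 562.0, 43.0e3),
    "old": (72.3, 150.0, 60.4e3),
}
_EIA_CPE_TARGETS: Dict[str, Dict[str, float]] = {
    "young": {"cpe_s": 15.6e-6, "cpe_d": 30.1e-6},
    "old": {"cpe_s": 13.5e-6, "cpe_d": 169.0e-6},
}


@dataclass(frozen=True)
class ReferenceGroup:
    """One age group with its packaged mean Cole parameters."""

    name: str
    cole_params: TissueModelParams


def _group_name(group: Union[str, ReferenceGroup]) -> str:
    name = group.name if isinstance(group, ReferenceGroup) else group
    if name not in GROUPS:
        raise KeyError(f"unknown group {name!r}; expected one of {GROUPS}")
    return name


def reference_group(name: str) -> ReferenceGroup:
    return ReferenceGroup(_group_name(name), _COLE_MEAN[_group_name(name)])


def cole_mean_params(group: Union[str, ReferenceGroup]) -> TissueModelParams:
    return _COLE_MEAN[_group_name(group)]


def recurrent_fit_params(group: Union[str, ReferenceGroup]) -> TissueModelParams:
    return _RECURRENT_FIT[_group_name(group)]


def eia_resistors(group: Union[str, ReferenceGroup]) -> tuple:
    """(R_ss, R_s, R_d) of the EIA-compliant recurrent circuit, ohms."""
    return _EIA_RESISTORS[_group_name(group)]


def eia_cpe_targets(group: Union[str, ReferenceGroup]) -> Dict[str, float]:
    """Pseudo-capacitance targets (F*s^-0.5) of the group's CPE emulators."""
    return dict(_EIA_CPE_TARGETS[_group_name(group)])


def reconstruct_reference(
    group: Union[str, ReferenceGroup], grid: Optional[FrequencyGrid] = None
) -> ImpedanceSpectrum:
    """Reconstruct a group's dentin impedance spectrum from the Cole model."""
    if grid is None:
        grid = DEFAULT_GRID
    return model_impedance(cole_mean_params(group), grid)


@dataclass(frozen=True)
class NoiseModel:
    """Polar measurement noise: fractional magnitude CV, phase SD in degrees."""

    magnitude_cv: float = 0.0
    phase_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude_cv < 0 or self.phase_sd < 0:
            raise ValueError("noise levels must be non-negative")


def add_measurement_noise(
    spectrum: ImpedanceSpectrum, noise: NoiseModel
) -> ImpedanceSpectrum:
    """Perturb |Z| multiplicatively and the phase additively, per point.

    Draws are independent Gaussians; reproducible under ``noise.seed``.
    Magnitude factors that would flip the sign of |Z| are clipped to a small
    positive floor (and counted in the log); with realistic CVs this never
    triggers.
    """
    rng = np.random.default_rng(noise.seed)
    n = len(spectrum)
    mag_factor = 1.0 + noise.magnitude_cv * rng.standard_normal(n)
    n_clipped = int(np.sum(mag_factor <= 0))
    if n_clipped:
        logger.warning("clipped %d non-positive magnitude draws", n_clipped)
        mag_factor = np.clip(mag_factor, 1e-12, None)
    magnitude = spectrum.magnitude * mag_factor
    phase = spectrum.phase_deg + noise.phase_sd * rng.standard_normal(n)
    return ImpedanceSpectrum.from_polar(spectrum.frequencies, magnitude, phase)
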