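"""Goodness-of-fit panel and CPE characterization statistics.

Error statistics follow EIS practice of reporting the real (resistance) and
imaginary (reactance) impedance components separately.  The panel comprises
per-point absolute relative errors (max/mean/median/SD), MAE, RMSE, the
squared Pearson correlation R^2, Nash–Sutcliffe efficiency (NSE), Willmott's
index of agreement (WIA) and Legates' coefficient of efficiency (LCE).  With
reference values o, test values s and o-bar = mean(o):

    NSE = 1 - sum (o-s)^2 / sum (o - o_bar)^2
    WIA = 1 - sum (o-s)^2 / sum (|s - o_bar| + |o - o_bar|)^2
    LCE = 1 - sum |o-s| / sum |o - o_bar|

NSE and LCE are 1 at perfect agreement and unbounded below; WIA lies in
[0, 1].  R^2 is the squared Pearson correlation of o and s (not 1 -
SSres/SStot, which would duplicate NSE).

``characterize_cpe`` grades an RC emulator of a constant phase element: the
per-frequency effective order is read off the phase (alpha_i = -theta_i/90),
the effective pseudo-capacitance from the magnitude, and both are summarised
with their coefficient of variation CoV = 100*SD/mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .circuits import CPE, ImpedanceSpectrum, cpe_impedance

__all__ = [
    "ErrorStats",
    "ComponentMetrics",
    "FitMetrics",
    "CPECharacterization",
    "relative_error_stats",
    "phase_error_stats",
    "fit_metrics",
    "characterize_cpe",
]

logger = logging.getLogger(__name__)

_COMPONENTS = ("re", "neg_imag", "magnitude")


@dataclass(frozen=True)
class ErrorStats:
    """Max / mean / median / sample SD of per-point absolute errors."""

    max: float
    mean: float
    median: float
    sd: float


@dataclass(frozen=True)
class ComponentMetrics:
    mae: float
    rmse: float
    r2: float
    nse: float
    wia: float
    lce: float


@dataclass(frozen=True)
class FitMetrics:
    """The six-statistic panel, computed separately for Re(Z) and Im(Z)."""

    real: ComponentMetrics
    imag: ComponentMetrics


@dataclass(frozen=True)
class CPECharacterization:
    order_mean: float
    order_sd: float
    order_cov: float
    pseudo_cap_mean: float
    pseudo_cap_sd: float
    pseudo_cap_cov: float
    magnitude_error: ErrorStats
    phase_error: ErrorStats


def _check_grids(reference: ImpedanceSpectrum, test: ImpedanceSpectrum) -> None:
    if len(reference) != len(test) or not np.allclose(
        reference.frequencies, test.frequencies, rtol=1e-9, atol=0.0
    ):
        raise ValueError("reference and test spectra must share a frequency grid")


def _stats(errors: np.ndarray) -> ErrorStats:
    return ErrorStats(
        max=float(np.max(errors)),
        mean=float(np.mean(errors)),
        median=float(np.median(errors)),
        sd=float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0,
    )


def _component(spectrum: ImpedanceSpectrum, component: str) -> np.ndarray:
    if component == "re":
        return spectrum.resistance
    if component == "neg_imag":
        return -spectrum.reactance
    if component == "magnitude":
        return spectrum.magnitude
    raise ValueError(f"unknown component {component!r}; expected one of {_COMPONENTS}")


def relative_error_stats(
    reference: ImpedanceSpectrum, test: ImpedanceSpectrum, component: str = "re"
) -> ErrorStats:
    """Per-point absolute relative error (%) of one impedance component.

    e_i = 100 * |x_test,i - x_ref,i| / |x_ref,i|.  Points where the
    reference component vanishes are excluded (count logged).
    """
    _check_grids(reference, test)
    ref = _component(reference, component)
    tst = _component(test, component)
    keep = ref != 0.0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.warning(
            "excluded %d points with zero reference %s component", n_dropped, component
        )
    if not np.any(keep):
        raise ValueError("all reference points are zero; relative error undefined")
    errors = 100.0 * np.abs(tst[keep] - ref[keep]) / np.abs(ref[keep])
    return _stats(errors)


def phase_error_stats(
    reference: ImpedanceSpectrum, test: ImpedanceSpectrum
) -> ErrorStats:
    """Per-point absolute phase error in degrees."""
    _check_grids(reference, test)
    return _stats(np.abs(test.phase_deg - reference.phase_deg))


def _component_metrics(o: np.ndarray, s: np.ndarray) -> ComponentMetrics:
    n = o.size
    resid = o - s
    mae = float(np.sum(np.abs(resid)) / n)
    rmse = float(np.sqrt(np.sum(resid**2) / n))
    o_bar = float(np.mean(o))
    ss_tot = float(np.sum((o - o_bar) ** 2))
    abs_tot = float(np.sum(np.abs(o - o_bar)))
    if ss_tot == 0.0:
        raise ValueError(
            "reference component has zero variance; NSE/WIA/LCE/R2 undefined"
        )
    nse = 1.0 - float(np.sum(resid**2)) / ss_tot
    wia = 1.0 - float(np.sum(resid**2)) / float(
        np.sum((np.abs(s - o_bar) + np.abs(o - o_bar)) ** 2)
    )
    lce = 1.0 - float(np.sum(np.abs(resid))) / abs_tot
    r = np.corrcoef(o, s)[0, 1]
    return ComponentMetrics(mae=mae, rmse=rmse, r2=float(r**2), nse=nse, wia=wia, lce=lce)


def fit_metrics(reference: ImpedanceSpectrum, test: ImpedanceSpectrum) -> FitMetrics:
    """Compute the panel for Re(Z) and Im(Z) on a shared grid."""
    _check_grids(reference, test)
    return FitMetrics(
        real=_component_metrics(reference.resistance, test.resistance),
        imag=_component_metrics(reference.reactance, test.reactance),
    )


def characterize_cpe(spectrum: ImpedanceSpectrum, target: CPE) -> CPECharacterization:
    """Grade how well a spectrum behaves as the target constant phase element.

    The effective order at each frequency is alpha_i = -theta_i/90 (theta in
    degrees); the effective pseudo-capacitance uses the mean order,
    C_i = 1 / (|Z_i| * omega_i^alpha_bar).  Magnitude errors are relative to
    the ideal CPE with the target's parameters; phase errors are against the
    constant -90*alpha_target degrees.
    """
    alpha_i = -spectrum.phase_deg / 90.0
    order_mean = float(np.mean(alpha_i))
    order_sd = float(np.std(alpha_i, ddof=1)) if len(spectrum) > 1 else 0.0
    cap_i = 1.0 / (spectrum.magnitude * spectrum.omega**order_mean)
    cap_mean = float(np.mean(cap_i))
    cap_sd = float(np.std(cap_i, ddof=1)) if len(spectrum) > 1 else 0.0

    ideal = ImpedanceSpectrum(
        spectrum.frequencies, cpe_impedance(target, spectrum.omega)
    )
    return CPECharacterization(
        order_mean=order_mean,
        order_sd=order_sd,
        order_cov=abs(100.0 * order_sd / order_mean),
        pseudo_cap_mean=cap_mean,
        pseudo_cap_sd=cap_sd,
        pseudo_cap_cov=abs(100.0 * cap_sd / cap_mean),
        magnitude_error=relative_error_stats(ideal, spectrum, "magnitude"),
        phase_error=phase_error_stats(ideal, spectrum),
    )
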