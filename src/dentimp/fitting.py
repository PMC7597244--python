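"""Complex nonlinear least-squares (CNLS) fitting of tissue models.

The objective is the weighted sum of squared real and imaginary residuals

    S = sum_i w_i [ (Re Z_i - Re Zhat_i)^2 + (Im Z_i - Im Zhat_i)^2 ],

minimised over the circuit parameters with Powell's direction-set method.
Modulus weighting (w_i = 1/|Z_i|^2, the default) balances residuals across
the six-decade impedance range of the dentin spectra; unit weighting is
available for comparison.  Resistances and pseudo-capacitances are searched
in log space (positivity by construction); free CPE orders are searched
through a logit map onto (0, 1).  A multi-start scheme jitters the starting
point to guard against local minima; the best restart is returned and the
whole procedure is deterministic under the configured seed.

Starting values come from the asymptotic structure of the models: the
high-frequency plateau of Re(Z) reads off R_ss, and the DC resistance
R_ss + R_s + R_d is recovered by fitting a circle to the low-frequency
Nyquist arc and intersecting it with the real axis — the spectra terminate
at 10 mHz well before the dispersion completes, so a plateau readout alone
underestimates the DC sum badly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .circuits import (
    COLE_PARALLEL,
    CPE,
    ImpedanceSpectrum,
    TissueModelParams,
    _model_values,
)

__all__ = ["FitConfig", "FitResult", "asymptotic_initializer", "cnls_fit"]

_WEIGHTINGS = ("unit", "modulus")
_ORDER_MODES = ("fixed", "free_equal", "free_independent")


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the CNLS fit; defaults reproduce the packaged study fits."""

    weighting: str = "modulus"
    order_mode: str = "fixed"
    fixed_order: float = 0.5
    initializer: str = "asymptotic"
    initial_params: Optional[TissueModelParams] = None
    max_iterations: int = 20000
    tolerance: float = 1e-14
    restarts: int = 5
    jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weighting not in _WEIGHTINGS:
            raise ValueError(f"weighting must be one of {_WEIGHTINGS}")
        if self.order_mode not in _ORDER_MODES:
            raise ValueError(f"order_mode must be one of {_ORDER_MODES}")
        if self.initializer not in ("asymptotic", "user"):
            raise ValueError("initializer must be 'asymptotic' or 'user'")
        if self.initializer == "user" and self.initial_params is None:
            raise ValueError("user initializer requires initial_params")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be at least 1")


@dataclass(frozen=True)
class FitResult:
    params: TissueModelParams
    objective: float
    converged: bool
    n_evaluations: int


def _dc_intercept(spectrum: ImpedanceSpectrum) -> float:
    """DC resistance estimate: real-axis intercept of the low-frequency arc.

    Algebraic (Kasa) circle fit through the lowest-frequency points of the
    Nyquist plot (Re Z, -Im Z); the right-hand intersection with the real
    axis extrapolates the incomplete dispersion to omega -> 0.
    """
    n = max(10, len(spectrum) // 7)
    x = spectrum.resistance[:n]
    y = -spectrum.reactance[:n]
    a = np.column_stack([x, y, np.ones(n)])
    b = x**2 + y**2
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + cx**2 + cy**2
    disc = r2 - cy**2
    if disc <= 0:
        return float(np.max(x))
    return float(cx + np.sqrt(disc))


def asymptotic_initializer(
    spectrum: ImpedanceSpectrum,
    topology: str = COLE_PARALLEL,
    order: float = 0.5,
) -> TissueModelParams:
    """Starting parameters from the model's frequency-limit structure.

    R_ss is the high-frequency resistance; R_s + R_d is the extrapolated DC
    resistance minus R_ss, split 1:9; pseudo-capacitances are seeded from
    the mid-band impedance level.  Degenerate (flat resistive or too-short)
    spectra fall back to a small epsilon for the series resistances.
    """
    f = spectrum.frequencies
    if f[-1] / f[0] < 1e3 or len(spectrum) < 10:
        r_ss = float(np.median(spectrum.resistance))
        r_rest = max(r_ss * 1e-6, 1e-9)
    else:
        # Re(Z) ~ R_ss + b * omega^(-order) at the top of the band; the
        # intercept of a linear fit in omega^(-order) strips the residual
        # CPE contribution from the plateau readout
        n_hi = max(10, len(spectrum) // 10)
        w_hi = spectrum.omega[-n_hi:]
        a = np.column_stack([np.ones(n_hi), w_hi ** (-order)])
        coef, *_ = np.linalg.lstsq(a, spectrum.resistance[-n_hi:], rcond=None)
        r_ss = float(coef[0]) if coef[0] > 0 else float(spectrum.resistance[-1])
        r_dc = _dc_intercept(spectrum)
        r_rest = r_dc - r_ss
    eps = max(abs(r_ss), 1.0) * 1e-6
    r_rest = max(r_rest, 2 * eps)
    r_s = max(0.1 * r_rest, eps)
    r_d = max(0.9 * r_rest, eps)

    mid = len(spectrum) // 2
    w_mid = spectrum.omega[mid]
    c_mid = 1.0 / (spectrum.magnitude[mid] * w_mid**order)
    cpe = CPE(order, float(c_mid))
    return TissueModelParams(
        r_ss=max(r_ss, eps),
        r_s=r_s,
        r_d=r_d,
        cpe_s=cpe,
        cpe_d=cpe,
        topology=topology,
    )


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _pack(params: TissueModelParams, config: FitConfig) -> np.ndarray:
    x = list(
        np.log([params.r_ss, params.r_s, params.r_d,
                params.cpe_s.pseudo_capacitance, params.cpe_d.pseudo_capacitance])
    )
    if config.order_mode == "free_equal":
        x.append(_logit(params.cpe_s.order))
    elif config.order_mode == "free_independent":
        x.append(_logit(params.cpe_s.order))
        x.append(_logit(params.cpe_d.order))
    return np.asarray(x)


def _unpack(x: np.ndarray, config: FitConfig, topology: str) -> TissueModelParams:
    r_ss, r_s, r_d, c_s, c_d = np.exp(x[:5])
    if config.order_mode == "fixed":
        a_s = a_d = config.fixed_order
    elif config.order_mode == "free_equal":
        a_s = a_d = float(_expit(x[5:6])[0])
    else:
        a_s, a_d = (float(v) for v in _expit(x[5:7]))
    return TissueModelParams(
        r_ss=float(r_ss),
        r_s=float(r_s),
        r_d=float(r_d),
        cpe_s=CPE(a_s, float(c_s)),
        cpe_d=CPE(a_d, float(c_d)),
        topology=topology,
    )


def cnls_fit(
    spectrum: ImpedanceSpectrum,
    topology: str = COLE_PARALLEL,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit a five-element tissue model to an impedance spectrum by CNLS."""
    if config is None:
        config = FitConfig()
    n_free = {"fixed": 5, "free_equal": 6, "free_independent": 7}[config.order_mode]
    if len(spectrum) < n_free:
        raise ValueError(
            f"spectrum has {len(spectrum)} points but the model has {n_free} "
            "free parameters"
        )

    omega = spectrum.omega
    z_ref = spectrum.values
    if config.weighting == "modulus":
        weights = 1.0 / np.abs(z_ref) ** 2
    else:
        weights = np.ones_like(omega)

    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        try:
            params = _unpack(x, config, topology)
        except (ValueError, OverflowError):
            return np.inf
        z = _model_values(params, omega)
        resid = z - z_ref
        return float(np.sum(weights * (resid.real**2 + resid.imag**2)))

    if config.initializer == "user":
        start = config.initial_params
        if start.topology != topology:
            start = replace(start, topology=topology)
    else:
        start = asymptotic_initializer(
            spectrum, topology=topology, order=config.fixed_order
        )
    x0 = _pack(start, config)

    rng = np.random.default_rng(config.seed)
    best_x, best_f, any_converged = None, np.inf, False
    for k in range(config.restarts):
        xk = x0 if k == 0 else x0 + config.jitter * rng.standard_normal(x0.size)
        res = minimize(
            objective,
            xk,
            method="Powell",
            options=dict(
                maxiter=config.max_iterations,
                xtol=1e-12,
                ftol=config.tolerance,
            ),
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
            any_converged = bool(res.success)
    return FitResult(
        params=_unpack(best_x, config, topology),
        objective=best_f,
        converged=any_converged,
        n_evaluations=n_evals,
    )
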