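"""Conductance-domain non-linear least-squares estimation of Cole parameters.

The fit minimises the residual between the measured conductance — the real
part of the admittance 1/Z — and the conductance form of the Cole model.
Because a parallel stray capacitance only adds imaginary admittance, fitting
in the conductance domain recovers the tissue's Cole parameters unchanged
under capacitive leakage.

Internally the problem is parameterised as (r_inf, r0 - r_inf, alpha, log fc)
so that the ordering r0 > r_inf > 0 and the positivity of fc are enforced by
simple box bounds; results are reported in the natural parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .cole import ColeParameters, ImpedanceSpectrum, cole_conductance, impedance_to_admittance
from .errors import InsufficientDataError, ValidationError

__all__ = ["FitOptions", "FitResult", "initial_guess", "fit_cole_conductance"]

#: Minimum number of frequency points and span (decades) for a meaningful fit.
MIN_POINTS = 8
MIN_SPAN_DECADES = 1.0


@dataclass(frozen=True)
class FitOptions:
    """Tolerances and bounds for the trust-region least-squares solver.

    ``fc`` is bounded to [f_min / fc_margin, f_max * fc_margin] relative to
    the measured grid; ``alpha`` to [alpha_min, 1].  The default tolerances
    sit at machine precision: on noiseless model-generated data the solver
    must recover parameters to ~1e-7 even when alpha lies on its upper
    bound, where looser gradient tolerances stop early.
    """

    ftol: float = 2.5e-16
    xtol: float = 2.5e-16
    gtol: float = 2.5e-16
    max_iterations: int = 500
    alpha_min: float = 1e-3
    fc_margin: float = 10.0

    def __post_init__(self) -> None:
        if self.ftol <= 0 or self.xtol <= 0 or self.gtol <= 0:
            raise ValidationError("tolerances must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if not (0 < self.alpha_min < 1):
            raise ValidationError("alpha_min must be in (0, 1)")
        if self.fc_margin < 1:
            raise ValidationError("fc_margin must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one conductance-domain Cole fit."""

    params: ColeParameters
    residual_rms: float  # siemens
    n_iterations: int
    converged: bool
    initial: ColeParameters
    meta: Optional[object] = None  # MeasurementMeta of the fitted spectrum


def _check_spectrum(spectrum: ImpedanceSpectrum) -> None:
    grid = spectrum.grid
    if len(grid) < MIN_POINTS:
        raise InsufficientDataError(
            f"need at least {MIN_POINTS} frequency points, got {len(grid)}"
        )
    span = math.log10(grid.f_max / grid.f_min)
    if span < MIN_SPAN_DECADES:
        raise InsufficientDataError(
            f"frequency span must cover >= {MIN_SPAN_DECADES} decade(s), got {span:.2f}"
        )


def initial_guess(spectrum: ImpedanceSpectrum) -> ColeParameters:
    """Heuristic starting point for the Cole fit.

    r0 is taken from the lowest-frequency resistance (inflated 5%), r_inf
    from the highest-frequency resistance (deflated 5%), alpha starts at 0.7,
    and fc at the frequency of peak reactance magnitude.  If the reactance
    peak sits on a grid boundary (the true peak lies outside the sweep) fc
    falls back to the geometric mean of the grid endpoints.  The returned
    parameters always satisfy the type invariants.
    """
    _check_spectrum(spectrum)
    grid = spectrum.grid
    r = spectrum.resistance
    r0 = float(r[0]) * 1.05
    r_inf = float(r[-1]) * 0.95
    if r_inf <= 0.0:
        r_inf = max(abs(r_inf), 1e-6)
    if r0 <= r_inf:
        # non-decreasing resistance trace: fall back to a nominal 10% spread
        r0 = r_inf * 1.1
    peak = int(np.argmax(np.abs(spectrum.reactance)))
    if peak == 0 or peak == len(grid) - 1:
        fc = math.sqrt(grid.f_min * grid.f_max)
    else:
        fc = float(grid.frequencies_hz[peak])
    return ColeParameters(r0=r0, r_inf=r_inf, alpha=0.7, fc=fc)


def fit_cole_conductance(
    spectrum: ImpedanceSpectrum,
    options: FitOptions = FitOptions(),
    start: Optional[ColeParameters] = None,
) -> FitResult:
    """Fit the conductance Cole model to a measured spectrum.

    The measured conductance is Re(1/Z); the residual is unweighted.  The
    solver is scipy's bounded trust-region-reflective least squares with a
    finite-difference Jacobian; given the same spectrum and options the
    result is deterministic (no random restarts).  Non-convergence within
    the iteration budget is flagged on the result, not raised.
    """
    _check_spectrum(spectrum)
    grid = spectrum.grid
    g_meas = impedance_to_admittance(spectrum).conductance
    guess = start if start is not None else initial_guess(spectrum)

    log_fc_lo = math.log(grid.f_min / options.fc_margin)
    log_fc_hi = math.log(grid.f_max * options.fc_margin)

    x0 = np.array(
        [
            guess.r_inf,
            guess.delta_r,
            min(max(guess.alpha, options.alpha_min), 1.0),
            min(max(math.log(guess.fc), log_fc_lo), log_fc_hi),
        ]
    )
    lower = np.array([1e-9, 1e-9, options.alpha_min, log_fc_lo])
    upper = np.array([np.inf, np.inf, 1.0, log_fc_hi])
    x0 = np.clip(x0, lower, upper)

    def residual(x: np.ndarray) -> np.ndarray:
        p = ColeParameters(r0=x[0] + x[1], r_inf=x[0], alpha=x[2], fc=math.exp(x[3]))
        return cole_conductance(p, grid) - g_meas

    sol = least_squares(
        residual,
        x0,
        bounds=(lower, upper),
        method="trf",
        ftol=options.ftol,
        xtol=options.xtol,
        gtol=options.gtol,
        max_nfev=options.max_iterations * x0.size,
        x_scale=np.maximum(np.abs(x0), 1e-3),
    )
    params = ColeParameters(
        r0=float(sol.x[0] + sol.x[1]),
        r_inf=float(sol.x[0]),
        alpha=float(sol.x[2]),
        fc=float(math.exp(sol.x[3])),
    )
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return FitResult(
        params=params,
        residual_rms=rms,
        n_iterations=int(sol.nfev),
        converged=bool(sol.status > 0),
        initial=guess,
        meta=spectrum.meta,
    )
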