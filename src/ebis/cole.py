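"""Cole dispersion model for electrical bioimpedance spectroscopy (EBIS).

Biological tissue measured over a frequency sweep shows a single dominant
dispersion that is well described by the four-parameter Cole model

    Z(f) = R_inf + (R0 - R_inf) / (1 + (j f / fc)^alpha)

where ``R0`` and ``R_inf`` are the resistance limits at zero and infinite
frequency, ``alpha`` in (0, 1] controls the depression of the impedance-locus
semicircle, and ``fc`` is the characteristic frequency at which the reactance
magnitude peaks.

This module provides the forward model in both the impedance domain and the
conductance (real admittance) domain, impedance/admittance conversion, and a
parallel stray-capacitance model.  The conductance domain matters because a
capacitance in parallel with the measurement load adds a purely imaginary
admittance: the conductance spectrum, and hence any Cole fit performed on it,
is immune to capacitive leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "ColeParameters",
    "FrequencyGrid",
    "MeasurementMeta",
    "ImpedanceSpectrum",
    "AdmittanceSpectrum",
    "cole_impedance",
    "cole_conductance",
    "impedance_to_admittance",
    "admittance_to_impedance",
    "add_parallel_capacitance",
]

#: Default measurement band: 256 log-spaced points over 3.096 kHz .. 1 MHz.
DEFAULT_F_MIN_HZ = 3.096e3
DEFAULT_F_MAX_HZ = 1.000e6
DEFAULT_N_POINTS = 256

HEMISPHERES = ("left", "right")
ELECTRODE_SETS = ("central", "lateral")
TISSUE_LABELS = ("healthy", "damaged")


@dataclass(frozen=True)
class ColeParameters:
    """The four Cole quantities describing one dispersion.

    Attributes
    ----------
    r0 : float
        DC (zero-frequency) resistance, ohm.  Must exceed ``r_inf``.
    r_inf : float
        Resistance at infinite frequency, ohm.  Must be positive.
    alpha : float
        Dispersion-broadness exponent, dimensionless, in (0, 1].
    fc : float
        Characteristic frequency, Hz.  Must be positive.
    """

    r0: float
    r_inf: float
    alpha: float
    fc: float

    def __post_init__(self) -> None:
        if not (self.r_inf > 0.0):
            raise ValidationError(f"r_inf must be > 0, got {self.r_inf}")
        if not (self.r0 > self.r_inf):
            raise ValidationError(
                f"r0 must exceed r_inf, got r0={self.r0}, r_inf={self.r_inf}"
            )
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (self.fc > 0.0):
            raise ValidationError(f"fc must be > 0, got {self.fc}")

    @property
    def y0(self) -> float:
        """Conductance limit at zero frequency, siemens (1 / r0)."""
        return 1.0 / self.r0

    @property
    def y_inf(self) -> float:
        """Conductance limit at infinite frequency, siemens (1 / r_inf)."""
        return 1.0 / self.r_inf

    @property
    def delta_r(self) -> float:
        """Dispersion magnitude r0 - r_inf, ohm."""
        return self.r0 - self.r_inf


def _as_freq_array(frequencies_hz) -> np.ndarray:
    f = np.asarray(frequencies_hz, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValidationError("frequency grid must be a non-empty 1-D array")
    if not np.all(f > 0.0):
        raise ValidationError("all frequencies must be > 0")
    if f.size > 1 and not np.all(np.diff(f) > 0.0):
        raise ValidationError("frequencies must be strictly increasing")
    f.setflags(write=False)
    return f


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of measurement frequencies in Hz."""

    frequencies_hz: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies_hz", _as_freq_array(self.frequencies_hz))

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """The standard sweep: 256 log-spaced points, 3.096 kHz to 1 MHz."""
        return cls(
            np.logspace(
                np.log10(DEFAULT_F_MIN_HZ), np.log10(DEFAULT_F_MAX_HZ), DEFAULT_N_POINTS
            )
        )

    def __len__(self) -> int:
        return int(self.frequencies_hz.size)

    @property
    def f_min(self) -> float:
        return float(self.frequencies_hz[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies_hz[-1])

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return np.array_equal(self.frequencies_hz, other.frequencies_hz)

    def __hash__(self) -> int:
        return hash(self.frequencies_hz.tobytes())


@dataclass(frozen=True)
class MeasurementMeta:
    """Identity of one recorded sweep: who, which side, which montage, which repeat."""

    subject_id: str
    hemisphere: str  # "left" | "right"
    electrode_set: str  # "central" | "lateral"
    repeat: int
    label: Optional[str] = None  # "healthy" | "damaged" | None (unknown)

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"hemisphere must be one of {HEMISPHERES}")
        if self.electrode_set not in ELECTRODE_SETS:
            raise ValidationError(f"electrode_set must be one of {ELECTRODE_SETS}")
        if self.label is not None and self.label not in TISSUE_LABELS:
            raise ValidationError(f"label must be one of {TISSUE_LABELS} or None")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """One complex impedance sweep: Z(f) = resistance + j * reactance.

    Reactance is stored signed (Im Z, negative throughout a Cole dispersion);
    consumers needing the magnitude take ``abs`` explicitly.
    """

    grid: FrequencyGrid
    resistance: np.ndarray
    reactance: np.ndarray
    meta: Optional[MeasurementMeta] = None

    def __post_init__(self) -> None:
        r = np.asarray(self.resistance, dtype=float)
        x = np.asarray(self.reactance, dtype=float)
        if r.shape != (len(self.grid),) or x.shape != (len(self.grid),):
            raise ValidationError(
                "resistance and reactance must match the grid length"
            )
        r.setflags(write=False)
        x.setflags(write=False)
        object.__setattr__(self, "resistance", r)
        object.__setattr__(self, "reactance", x)

    @property
    def complex_impedance(self) -> np.ndarray:
        return self.resistance + 1j * self.reactance


@dataclass(frozen=True)
class AdmittanceSpectrum:
    """One complex admittance sweep: Y(f) = conductance + j * susceptance."""

    grid: FrequencyGrid
    conductance: np.ndarray
    susceptance: np.ndarray
    meta: Optional[MeasurementMeta] = None

    def __post_init__(self) -> None:
        g = np.asarray(self.conductance, dtype=float)
        b = np.asarray(self.susceptance, dtype=float)
        if g.shape != (len(self.grid),) or b.shape != (len(self.grid),):
            raise ValidationError(
                "conductance and susceptance must match the grid length"
            )
        g.setflags(write=False)
        b.setflags(write=False)
        object.__setattr__(self, "conductance", g)
        object.__setattr__(self, "susceptance", b)

    @property
    def complex_admittance(self) -> np.ndarray:
        return self.conductance + 1j * self.susceptance


def cole_impedance(params: ColeParameters, grid: FrequencyGrid) -> np.ndarray:
    """Evaluate the Cole impedance Z(f) on a frequency grid.

    Uses the principal branch of the complex power ``(j f / fc)^alpha``.
    The real part lies in (r_inf, r0); the imaginary part is non-positive.
    """
    f = grid.frequencies_hz
    jw = (1j * f / params.fc) ** params.alpha
    return params.r_inf + params.delta_r / (1.0 + jw)


def cole_conductance(params: ColeParameters, grid: FrequencyGrid) -> np.ndarray:
    """Evaluate the conductance-domain Cole model G(f) on a frequency grid.

    G(f) is the real part of the admittance of the Cole impedance, written in
    the algebraic form with Y0 = 1/r0, Yinf = 1/r_inf:

        G(f) = Y0 + (Yinf - Y0) * (1 + rho * u * c) / (1 + rho^2 u^2 + 2 rho u c)

    with rho = Yinf/Y0, u = (f/fc)^(-alpha) and c = cos(alpha * pi / 2).
    G increases monotonically from Y0 (f -> 0) to Yinf (f -> infinity) and is
    identical to Re(1/Z) of `cole_impedance` (tested property).
    """
    f = grid.frequencies_hz
    y0, y_inf = params.y0, params.y_inf
    rho = y_inf / y0
    u = (f / params.fc) ** (-params.alpha)
    c = np.cos(params.alpha * np.pi / 2.0)
    num = 1.0 + rho * u * c
    den = 1.0 + rho * rho * u * u + 2.0 * rho * u * c
    return y0 + (y_inf - y0) * num / den


def impedance_to_admittance(spectrum: ImpedanceSpectrum) -> AdmittanceSpectrum:
    """Convert Z(f) to Y(f) = 1/Z(f) pointwise."""
    z = spectrum.complex_impedance
    if np.any(np.abs(z) == 0.0):
        idx = int(np.argmin(np.abs(z)))
        raise DegenerateInputError(
            f"zero-magnitude impedance at grid point {idx}; admittance undefined"
        )
    y = 1.0 / z
    return AdmittanceSpectrum(
        grid=spectrum.grid,
        conductance=y.real,
        susceptance=y.imag,
        meta=spectrum.meta,
    )


def admittance_to_impedance(spectrum: AdmittanceSpectrum) -> ImpedanceSpectrum:
    """Convert Y(f) back to Z(f) = 1/Y(f) pointwise (inverse of the above)."""
    y = spectrum.complex_admittance
    if np.any(np.abs(y) == 0.0):
        idx = int(np.argmin(np.abs(y)))
        raise DegenerateInputError(
            f"zero-magnitude admittance at grid point {idx}; impedance undefined"
        )
    z = 1.0 / y
    return ImpedanceSpectrum(
        grid=spectrum.grid,
        resistance=z.real,
        reactance=z.imag,
        meta=spectrum.meta,
    )


def add_parallel_capacitance(
    spectrum: ImpedanceSpectrum, c_p: float
) -> ImpedanceSpectrum:
    """Load a spectrum with a stray capacitance ``c_p`` (farad) in parallel.

    The combined impedance Z' satisfies 1/Z' = 1/Z + j 2 pi f c_p, so the
    susceptance grows by 2 pi f c_p while the conductance is algebraically
    unchanged — the basis of leakage-robust conductance-domain fitting.
    """
    if c_p < 0.0:
        raise ValidationError(f"parallel capacitance must be >= 0, got {c_p}")
    if c_p == 0.0:
        return spectrum
    adm = impedance_to_admittance(spectrum)
    b = adm.susceptance + 2.0 * np.pi * spectrum.grid.frequencies_hz * c_p
    loaded = replace(adm, susceptance=b)
    return admittance_to_impedance(loaded)
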