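"""Closed-form Reichardt elementary-motion-detector (EMD) response.

The correlation-type EMD multiplies the temporally low-pass-filtered signal
of one ommatidium with the instantaneous signal of its neighbor and
subtracts the mirror-symmetric product.  For a drifting sine grating of
spatial wavelength ``lambda`` (deg) moving at angular velocity ``v``
(deg/s), the steady-state output factorizes into four terms:

    R = (1 + x^2)^(-1/2) * sin(arctan x) * sin(2*pi*dphi/lambda)
        * (1 + (drho/lambda)^2)^(-1/2),        x = 2*pi*tau*v/lambda

where ``tau`` is the delay-filter time constant, ``dphi`` the
interommatidial angle and ``drho`` the photoreceptor acceptance angle
(both in degrees, entering only through the dimensionless ratios
``dphi/lambda`` and ``drho/lambda``).  The first factor is the first-order
low-pass gain, the second the temporal-frequency term, the third the
spatial interference term (zero whenever ``lambda = 2*dphi/k``, the
aliasing nulls), and the fourth the optics (spatial blur) term.

The product of the two temporal factors is ``x / (1 + x^2)``, maximal at
``x = 1``; the response therefore peaks at the temporal frequency
``f_opt = 1 / (2*pi*tau)`` regardless of wavelength, and the interference
term peaks at ``lambda_max = 4*dphi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EMDParams",
    "EMDTerms",
    "TemporalTuning",
    "WavelengthSensitivity",
    "emd_terms",
    "emd_response",
    "temporal_tuning_curve",
    "optimal_frequency",
    "tau_from_fopt",
    "lambda_max",
    "wavelength_sensitivity",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class EMDParams:
    """Parameters of the elementary motion detector.

    Attributes
    ----------
    tau : float
        Low-pass (delay) filter time constant in seconds.
    io_angle : float
        Interommatidial angle (angular spacing of neighboring visual
        axes) in degrees.
    acceptance_angle : float
        Acceptance angle (angular field of view of one ommatidium) in
        degrees.
    """

    tau: float
    io_angle: float
    acceptance_angle: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.io_angle > 0:
            raise ValueError(f"io_angle must be > 0, got {self.io_angle}")
        if not self.acceptance_angle > 0:
            raise ValueError(
                f"acceptance_angle must be > 0, got {self.acceptance_angle}"
            )


@dataclass(frozen=True)
class EMDTerms:
    """Term-wise decomposition of the EMD response (same shapes as input)."""

    low_pass: np.ndarray
    temporal: np.ndarray
    interference: np.ndarray
    optics: np.ndarray

    @property
    def product(self) -> np.ndarray:
        return self.low_pass * self.temporal * self.interference * self.optics


def emd_terms(params: EMDParams, wavelength, velocity) -> EMDTerms:
    """Evaluate the four factors of the EMD response separately.

    ``wavelength`` (deg) and ``velocity`` (deg/s) broadcast against each
    other.  ``sin(arctan x)`` is computed as ``x / sqrt(1 + x^2)``, which
    is identical analytically and stable for large ``|x|``.
    """
    wavelength = np.asarray(wavelength, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if np.any(wavelength <= 0):
        raise ValueError("wavelength must be > 0")
    x = _TWO_PI * params.tau * velocity / wavelength
    g = 1.0 / np.sqrt(1.0 + x * x)
    return EMDTerms(
        low_pass=g,
        temporal=x * g,
        interference=np.sin(_TWO_PI * params.io_angle / wavelength),
        optics=1.0 / np.sqrt(1.0 + (params.acceptance_angle / wavelength) ** 2),
    )


def emd_response(params: EMDParams, wavelength, velocity):
    """Steady-state EMD response to a grating (unitless, in [-1, 1]).

    Odd in ``velocity`` (direction selectivity); zero at
    ``wavelength = 2 * io_angle / k`` for integer ``k`` (spatial
    aliasing nulls).
    """
    return emd_terms(params, wavelength, velocity).product


@dataclass(frozen=True)
class TemporalTuning:
    """Normalized temporal-frequency tuning curve at one wavelength."""

    frequencies: np.ndarray  # Hz
    response: np.ndarray  # normalized to own maximum
    f_peak: float  # Hz, grid argmax
    wavelength: float  # deg


def temporal_tuning_curve(
    params: EMDParams, wavelength: float, frequencies
) -> TemporalTuning:
    """EMD response across temporal frequencies, normalized to its maximum.

    The stimulus velocity at each grid point is ``f * wavelength``, so
    the wavelength-dependent interference and optics factors are constant
    along the curve and cancel in the normalization: normalized curves
    for different wavelengths coincide point-for-point (provided the
    constant factor is positive, i.e. ``wavelength > 2 * io_angle``).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size == 0 or np.any(frequencies <= 0):
        raise ValueError("frequency grid must be positive and non-empty")
    r = emd_response(params, wavelength, frequencies * wavelength)
    peak = np.max(np.abs(r))
    if peak == 0:
        raise ValueError("response is identically zero on this grid")
    r = r / np.max(r) if np.max(r) > 0 else r / peak
    return TemporalTuning(
        frequencies=frequencies,
        response=r,
        f_peak=float(frequencies[np.argmax(r)]),
        wavelength=float(wavelength),
    )


def optimal_frequency(tau: float) -> float:
    """Temporal frequency of maximal response, ``1 / (2*pi*tau)`` in Hz.

    Analytic argmax of ``x / (1 + x^2)`` at ``x = 2*pi*tau*f = 1``.
    """
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return 1.0 / (_TWO_PI * tau)


def tau_from_fopt(f_opt: float) -> float:
    """Delay time constant implied by an optimal frequency: ``1/(2*pi*f_opt)`` s."""
    if not f_opt > 0:
        raise ValueError(f"f_opt must be > 0, got {f_opt}")
    return 1.0 / (_TWO_PI * f_opt)


def lambda_max(io_angle: float) -> float:
    """Wavelength of maximal interference term, ``4 * io_angle`` (deg)."""
    if not io_angle > 0:
        raise ValueError(f"io_angle must be > 0, got {io_angle}")
    return 4.0 * io_angle


@dataclass(frozen=True)
class WavelengthSensitivity:
    """EMD response across wavelengths at fixed temporal frequency."""

    wavelengths: np.ndarray  # deg
    response: np.ndarray  # raw (signed; aliasing oscillations preserved)
    lambda_max_analytic: float  # deg, 4 * io_angle
    lambda_max_grid: float  # deg, grid argmax of the interference term
    frequency: float  # Hz


def wavelength_sensitivity(
    params: EMDParams, frequency: float, wavelengths
) -> WavelengthSensitivity:
    """EMD response per wavelength with velocity ``f * lambda`` at each point.

    Sign changes below ``2 * io_angle`` (spatial aliasing) are preserved,
    not clipped.  Both the analytic ``lambda_max = 4 * io_angle`` and the
    grid argmax of the interference factor are reported.
    """
    if not frequency > 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0 or np.any(wavelengths <= 0):
        raise ValueError("wavelength grid must be positive and non-empty")
    terms = emd_terms(params, wavelengths, frequency * wavelengths)
    return WavelengthSensitivity(
        wavelengths=wavelengths,
        response=terms.product,
        lambda_max_analytic=lambda_max(params.io_angle),
        lambda_max_grid=float(wavelengths[np.argmax(terms.interference)]),
        frequency=float(frequency),
    )
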