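"""Spectral densities and 15N relaxation rate expressions.

The orientational correlation function of the N-H vector is modelled as a sum
of decaying exponentials plus a non-decaying plateau,

    C(t) = plateau + sum_k a_k exp(-lambda_k t),

normalised to C(0) = 1.  Internal motion alone (the extended model-free form)
keeps its plateau S2_fast*S2_slow explicit; composing with overall tumbling
shifts every decay rate by 1/tau_P and turns the plateau into a mode with the
tumbling rate, after which the spectral density is the Lorentzian sum

    J(omega) = (2/5) * sum_k a_k * tau_k / (1 + (omega tau_k)^2),
    tau_k = 1 / lambda_k.

Rates follow the standard Redfield expressions for the dipolar + axially
symmetric CSA mechanisms (conventions in :mod:`gnasr.constants`):

    R1     = (D^2/4) [J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + C^2 J(wN)
    R2     = (D^2/8) [4 J(0) + J(wH-wN) + 3 J(wN) + 6 J(wH) + 6 J(wH+wN)]
             + (C^2/6) [4 J(0) + 3 J(wN)] + Rex
    eta_xy = kappa P2(cos beta) [4 J(0) + 3 J(wN)]
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import SpinSystemConstants
from .errors import InvalidMotionError

__all__ = [
    "MotionModel",
    "SpectralDensityModes",
    "internal_correlation_modes",
    "compose_with_tumbling",
    "r1_rate",
    "r2_rate",
    "eta_xy_rate",
    "r2_from_r1rho",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class MotionModel:
    """Per-residue internal dynamics in the extended model-free picture.

    ``S2_fast``/``tau_fast`` describe fast (ps) librations, ``S2_slow``/
    ``tau_slow`` an optional slower (ns to sub-us) process, and ``Rex`` an
    exchange-broadening contribution added to R2 (identical with and without
    gel, hence invisible to gNASR differences).
    """

    S2_fast: float = 1.0
    tau_fast: float = 0.0
    S2_slow: float = 1.0
    tau_slow: float = 0.0
    Rex: float = 0.0

    def __post_init__(self) -> None:
        for name in ("S2_fast", "S2_slow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidMotionError(f"{name}={v} outside [0, 1]")
        if self.Rex < 0.0:
            raise InvalidMotionError(f"Rex={self.Rex} must be >= 0")
        if self.S2_fast < 1.0 and self.tau_fast <= 0.0:
            raise InvalidMotionError("S2_fast < 1 requires tau_fast > 0")
        if self.S2_slow < 1.0 and self.tau_slow <= 0.0:
            raise InvalidMotionError("S2_slow < 1 requires tau_slow > 0")
        if self.S2_slow < 1.0 and self.S2_fast < 1.0 and not self.tau_fast < self.tau_slow:
            raise InvalidMotionError("two-time-scale motion requires tau_fast < tau_slow")

    @property
    def S2_total(self) -> float:
        return self.S2_fast * self.S2_slow


@dataclass(frozen=True)
class SpectralDensityModes:
    """Multi-exponential orientational correlation function.

    ``amplitudes[k]`` decays at ``rates[k]`` (s^-1, all > 0); ``plateau``
    holds the non-decaying part (nonzero only before composition with overall
    tumbling).  Total amplitude is 1 (C(0) = 1).  Mode amplitudes may be
    (slightly) negative for intermediate-exchange tumbling models; physical
    positivity of J is asserted where those models are built.
    """

    amplitudes: np.ndarray
    rates: np.ndarray
    plateau: float = 0.0

    def __post_init__(self) -> None:
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "rates", rates)
        if amps.shape != rates.shape:
            raise ValueError("amplitudes and rates must have equal length")
        if not (np.all(np.isfinite(amps)) and np.all(np.isfinite(rates))):
            raise ValueError("amplitudes and rates must be finite")
        if amps.size and np.any(rates <= 0.0):
            raise ValueError("all mode decay rates must be > 0 (zero rate makes J(0) infinite)")
        total = float(amps.sum()) + self.plateau
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"amplitudes + plateau must sum to 1 (got {total!r})")

    @property
    def n_modes(self) -> int:
        return int(self.amplitudes.size)

    def correlation(self, t):
        """C(t) evaluated from the mode sum (vectorised in t)."""
        t = np.asarray(t, dtype=float)
        decay = self.amplitudes * np.exp(-np.outer(t, self.rates))
        return self.plateau + decay.sum(axis=-1).reshape(t.shape)

    def j(self, omega):
        """J(omega) = (2/5) sum_k a_k tau_k / (1 + (omega tau_k)^2), seconds."""
        if self.plateau != 0.0:
            raise ValueError(
                "spectral density undefined for a non-decaying plateau; "
                "compose with overall tumbling first"
            )
        omega = np.asarray(omega, dtype=float)
        lam = self.rates
        out = 0.4 * np.sum(
            self.amplitudes * lam / (lam**2 + np.expand_dims(omega**2, -1)), axis=-1
        )
        return float(out) if omega.ndim == 0 else out


def internal_correlation_modes(motion: MotionModel) -> SpectralDensityModes:
    """Decompose the extended model-free internal correlation function.

    C_int(t) = S2f*S2s + (1-S2f) e^(-t/tau_f) + S2f (1-S2s) e^(-t/tau_s)
    (additive, cross-term-free form).  The plateau S2_fast*S2_slow is kept as
    ``plateau`` so composition with tumbling can assign it the tumbling rate.
    """
    amps: list[float] = []
    rates: list[float] = []
    if motion.S2_fast < 1.0:
        amps.append(1.0 - motion.S2_fast)
        rates.append(1.0 / motion.tau_fast)
    if motion.S2_slow < 1.0:
        amps.append(motion.S2_fast * (1.0 - motion.S2_slow))
        rates.append(1.0 / motion.tau_slow)
    return SpectralDensityModes(
        amplitudes=np.array(amps), rates=np.array(rates), plateau=motion.S2_total
    )


def compose_with_tumbling(internal: SpectralDensityModes, tau_P: float) -> SpectralDensityModes:
    """Multiply by single-exponential overall tumbling exp(-t/tau_P).

    Every internal rate gains 1/tau_P and the plateau becomes a mode decaying
    at 1/tau_P; for single-time-scale motion this reduces to the Lipari-Szabo
    two-Lorentzian spectral density.
    """
    if not tau_P > 0.0:
        raise ValueError("tau_P must be > 0")
    lam_P = 1.0 / tau_P
    amps = np.concatenate(([internal.plateau], internal.amplitudes))
    rates = np.concatenate(([lam_P], internal.rates + lam_P))
    keep = amps != 0.0
    keep[0] = True  # always keep the tumbling mode, even for S2_total = 0
    return SpectralDensityModes(amplitudes=amps[keep], rates=rates[keep], plateau=0.0)


def _as_callable(J):
    return J.j if isinstance(J, SpectralDensityModes) else J


def r1_rate(J, k: SpinSystemConstants) -> float:
    """Longitudinal 15N relaxation rate, s^-1."""
    j = _as_callable(J)
    D2 = k.dipolar_constant**2
    C2 = k.csa_constant**2
    wH, wN = k.omega_H, k.omega_N
    return float(D2 / 4.0 * (j(wH - wN) + 3.0 * j(wN) + 6.0 * j(wH + wN)) + C2 * j(wN))


def r2_rate(J, k: SpinSystemConstants, Rex: float = 0.0) -> float:
    """Transverse 15N relaxation rate including additive exchange broadening."""
    if Rex < 0.0:
        raise ValueError("Rex must be >= 0")
    j = _as_callable(J)
    D2 = k.dipolar_constant**2
    C2 = k.csa_constant**2
    wH, wN = k.omega_H, k.omega_N
    dd = D2 / 8.0 * (4.0 * j(0.0) + j(wH - wN) + 3.0 * j(wN) + 6.0 * j(wH) + 6.0 * j(wH + wN))
    csa = C2 / 6.0 * (4.0 * j(0.0) + 3.0 * j(wN))
    return float(dd + csa + Rex)


def eta_xy_rate(J, k: SpinSystemConstants) -> float:
    """Transverse DD/CSA cross-correlated relaxation rate eta_xy, s^-1.

    Rex-free by mechanism; proportional to the same [4J(0) + 3J(wN)]
    combination as the adiabatic part of R2.
    """
    j = _as_callable(J)
    return float(k.cross_prefactor * k.p2_cos_beta * (4.0 * j(0.0) + 3.0 * j(k.omega_N)))


def r2_from_r1rho(R1rho: float, R1: float, offset_hz: float, spinlock_hz: float) -> float:
    """Combine R1rho and R1 into R2 with the standard tilted-frame correction.

    R2 = (R1rho - R1 cos^2 theta) / sin^2 theta with tan theta = nu1 / offset.
    A negative result (below-noise R1rho) is returned but flagged with a
    warning: it marks an invalid measurement, not a valid rate.
    """
    if spinlock_hz <= 0.0:
        raise ZeroDivisionError("spin-lock field strength must be > 0")
    theta = math.atan2(spinlock_hz, offset_hz)
    sin2 = math.sin(theta) ** 2
    cos2 = math.cos(theta) ** 2
    r2 = (R1rho - R1 * cos2) / sin2
    if r2 < 0.0:
        warnings.warn(
            f"R2={r2:.3g} s^-1 < 0 from R1rho={R1rho}, R1={R1}: invalid measurement",
            stacklevel=2,
        )
    return r2
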