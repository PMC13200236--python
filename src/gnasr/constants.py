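"""Spin-system constants for backbone amide 15N relaxation.

The 15N relaxation of an amide group is driven by the 1H-15N dipolar coupling
and the (axially symmetric) 15N chemical shielding anisotropy (CSA).  All rate
expressions in :mod:`gnasr.relaxation` are written in terms of two interaction
constants derived here:

    D = (mu0/4pi) * gamma_H * gamma_N * hbar / r_NH^3      (dipolar, rad/s)
    C = delta_sigma * omega_N / sqrt(3)                    (CSA, rad/s)

with omega_N = |gamma_N| * B0.  The DD/CSA cross-correlation prefactor is

    kappa = D * C * sqrt(3) / 6

so that eta_xy = kappa * P2(cos beta) * [4 J(0) + 3 J(omega_N)].  gamma_N is
negative and delta_sigma is negative for the amide 15N, hence kappa > 0 and
eta_xy carries the same sign as R2, matching the usual experimental convention.

The bond length (1.02 A), CSA (-170 ppm) and the 17 degree angle between the
N-H vector and the CSA principal axis are the conventional backbone-amide
values.  Calibrated gNASR order parameters are insensitive to all three: they
enter only through global prefactors that are absorbed by the calibration
factor d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MU0_OVER_4PI = 1.0e-7  # T m / A
HBAR = 1.054571817e-34  # J s
GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
GAMMA_N = -2.7126189e7  # rad s^-1 T^-1


@dataclass(frozen=True)
class SpinSystemConstants:
    """Field strength and interaction constants of the 1H-15N spin pair.

    Parameters
    ----------
    proton_larmor_mhz:
        1H resonance frequency in MHz (850 MHz corresponds to 19.97 T).
    magnetic_field:
        Static field in Tesla.  Derived from the Larmor frequency when None;
        if given explicitly it must agree with the frequency to within 0.5 %.
    r_NH:
        N-H bond length in meters.
    delta_sigma_ppm:
        Axially symmetric 15N CSA in ppm (negative for backbone amides).
    beta_angle_deg:
        Angle between the N-H vector and the CSA symmetry axis; enters only
        the eta_xy cross-correlation rate through P2(cos beta).
    """

    proton_larmor_mhz: float = 850.0
    magnetic_field: float | None = None
    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N
    r_NH: float = 1.02e-10
    delta_sigma_ppm: float = -170.0
    beta_angle_deg: float = 17.0

    def __post_init__(self) -> None:
        if not self.proton_larmor_mhz > 0:
            raise ValueError("proton_larmor_mhz must be > 0")
        if not (0.9e-10 <= self.r_NH <= 1.1e-10):
            raise ValueError("r_NH must lie in [0.9, 1.1] Angstrom")
        if self.magnetic_field is not None:
            implied = 2.0 * math.pi * self.proton_larmor_mhz * 1e6 / self.gamma_H
            if abs(self.magnetic_field - implied) > 0.005 * implied:
                raise ValueError(
                    f"magnetic_field {self.magnetic_field:.4f} T inconsistent with "
                    f"{self.proton_larmor_mhz} MHz (implies {implied:.4f} T)"
                )

    @property
    def B0(self) -> float:
        """Static field in Tesla (single source of truth: the 1H frequency)."""
        if self.magnetic_field is not None:
            return self.magnetic_field
        return 2.0 * math.pi * self.proton_larmor_mhz * 1e6 / self.gamma_H

    @property
    def omega_H(self) -> float:
        """1H angular Larmor frequency, rad/s."""
        return self.gamma_H * self.B0

    @property
    def omega_N(self) -> float:
        """15N angular Larmor frequency magnitude, rad/s."""
        return abs(self.gamma_N) * self.B0

    @property
    def dipolar_constant(self) -> float:
        """D = (mu0/4pi) gamma_H gamma_N hbar / r_NH^3 (signed, rad/s)."""
        return MU0_OVER_4PI * self.gamma_H * self.gamma_N * HBAR / self.r_NH**3

    @property
    def csa_constant(self) -> float:
        """C = delta_sigma * omega_N / sqrt(3) (signed, rad/s)."""
        return self.delta_sigma_ppm * 1e-6 * self.omega_N / math.sqrt(3.0)

    @property
    def cross_prefactor(self) -> float:
        """kappa = D*C*sqrt(3)/6, the DD/CSA cross-correlation prefactor."""
        return self.dipolar_constant * self.csa_constant * math.sqrt(3.0) / 6.0

    @property
    def p2_cos_beta(self) -> float:
        x = math.cos(math.radians(self.beta_angle_deg))
        return 0.5 * (3.0 * x * x - 1.0)
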