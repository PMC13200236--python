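"""Exchange-modulated overall tumbling and gel-induced relaxation enhancements.

The gel model is a two-state Markov-modulated isotropic rotational diffusion:
the protein either tumbles freely inside a gel cavity with correlation time
``tau_free_gel`` (slowed relative to the gel-free reference ``tau_ref`` by the
higher microscopic viscosity) or is transiently bound to the gel matrix, where
overall tumbling is fully suppressed (decay rate 0).  Orientational (rank-2)
correlation decays at lambda_state = 1/tau_state within each state while the
state hops with generator

    K = [[-k_fb, k_bf], [k_fb, -k_bf]],   k_fb = p_b k_ex, k_bf = (1-p_b) k_ex.

The overall correlation function is C_ov(t) = 1^T exp((K - diag(lambda)) t) p_eq,
which eigendecomposes into exactly two Lorentzian modes.  This discrete-state
reduction of the stochastic Liouville treatment is exact for the model as
drawn: no trajectory simulation is needed, and the bound state's tau -> inf is
represented exactly by lambda_b = 0.

Composite spectral densities multiply the overall modes with the internal
(model-free) modes; gel-minus-free rate differences (Delta R2, Delta R1,
Delta eta_xy) are formed with the exchange-broadening term Rex stripped, since
(x + Rex) - (y + Rex) = x - y identically — the Rex cancellation that makes
the method immune to chemical exchange.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.linalg

from .constants import SpinSystemConstants
from .errors import InfeasibleModelError, OracleFailure
from .relaxation import (
    MotionModel,
    SpectralDensityModes,
    compose_with_tumbling,
    eta_xy_rate,
    internal_correlation_modes,
    r1_rate,
    r2_rate,
)

__all__ = [
    "TumblingExchangeModel",
    "RateSet",
    "SweepResult",
    "overall_tumbling_modes",
    "composite_spectral_density",
    "free_spectral_density",
    "free_rates",
    "gel_rates",
    "delta_rates",
    "delta_r1",
    "delta_r2",
    "delta_eta_xy",
    "sweep_timescale_map",
    "effective_nasr_prefactor",
    "numerical_correlation_oracle",
]


@dataclass(frozen=True)
class TumblingExchangeModel:
    """Two-state gel tumbling model (defaults: the K-Ras-representative set).

    tau_ref 10 ns (gel-free sample), tau_free_gel 16 ns (unbound protein in
    the gel), bound population p_b = 0.25 % exchanging at k_ex = 5e5 s^-1 with
    tumbling fully suppressed while bound.
    """

    tau_ref: float = 10e-9
    tau_free_gel: float = 16e-9
    p_b: float = 0.0025
    k_ex: float = 5e5
    bound_tumbling_suppressed: bool = True

    def __post_init__(self) -> None:
        if not self.tau_ref > 0:
            raise ValueError("tau_ref must be > 0")
        if self.tau_free_gel < self.tau_ref:
            raise ValueError("tau_free_gel must be >= tau_ref (gel slows tumbling)")
        if not 0.0 <= self.p_b < 1.0:
            raise ValueError("p_b must lie in [0, 1)")
        if self.k_ex < 0:
            raise ValueError("k_ex must be >= 0")
        if self.p_b > 0 and self.bound_tumbling_suppressed and self.k_ex <= 0:
            raise InfeasibleModelError(
                "p_b > 0 with k_ex = 0 and suppressed bound tumbling: "
                "non-decaying bound component makes J(0) infinite"
            )

    @property
    def k_fb(self) -> float:
        return self.p_b * self.k_ex

    @property
    def k_bf(self) -> float:
        return (1.0 - self.p_b) * self.k_ex

    def generator(self) -> np.ndarray:
        """G = K - diag(lambda_f, lambda_b) acting on (free, bound) populations."""
        lam_f = 1.0 / self.tau_free_gel
        lam_b = 0.0 if self.bound_tumbling_suppressed else lam_f
        return np.array(
            [
                [-(self.k_fb + lam_f), self.k_bf],
                [self.k_fb, -(self.k_bf + lam_b)],
            ]
        )

    @property
    def p_eq(self) -> np.ndarray:
        return np.array([1.0 - self.p_b, self.p_b])


def overall_tumbling_modes(model: TumblingExchangeModel) -> SpectralDensityModes:
    """Eigendecompose the two-state tumbling correlation into Lorentzian modes.

    Returns one mode (pure tumbling) when p_b = 0, otherwise two.  Raises
    :class:`InfeasibleModelError` when a non-decaying component carries weight
    (bound state with no exchange, or all tumbling switched off).
    """
    lam_f = 1.0 / model.tau_free_gel
    if model.p_b == 0.0:
        return SpectralDensityModes(np.array([1.0]), np.array([lam_f]))
    G = model.generator()
    w, V = np.linalg.eig(G)
    if np.max(np.abs(w.imag)) > 1e-9 * np.max(np.abs(w.real)):
        raise InfeasibleModelError("complex tumbling eigenvalues (invalid generator)")
    w = w.real
    V = V.real
    coeff = np.linalg.solve(V, model.p_eq)
    amps = V.sum(axis=0) * coeff
    rates = -w
    scale = max(lam_f, model.k_ex)
    bad = (rates <= 1e-12 * scale) & (np.abs(amps) > 1e-12)
    if np.any(bad):
        raise InfeasibleModelError(
            "non-decaying orientational component with nonzero amplitude "
            f"(rates={rates}, amplitudes={amps})"
        )
    order = np.argsort(-rates)
    return SpectralDensityModes(amps[order], rates[order])


def composite_spectral_density(
    overall: SpectralDensityModes, motion: MotionModel
) -> SpectralDensityModes:
    """Product of overall tumbling and internal correlation functions.

    The product of two multi-exponentials is the multi-exponential with
    pairwise-summed rates and multiplied amplitudes; the internal plateau
    pairs with the overall modes so slow internal motion only decays through
    tumbling/exchange.
    """
    internal = internal_correlation_modes(motion)
    amps = [overall.amplitudes * internal.plateau]
    rates = [overall.rates.copy()]
    for a_k, nu_k in zip(internal.amplitudes, internal.rates):
        amps.append(overall.amplitudes * a_k)
        rates.append(overall.rates + nu_k)
    return SpectralDensityModes(np.concatenate(amps), np.concatenate(rates))


def free_spectral_density(motion: MotionModel, tau_ref: float) -> SpectralDensityModes:
    """Spectral density of the gel-free reference condition."""
    return compose_with_tumbling(internal_correlation_modes(motion), tau_ref)


@dataclass(frozen=True)
class RateSet:
    R1: float
    R2: float
    eta_xy: float


def free_rates(
    motion: MotionModel, model: TumblingExchangeModel, k: SpinSystemConstants
) -> RateSet:
    """R1, R2 (incl. Rex), eta_xy in the gel-free reference sample."""
    J = free_spectral_density(motion, model.tau_ref)
    return RateSet(r1_rate(J, k), r2_rate(J, k, motion.Rex), eta_xy_rate(J, k))


def gel_rates(
    motion: MotionModel, model: TumblingExchangeModel, k: SpinSystemConstants
) -> RateSet:
    """R1, R2 (incl. Rex), eta_xy in the gel, under exchange-modulated tumbling."""
    J = composite_spectral_density(overall_tumbling_modes(model), motion)
    return RateSet(r1_rate(J, k), r2_rate(J, k, motion.Rex), eta_xy_rate(J, k))


def delta_rates(
    motion: MotionModel, model: TumblingExchangeModel, k: SpinSystemConstants
) -> RateSet:
    """Gel-minus-free rate differences (Delta R1, Delta R2, Delta eta_xy).

    Rex is stripped before differencing: the cancellation is an algebraic
    identity, so the result is bitwise independent of ``motion.Rex``.
    """
    m0 = dataclasses.replace(motion, Rex=0.0)
    g = gel_rates(m0, model, k)
    f = free_rates(m0, model, k)
    return RateSet(g.R1 - f.R1, g.R2 - f.R2, g.eta_xy - f.eta_xy)


def delta_r1(motion, model, k) -> float:
    return delta_rates(motion, model, k).R1


def delta_r2(motion, model, k) -> float:
    return delta_rates(motion, model, k).R2


def delta_eta_xy(motion, model, k) -> float:
    return delta_rates(motion, model, k).eta_xy


@dataclass(frozen=True)
class SweepResult:
    """Delta R2 and free-R2 maps over motional amplitude and time scale.

    ``delta_R2[i, j]`` is the gel enhancement for S2 = ``S2_values[i]`` and a
    single internal time scale ``tau_int_grid[j]``; ``normalized_R2_free`` is
    the gel-free R2 divided by its rigid-rotor value (the gray reference
    curves).  ``delta_R2_rigid`` is the rigid-limit enhancement.
    """

    S2_values: np.ndarray
    tau_int_grid: np.ndarray
    delta_R2: np.ndarray
    normalized_R2_free: np.ndarray
    delta_R2_rigid: float

    def to_tsv(self, path) -> None:
        """Matrix TSV: header row of tau_int (s), first column of S2."""
        with open(path, "w") as fh:
            fh.write("# gNASR Delta R2 sweep (s^-1); rows S2, columns tau_int (s)\n")
            fh.write("S2\t" + "\t".join(f"{t:.6g}" for t in self.tau_int_grid) + "\n")
            for s2, row in zip(self.S2_values, self.delta_R2):
                fh.write(f"{s2:.6g}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def sweep_timescale_map(
    S2_values,
    tau_int_grid,
    model: TumblingExchangeModel,
    k: SpinSystemConstants,
) -> SweepResult:
    """Map Delta R2 over (S2, tau_int) for single-time-scale internal motion.

    The probed motion occupies the slow slot (S2_fast = 1) so its time scale
    may range from ps to microseconds.
    """
    S2_values = np.atleast_1d(np.asarray(S2_values, dtype=float))
    tau_int_grid = np.atleast_1d(np.asarray(tau_int_grid, dtype=float))
    if S2_values.size == 0 or tau_int_grid.size == 0:
        raise ValueError("S2_values and tau_int_grid must be nonempty")
    rigid = MotionModel()
    d_rigid = delta_r2(rigid, model, k)
    r2_rigid_free = free_rates(rigid, model, k).R2
    dR2 = np.empty((S2_values.size, tau_int_grid.size))
    r2f = np.empty_like(dR2)
    for i, s2 in enumerate(S2_values):
        for j, tau in enumerate(tau_int_grid):
            motion = MotionModel(S2_fast=1.0, S2_slow=s2, tau_slow=tau)
            dR2[i, j] = delta_r2(motion, model, k)
            r2f[i, j] = free_rates(motion, model, k).R2
    return SweepResult(S2_values, tau_int_grid, dR2, r2f / r2_rigid_free, d_rigid)


@dataclass(frozen=True)
class NasrPrefactor:
    """Least-squares slope of Delta R2 vs S2 (the effective NASR prefactor c')."""

    slope: float  # s^-1 per unit S2
    intercept: float
    r_squared: float


def effective_nasr_prefactor(
    model: TumblingExchangeModel,
    k: SpinSystemConstants,
    tau_int: float = 50e-12,
    s2_grid=None,
) -> NasrPrefactor:
    """Slope of Delta R2 against S2 for fast internal motion (tau_int << tau_ref).

    In the fast-exchange NASR picture Delta R2 = c p_b tau_NP S2; here the
    slope bundles the binding and viscosity contributions into one effective
    global prefactor, reported with the linearity R^2 of the fit.
    """
    if s2_grid is None:
        s2_grid = np.linspace(0.3, 1.0, 15)
    s2_grid = np.asarray(s2_grid, dtype=float)
    d = np.array(
        [
            delta_r2(MotionModel(S2_fast=s2, tau_fast=tau_int), model, k)
            for s2 in s2_grid
        ]
    )
    slope, intercept = np.polyfit(s2_grid, d, 1)
    resid = d - (slope * s2_grid + intercept)
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return NasrPrefactor(float(slope), float(intercept), r2)


# ---------------------------------------------------------------------------
# Quadrature oracle


def _fourier_cos_integral(f, omega: float) -> float:
    """integral_0^inf f(t) cos(omega t) dt by piecewise adaptive quadrature.

    The correlation function spans ps to sub-ms scales, so the axis is split
    into log-spaced decade segments up to the point where the envelope is
    negligible; each finite segment uses the oscillatory (QAWO) rule when
    omega > 0.  The neglected tail is bounded by the envelope cutoff.
    """
    decades = 10.0 ** np.arange(-13.0, -1.0)
    t_max = decades[-1]
    for t in decades:
        if abs(f(t)) < 1e-22:
            t_max = t
            break
    edges = np.concatenate(([0.0], decades[decades < t_max], [t_max]))
    total = 0.0
    err_total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        kwargs = dict(epsabs=1e-20, epsrel=1e-9, limit=500, full_output=1)
        if omega > 0.0:
            kwargs.update(weight="cos", wvar=omega)
        out = scipy.integrate.quad(f, a, b, **kwargs)
        val, err = out[0], out[1]
        if len(out) > 3 and err > max(1e-8 * abs(val), 1e-18):
            raise OracleFailure(f"quadrature failed on [{a:g}, {b:g}]: {out[3]}")
        total += val
        err_total += err
    if err_total > max(1e-6 * abs(total), 1e-16):
        raise OracleFailure(
            f"accumulated quadrature error {err_total:g} too large for J={total:g}"
        )
    return total


def numerical_correlation_oracle(
    source,
    omega: float,
    model: TumblingExchangeModel | None = None,
) -> float:
    """J(omega) by adaptive quadrature of (2/5) integral C(t) cos(wt) dt.

    ``source`` is either a :class:`SpectralDensityModes` (C from the mode sum)
    or a :class:`MotionModel`, in which case ``model`` must be given and the
    overall correlation is evaluated from the matrix exponential of the
    two-state generator — fully independent of the eigendecomposition path it
    is used to check.
    """
    if isinstance(source, MotionModel):
        if model is None:
            raise ValueError("a TumblingExchangeModel is required with a MotionModel")
        G = model.generator()
        p_eq = model.p_eq
        motion = source

        def c_int(t: float) -> float:
            out = motion.S2_total
            if motion.S2_fast < 1.0:
                out += (1.0 - motion.S2_fast) * np.exp(-t / motion.tau_fast)
            if motion.S2_slow < 1.0:
                out += motion.S2_fast * (1.0 - motion.S2_slow) * np.exp(-t / motion.tau_slow)
            return out

        if model.p_b == 0.0:
            lam_f = 1.0 / model.tau_free_gel

            def f(t: float) -> float:
                return 0.4 * np.exp(-lam_f * t) * c_int(t)

        else:

            def f(t: float) -> float:
                return 0.4 * float(scipy.linalg.expm(G * t).sum(axis=0) @ p_eq) * c_int(t)

    else:
        modes: SpectralDensityModes = source
        if modes.plateau != 0.0:
            raise ValueError("oracle requires fully decaying modes (plateau = 0)")

        def f(t: float) -> float:
            return 0.4 * float(np.sum(modes.amplitudes * np.exp(-modes.rates * t)))

    return _fourier_cos_integral(f, omega)
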