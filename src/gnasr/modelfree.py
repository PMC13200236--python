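"""Lean model-free analysis of free-protein R1 and R2.

"Lean" means R1 and R2 only (no heteronuclear NOE): a global tumbling time
tau_P is estimated from the trimmed R2/R1 ratio of well-ordered residues, then
each residue is fit with the single-time-scale Lipari-Szabo spectral density

    J(w) = (2/5) [ S2 tau_P / (1 + (w tau_P)^2) + (1-S2) tau' / (1 + (w tau')^2) ],
    1/tau' = 1/tau_P + 1/tau_int.

With two observables and two parameters the problem is exactly determined.
Both rates are linear in S2 at fixed tau_int, so the fit eliminates S2 through
R1 and solves a bracketed 1-D root problem in tau_int; a chi-squared grid +
local refinement serves as fallback when no exact root exists (e.g. data
corrupted by exchange broadening, which two observables cannot constrain —
such residues are flagged ``excluded``, not fitted).

Because only motions faster than tau_P modulate the free-protein rates
appreciably, S2 from this analysis reflects S2_fast alone: slower (ns-us)
motions are its blind spot, which the gNASR difference is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .constants import SpinSystemConstants
from .errors import EstimationError, InsufficientDataError
from .relaxation import SpectralDensityModes, r1_rate, r2_rate

__all__ = [
    "ModelFreeResult",
    "estimate_global_tumbling",
    "fit_residue_modelfree",
    "lean_modelfree_profile",
]

DEFAULT_RELATIVE_ERROR = 0.02
TAU_INT_MAX = 5e-9  # s, upper fit bound
TAU_INT_FLOOR = 1e-12  # below 1 ps the time scale is not determined


@dataclass(frozen=True)
class ModelFreeResult:
    residue_id: int
    S2: float
    tau_int: float
    tau_P_used: float
    chi2: float
    model_flag: str  # "S2-only" | "S2+tau" | "excluded"


def _rigid_rates(tau_P: float, k: SpinSystemConstants) -> tuple[float, float]:
    J = SpectralDensityModes(np.array([1.0]), np.array([1.0 / tau_P]))
    return r1_rate(J, k), r2_rate(J, k)


def _mode_rates(lam, k: SpinSystemConstants):
    """R1, R2 generated by a unit-amplitude Lorentzian of decay rate lam.

    Closed form (vectorised in lam) for speed: the per-residue fit evaluates
    this on dense tau grids.
    """
    lam = np.asarray(lam, dtype=float)

    def j(w):
        return 0.4 * lam / (lam**2 + w**2)

    D2 = k.dipolar_constant**2
    C2 = k.csa_constant**2
    wH, wN = k.omega_H, k.omega_N
    r1 = D2 / 4.0 * (j(wH - wN) + 3 * j(wN) + 6 * j(wH + wN)) + C2 * j(wN)
    r2 = (
        D2 / 8.0 * (4 * j(0.0) + j(wH - wN) + 3 * j(wN) + 6 * j(wH) + 6 * j(wH + wN))
        + C2 / 6.0 * (4 * j(0.0) + 3 * j(wN))
    )
    return r1, r2


def estimate_global_tumbling(
    table,
    k: SpinSystemConstants,
    bracket: tuple[float, float] = (1e-9, 100e-9),
    n_trim_passes: int = 2,
) -> float:
    """Global tumbling time from the trimmed mean R2/R1 ratio.

    Residues whose R2/R1 deviates more than 1.5 SD from the median are
    excluded (the exclusion pass is iterated once), then tau_P solves
    <R2/R1> = f(tau_P) for a rigid rotor, bracketed on [1, 100] ns.
    """
    df = table.data[["R1", "R2"]].dropna()
    df = df[(df["R1"] > 0) & (df["R2"] > 0)]
    if len(df) < 5:
        raise InsufficientDataError(
            f"tumbling estimation needs >= 5 residues with valid R1, R2 (got {len(df)})"
        )
    ratio = (df["R2"] / df["R1"]).to_numpy()
    keep = np.ones(ratio.size, dtype=bool)
    for _ in range(n_trim_passes):
        med = np.median(ratio[keep])
        sd = np.std(ratio[keep], ddof=1) if keep.sum() > 1 else 0.0
        if sd == 0.0:
            break
        keep = np.abs(ratio - med) <= 1.5 * sd
    target = float(ratio[keep].mean())

    def g(tau: float) -> float:
        r1, r2 = _rigid_rates(tau, k)
        return r2 / r1 - target

    lo, hi = bracket
    if g(lo) * g(hi) > 0:
        raise EstimationError(
            f"no tumbling time in [{lo * 1e9:.0f}, {hi * 1e9:.0f}] ns matches "
            f"<R2/R1> = {target:.3f}"
        )
    return float(scipy.optimize.brentq(g, lo, hi, xtol=1e-16, rtol=8.9e-16))


def _predict(s2: float, tau_int: float, plateau: tuple, k: SpinSystemConstants, tau_P: float):
    r1p, r2p = plateau
    if tau_int <= 0.0:
        return s2 * r1p, s2 * r2p
    lam = 1.0 / tau_P + 1.0 / tau_int
    r1m, r2m = _mode_rates(lam, k)
    return s2 * r1p + (1.0 - s2) * float(r1m), s2 * r2p + (1.0 - s2) * float(r2m)


def fit_residue_modelfree(
    R1: float,
    R2: float,
    R1_err: float | None,
    R2_err: float | None,
    tau_P: float,
    k: SpinSystemConstants,
    residue_id: int = 0,
    chi2_max: float = 10.0,
) -> ModelFreeResult:
    """Two-parameter (S2, tau_int) fit of one residue's R1 and R2.

    Uncertainties default to 2 % of the rate when absent.  If the best
    tau_int falls below 1 ps or the solution is degenerate (rigid residue),
    the residue is refit with tau_int fixed at 0 (``S2-only``); a residual
    chi2 above ``chi2_max`` flags the residue ``excluded``.
    """
    s1 = R1_err if (R1_err is not None and R1_err > 0) else DEFAULT_RELATIVE_ERROR * abs(R1)
    s2e = R2_err if (R2_err is not None and R2_err > 0) else DEFAULT_RELATIVE_ERROR * abs(R2)
    plateau = _rigid_rates(tau_P, k)
    r1p, r2p = plateau

    def chi2_of(s2: float, tau: float) -> float:
        c1, c2 = _predict(s2, tau, plateau, k, tau_P)
        return ((R1 - c1) / s1) ** 2 + ((R2 - c2) / s2e) ** 2

    # S2-only solution (tau_int = 0): weighted least squares, both rates ~ S2
    num = R1 * r1p / s1**2 + R2 * r2p / s2e**2
    den = r1p**2 / s1**2 + r2p**2 / s2e**2
    s2_only = float(np.clip(num / den, 0.0, 1.0))
    cand = [(chi2_of(s2_only, 0.0), s2_only, 0.0)]

    # Full fit: eliminate S2 via R1, root-find the R2 residual in tau_int.
    # Near the R1 degeneracy (r1m = r1p) the unclipped S2 diverges; clipping
    # to [0, 1] keeps g finite and simply marks that tau region infeasible.
    def s2_from_r1(tau: float) -> float:
        lam = 1.0 / tau_P + 1.0 / tau
        r1m = float(_mode_rates(lam, k)[0])
        d = r1p - r1m
        if d == 0.0:
            return np.inf if R1 >= r1p else -np.inf
        return (R1 - r1m) / d

    def g(tau: float) -> float:
        s2c = float(np.clip(s2_from_r1(tau), 0.0, 1.0))
        _, c2 = _predict(s2c, tau, plateau, k, tau_P)
        return c2 - R2

    taus = np.logspace(-13, np.log10(TAU_INT_MAX), 60)
    r1m_g, r2m_g = _mode_rates(1.0 / tau_P + 1.0 / taus, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2_raw = (R1 - r1m_g) / (r1p - r1m_g)
    s2_cl = np.clip(np.nan_to_num(s2_raw, nan=np.inf, posinf=np.inf, neginf=-np.inf), 0.0, 1.0)
    gv = s2_cl * r2p + (1.0 - s2_cl) * r2m_g - R2
    for i in range(len(taus) - 1):
        if gv[i] * gv[i + 1] > 0:
            continue
        root = scipy.optimize.brentq(g, taus[i], taus[i + 1], xtol=1e-18, rtol=8.9e-16)
        s2c = float(np.clip(s2_from_r1(root), 0.0, 1.0))
        cand.append((chi2_of(s2c, root), s2c, float(root)))

    # chi2-surface fallback/refinement from the best grid point
    s2_grid = np.linspace(0.0, 1.0, 21)
    c1 = s2_grid[:, None] * r1p + (1.0 - s2_grid[:, None]) * r1m_g[None, :]
    c2 = s2_grid[:, None] * r2p + (1.0 - s2_grid[:, None]) * r2m_g[None, :]
    chi_grid = ((R1 - c1) / s1) ** 2 + ((R2 - c2) / s2e) ** 2
    i0, j0 = np.unravel_index(np.argmin(chi_grid), chi_grid.shape)
    res = scipy.optimize.minimize(
        lambda x: chi2_of(x[0], x[1]),
        x0=[s2_grid[i0], taus[j0]],
        bounds=[(0.0, 1.0), (0.0, TAU_INT_MAX)],
        method="L-BFGS-B",
    )
    cand.append((float(res.fun), float(res.x[0]), float(res.x[1])))

    # lowest chi2, ties broken by lowest tau_int
    cand.sort(key=lambda c: (round(c[0], 12), c[2]))
    chi2_best, s2_best, tau_best = cand[0]
    flag = "S2+tau"
    if tau_best < TAU_INT_FLOOR:
        chi2_best, s2_best, tau_best = cand[0][0], s2_only, 0.0
        chi2_best = chi2_of(s2_only, 0.0)
        flag = "S2-only"
    if chi2_best > chi2_max:
        flag = "excluded"
    return ModelFreeResult(
        residue_id=residue_id,
        S2=s2_best,
        tau_int=tau_best,
        tau_P_used=tau_P,
        chi2=chi2_best,
        model_flag=flag,
    )


def lean_modelfree_profile(
    table,
    k: SpinSystemConstants,
    tau_P: float | None = None,
    chi2_max: float = 10.0,
):
    """Per-residue lean model-free order parameters for one rate table.

    Returns an :class:`~gnasr.tables.OrderParameterProfile` with source
    ``"MF"``; tau_P is estimated from the table unless given.
    """
    from .tables import OrderParameterProfile

    if len(table.data) == 0:
        raise InsufficientDataError("empty rate table")
    if tau_P is None:
        tau_P = estimate_global_tumbling(table, k)
    rows = []
    for residue, rec in table.data.iterrows():
        res = fit_residue_modelfree(
            rec["R1"],
            rec["R2"],
            rec.get("R1_err"),
            rec.get("R2_err"),
            tau_P,
            k,
            residue_id=int(residue),
            chi2_max=chi2_max,
        )
        rows.append(
            {
                "residue": res.residue_id,
                "S2": res.S2,
                "S2_err": np.nan,
                "tau_int": res.tau_int,
                "chi2": res.chi2,
                "model_flag": res.model_flag,
            }
        )
    data = pd.DataFrame(rows).set_index("residue")
    return OrderParameterProfile(source="MF", data=data, tau_P_used=tau_P)
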