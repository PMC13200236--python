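"""The gNASR analysis pipeline: difference, calibrate, compare.

Workflow: pair matched free/gel rate tables residue-by-residue, form the
gel-induced enhancements Delta R2 (and Delta R1, Delta eta_xy), then convert
Delta R2 to order parameters by uniform scaling,

    S2(gNASR) = d * Delta R2,

with d fixed so that the mean S2 over a user-supplied calibration mask — the
most stable stretches of secondary structure, assumed rigid apart from fast
librations with S2 ~ 0.85 — equals the calibration target (default 0.85).
Delta eta_xy is converted to S2_eta(gNASR) in the identical way.  Because d
absorbs every global prefactor, the result is independent of bond length,
CSA, cross-correlation convention, and overall scale of the input rates.

The calibrated profile is finally compared against a conventional lean
model-free profile from the free-protein rates; residues where S2(gNASR)
falls well below S2(MF) are candidate sites of ns-us internal motion that the
free-protein rates cannot see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import SpinSystemConstants
from .errors import CalibrationError, ComparisonError, GnasrError, PairingError
from .modelfree import lean_modelfree_profile
from .tables import (
    CalibrationMask,
    DeltaProfile,
    OrderParameterProfile,
    RateTable,
    RunConfig,
    read_mask,
    read_rate_table,
)

logger = logging.getLogger("gnasr")

__all__ = [
    "pair_and_difference",
    "calibrate_order_parameters",
    "compare_profiles",
    "ProfileComparison",
    "AnalysisResult",
    "analyze",
    "SLOW_MOTION_MARGIN",
]

#: a-profile S2 below b-profile S2 by more than this margin flags a residue
#: as a candidate slow-motion site
SLOW_MOTION_MARGIN = 0.1


def pair_and_difference(free: RateTable, gel: RateTable) -> DeltaProfile:
    """Per-residue gel-minus-free differences with quadrature errors.

    Only residues present in both tables enter the profile; unmatched
    residues are logged, not fatal.
    """
    if free.condition != "free" or gel.condition != "gel":
        raise PairingError(
            f"expected conditions free/gel, got {free.condition!r}/{gel.condition!r}"
        )
    shared = free.residues.intersection(gel.residues)
    if len(shared) == 0:
        raise PairingError("free and gel tables share no residues")
    shared = shared.sort_values()
    unmatched_free = free.residues.difference(shared).tolist()
    unmatched_gel = gel.residues.difference(shared).tolist()
    if unmatched_free or unmatched_gel:
        logger.info(
            "unmatched residues: %d free-only, %d gel-only",
            len(unmatched_free),
            len(unmatched_gel),
        )
    f = free.data.loc[shared]
    g = gel.data.loc[shared]
    out = pd.DataFrame(index=shared)
    out.index.name = "residue"
    for name in ("R1", "R2"):
        out[f"delta_{name}"] = g[name] - f[name]
        out[f"delta_{name}_err"] = np.hypot(g[f"{name}_err"], f[f"{name}_err"])
    if free.has_eta and gel.has_eta:
        out["delta_eta"] = g["eta_xy"] - f["eta_xy"]
        out["delta_eta_err"] = np.hypot(g["eta_err"], f["eta_err"])
    return DeltaProfile(data=out, unmatched_free=unmatched_free, unmatched_gel=unmatched_gel)


def calibrate_order_parameters(
    delta: DeltaProfile,
    mask: CalibrationMask,
    target: float = 0.85,
    channel: str = "R2",
) -> OrderParameterProfile:
    """Scale a delta profile to order parameters, S2 = d * delta.

    d = target / <delta over the calibration mask>.  Values above 1 are kept
    (and flagged) rather than clamped: they are evidence of noise or a
    misspecified mask, and hiding them would bias the profile.
    """
    if channel not in {"R2", "eta"}:
        raise ValueError(f"channel must be 'R2' or 'eta', got {channel!r}")
    col = "delta_R2" if channel == "R2" else "delta_eta"
    if col not in delta.data.columns:
        raise CalibrationError(f"delta profile has no {col} channel")
    cal = mask.calibration_residues.intersection(delta.data.index)
    if len(cal) < 3:
        raise CalibrationError(
            f"only {len(cal)} calibration residues present in the delta profile (need >= 3)"
        )
    masked_mean = float(delta.data.loc[cal, col].mean())
    if not masked_mean > 0.0:
        raise CalibrationError(
            f"non-positive calibration-mask mean {col} = {masked_mean:.4g}: "
            "corrupted input or swapped free/gel condition labels"
        )
    d = target / masked_mean
    out = pd.DataFrame(index=delta.data.index)
    out["S2"] = d * delta.data[col]
    out["S2_err"] = d * delta.data[f"{col}_err"]
    out["above_one"] = out["S2"] > 1.0
    n_above = int(out["above_one"].sum())
    if n_above:
        logger.warning("%d residues calibrated to S2 > 1 (retained, flagged)", n_above)
    source = "gNASR" if channel == "R2" else "eta-gNASR"
    return OrderParameterProfile(source=source, data=out, calibration_factor_d=d)


@dataclass
class ProfileComparison:
    """Summary of two order-parameter profiles on their shared residues."""

    data: pd.DataFrame  # S2_a, S2_b, diff
    rmsd: float
    pearson_r: float
    slow_motion_residues: list  # residues with S2_a < S2_b - SLOW_MOTION_MARGIN
    source_a: str
    source_b: str


def compare_profiles(a: OrderParameterProfile, b: OrderParameterProfile) -> ProfileComparison:
    """Residue-matched comparison: differences, RMSD, Pearson r, slow-motion flags.

    Residues flagged ``excluded`` in either profile (e.g. exchange-broadened
    sites the lean model-free fit cannot describe) carry no valid S2 and are
    dropped before comparison.
    """
    shared = a.data.index.intersection(b.data.index).sort_values()
    for prof in (a, b):
        if "model_flag" in prof.data.columns:
            bad = prof.data.index[prof.data["model_flag"] == "excluded"]
            if len(bad):
                logger.info("dropping %d excluded residues from comparison", len(bad))
                shared = shared.difference(bad)
    if len(shared) < 3:
        raise ComparisonError(f"profiles share only {len(shared)} residues (need >= 3)")
    s2a = a.data.loc[shared, "S2"]
    s2b = b.data.loc[shared, "S2"]
    diff = s2a - s2b
    df = pd.DataFrame({"S2_a": s2a, "S2_b": s2b, "diff": diff})
    rmsd = float(np.sqrt(np.mean(diff.to_numpy() ** 2)))
    if np.std(s2a) == 0.0 or np.std(s2b) == 0.0:
        r = 1.0 if rmsd == 0.0 else np.nan
    else:
        r = float(np.corrcoef(s2a, s2b)[0, 1])
    flagged = shared[s2a < s2b - SLOW_MOTION_MARGIN].tolist()
    return ProfileComparison(
        data=df,
        rmsd=rmsd,
        pearson_r=r,
        slow_motion_residues=flagged,
        source_a=a.source,
        source_b=b.source,
    )


@dataclass
class AnalysisResult:
    """End-to-end gNASR analysis bundle."""

    delta: DeltaProfile
    s2_gnasr: OrderParameterProfile
    s2_eta: OrderParameterProfile | None
    s2_mf: OrderParameterProfile
    comparison: ProfileComparison  # gNASR vs MF
    eta_consistency: ProfileComparison | None  # eta-gNASR vs gNASR
    config: RunConfig


def analyze(
    free_path,
    gel_path,
    mask_path,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """Run the full pipeline on free/gel/mask files.

    Deterministic given the inputs.  Any stage failure is re-raised with the
    stage name prepended.  The eta channel is analysed only when both tables
    carry eta columns.
    """
    config = config or RunConfig()
    k = SpinSystemConstants(proton_larmor_mhz=config.field_mhz)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GnasrError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    free = stage("read-free", read_rate_table, free_path, condition="free")
    gel = stage("read-gel", read_rate_table, gel_path, condition="gel")
    mask = stage("read-mask", read_mask, mask_path)
    delta = stage("difference", pair_and_difference, free, gel)
    s2_gnasr = stage(
        "calibrate", calibrate_order_parameters, delta, mask, target=config.target_s2
    )
    s2_eta = None
    eta_consistency = None
    if delta.has_eta:
        s2_eta = stage(
            "calibrate-eta",
            calibrate_order_parameters,
            delta,
            mask,
            target=config.target_s2,
            channel="eta",
        )
    else:
        logger.info("eta columns absent: eta-gNASR channel skipped")
    s2_mf = stage(
        "model-free", lean_modelfree_profile, free, k, chi2_max=config.chi2_max
    )
    comparison = stage("compare", compare_profiles, s2_gnasr, s2_mf)
    if s2_eta is not None:
        eta_consistency = stage("compare-eta", compare_profiles, s2_eta, s2_gnasr)
    return AnalysisResult(
        delta=delta,
        s2_gnasr=s2_gnasr,
        s2_eta=s2_eta,
        s2_mf=s2_mf,
        comparison=comparison,
        eta_consistency=eta_consistency,
        config=config,
    )
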