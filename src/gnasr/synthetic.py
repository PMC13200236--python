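"""Synthetic paired free/gel relaxation datasets with known ground truth.

The generator emulates the dynamics architecture of a small globular GTPase
(K-Ras-like, 170 residues by default): rigid helix/sheet cores with fast
(tens of ps) librations of S2_fast ~ 0.85, more mobile loops, termini ramping
toward S2 ~ 0.2, one or more "slow loops" carrying an additional ns-sub-us
process invisible to conventional model-free analysis (the Switch-II-like
dip), and isolated exchange-broadened sites whose Rex inflates R2 equally
with and without gel.

Rates are produced by the package's own forward model — the gel-free spectral
density at tau_ref and the exchange-modulated gel model — then perturbed by
independent Gaussian relative noise.  Helix/sheet segment centres are flagged
as the calibration mask and are rigid apart from fast librations by
construction (S2_fast in [0.82, 0.88], S2_slow = 1, Rex = 0), so the
calibration premise holds exactly in every generated bundle.

Randomness is drawn from per-residue substreams seeded as (seed, residue),
so enlarging or editing the architecture never reshuffles other residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import SpinSystemConstants
from .errors import GnasrError
from .exchange import TumblingExchangeModel, free_rates, gel_rates
from .relaxation import MotionModel
from .tables import RateTable, RunConfig, write_mask, write_rate_table
from .tables import CalibrationMask

__all__ = [
    "Segment",
    "GroundTruthProfile",
    "kras_like_architecture",
    "representative_slow_architecture",
    "generate_ground_truth_profile",
    "simulate_rate_tables",
    "write_fixture_set",
    "REPRESENTATIVE_SLOW_LOOP",
]

#: per-segment-kind default parameter ranges; tuples are uniform ranges
#: (log-uniform for tau_slow), scalars are fixed values
KIND_DEFAULTS: dict[str, dict] = {
    "helix": {"S2_fast": (0.82, 0.88), "tau_fast": (20e-12, 80e-12)},
    "sheet": {"S2_fast": (0.82, 0.88), "tau_fast": (20e-12, 80e-12)},
    "loop": {"S2_fast": (0.5, 0.8), "tau_fast": (20e-12, 80e-12)},
    "terminus": {"tau_fast": (20e-12, 80e-12)},  # S2_fast ramps toward 0.2
    "slow_loop": {
        "S2_fast": (0.5, 0.8),
        "tau_fast": (20e-12, 80e-12),
        "S2_slow": (0.5, 0.8),
        "tau_slow": (50e-9, 1e-6),
    },
    "rex_site": {"S2_fast": (0.5, 0.8), "tau_fast": (20e-12, 80e-12), "Rex": (2.0, 10.0)},
}

SS_CLASS = {"helix": "H", "sheet": "E"}
TERMINUS_FLOOR = 0.2


@dataclass(frozen=True)
class Segment:
    """Contiguous stretch of residues sharing one dynamics regime.

    ``params`` overrides the kind defaults; a 2-tuple is sampled uniformly
    (log-uniformly for tau_slow), a scalar is fixed.
    """

    kind: str
    start: int
    end: int  # inclusive
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KIND_DEFAULTS:
            raise GnasrError(f"unknown segment kind {self.kind!r}")
        if self.end < self.start:
            raise GnasrError(f"segment {self.kind} has end < start")


def kras_like_architecture(n_residues: int = 170) -> list[Segment]:
    """Default 170-residue architecture loosely modelled on a small GTPase.

    Flexible termini, alternating sheets/helices with connecting loops, a
    Switch-I-like and a Switch-II-like slow loop (residues 30-36 and 60-64),
    and a short exchange-broadened patch.  For other lengths the structured
    part is clipped or the final helix extended, keeping a 4-residue
    C-terminal tail; at least 70 residues are required.
    """
    segments = [
        Segment("terminus", 1, 4),
        Segment("sheet", 5, 14),
        Segment("loop", 15, 16),
        Segment("helix", 17, 25),
        Segment("loop", 26, 29),
        Segment("slow_loop", 30, 36),  # Switch-I-like
        Segment("sheet", 37, 46),
        Segment("loop", 47, 56),
        Segment("rex_site", 57, 59),
        Segment("slow_loop", 60, 64),  # Switch-II-like
        Segment("helix", 65, 74),
        Segment("loop", 75, 76),
        Segment("sheet", 77, 84),
        Segment("loop", 85, 86),
        Segment("helix", 87, 104),
        Segment("loop", 105, 109),
        Segment("sheet", 110, 116),
        Segment("loop", 117, 126),
        Segment("helix", 127, 137),
        Segment("loop", 138, 140),
        Segment("sheet", 141, 148),
        Segment("loop", 149, 151),
        Segment("helix", 152, 166),
    ]
    if n_residues < 70:
        raise GnasrError("kras_like_architecture needs >= 70 residues")
    cut = n_residues - 4  # last structured residue before the C-terminal tail
    out = []
    for seg in segments:
        if seg.start > cut:
            break
        out.append(Segment(seg.kind, seg.start, min(seg.end, cut), seg.params))
    last = out[-1]
    if last.end < cut:  # chain longer than the canonical layout
        out[-1] = Segment(last.kind, last.start, cut, last.params)
    out.append(Segment("terminus", cut + 1, n_residues))
    return out


#: representative slow-loop parameterization: the reference slow process
#: (S2_slow = 0.6, tau_slow = 200 ns) carried by an otherwise ordered
#: backbone, i.e. the Switch-II-like picture of a localized S2 dip within a
#: high-S2 region
REPRESENTATIVE_SLOW_LOOP = {
    "S2_fast": (0.82, 0.88),
    "S2_slow": 0.6,
    "tau_slow": 200e-9,
}


def representative_slow_architecture(n_residues: int = 170) -> list[Segment]:
    """Default architecture with slow loops at the representative strength."""
    return [
        Segment("slow_loop", s.start, s.end, REPRESENTATIVE_SLOW_LOOP)
        if s.kind == "slow_loop"
        else s
        for s in kras_like_architecture(n_residues)
    ]


def _validate_architecture(segments: list[Segment], n_residues: int) -> None:
    covered = np.zeros(n_residues + 1, dtype=int)
    for seg in segments:
        if seg.start < 1 or seg.end > n_residues:
            raise GnasrError(f"segment {seg.kind} [{seg.start}, {seg.end}] outside 1..{n_residues}")
        covered[seg.start : seg.end + 1] += 1
    if np.any(covered[1:] != 1):
        bad = np.nonzero(covered[1:] != 1)[0] + 1
        raise GnasrError(f"segments must cover 1..{n_residues} exactly once; bad residues {bad[:10]}")


@dataclass
class GroundTruthProfile:
    """Per-residue motion models plus the global simulation conditions."""

    data: pd.DataFrame  # index residue; kind, ss_class, in_calibration, motion params
    gel_model: TumblingExchangeModel
    constants: SpinSystemConstants
    noise_level: float
    seed: int

    def motion(self, residue: int) -> MotionModel:
        rec = self.data.loc[residue]
        return MotionModel(
            S2_fast=rec["S2_fast"],
            tau_fast=rec["tau_fast"],
            S2_slow=rec["S2_slow"],
            tau_slow=rec["tau_slow"],
            Rex=rec["Rex"],
        )

    @property
    def slow_motion_residues(self) -> list:
        return self.data.index[self.data["S2_slow"] < 1.0].tolist()

    @property
    def mask(self) -> CalibrationMask:
        df = self.data[["ss_class", "in_calibration"]].copy()
        return CalibrationMask(data=df)


def _draw(rng, spec, log: bool = False) -> float:
    if np.isscalar(spec):
        return float(spec)
    lo, hi = spec
    if log:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def generate_ground_truth_profile(
    n_residues: int = 170,
    architecture: list[Segment] | None = None,
    seed: int = 0,
    noise_level: float = 0.02,
    gel_model: TumblingExchangeModel | None = None,
    constants: SpinSystemConstants | None = None,
) -> GroundTruthProfile:
    """Draw a per-residue ground-truth motional profile.

    Deterministic given ``seed``; the calibration-mask invariant (flagged
    residues rigid apart from fast librations, S2_fast in [0.82, 0.88]) holds
    for every generated profile because only interior helix/sheet residues
    are flagged.
    """
    if n_residues < 20:
        raise GnasrError("need at least 20 residues")
    architecture = architecture or kras_like_architecture(n_residues)
    _validate_architecture(architecture, n_residues)
    gel_model = gel_model or TumblingExchangeModel()
    constants = constants or SpinSystemConstants()
    rows = []
    for seg in architecture:
        params = {**KIND_DEFAULTS[seg.kind], **seg.params}
        for residue in range(seg.start, seg.end + 1):
            rng = np.random.default_rng([seed, residue])
            s2f = _draw(rng, params.get("S2_fast", (0.82, 0.88)))
            tauf = _draw(rng, params.get("tau_fast", (20e-12, 80e-12)))
            s2s = _draw(rng, params.get("S2_slow", 1.0))
            taus = _draw(rng, params.get("tau_slow", 0.0), log="tau_slow" in params)
            rex = _draw(rng, params.get("Rex", 0.0))
            if seg.kind == "terminus":
                # ramp S2_fast from a loop-like value at the inner edge down
                # to TERMINUS_FLOOR at the chain end
                span = max(seg.end - seg.start, 1)
                if seg.start == 1:  # N-terminus: end of chain is residue 1
                    frac = (seg.end - residue) / span
                else:
                    frac = (residue - seg.start) / span
                s2f = 0.7 + (TERMINUS_FLOOR - 0.7) * frac
            interior = seg.start + 2 <= residue <= seg.end - 2
            in_cal = seg.kind in ("helix", "sheet") and interior
            rows.append(
                {
                    "residue": residue,
                    "kind": seg.kind,
                    "ss_class": SS_CLASS.get(seg.kind, "L"),
                    "in_calibration": in_cal,
                    "S2_fast": s2f,
                    "tau_fast": tauf,
                    "S2_slow": s2s,
                    "tau_slow": taus,
                    "Rex": rex,
                }
            )
    data = pd.DataFrame(rows).set_index("residue").sort_index()
    data["S2_total"] = data["S2_fast"] * data["S2_slow"]
    if int(data["in_calibration"].sum()) < 3:
        raise GnasrError("architecture yields fewer than 3 calibration residues")
    return GroundTruthProfile(
        data=data,
        gel_model=gel_model,
        constants=constants,
        noise_level=noise_level,
        seed=seed,
    )


def simulate_rate_tables(
    profile: GroundTruthProfile, include_eta: bool = True
) -> tuple[RateTable, RateTable, pd.DataFrame]:
    """Forward-simulate paired free/gel rate tables from a ground-truth profile.

    Noise-free rates come from the package's relaxation and exchange models;
    Gaussian relative noise of size ``noise_level`` is then applied and the
    error columns are set to ``noise_level * rate``.  Returns (free, gel,
    truth) where truth carries the per-residue ground-truth parameters and
    the noise-free rates.
    """
    k = profile.constants
    model = profile.gel_model
    free_rows, gel_rows, truth_rows = [], [], []
    for residue in profile.data.index:
        motion = profile.motion(residue)
        f = free_rates(motion, model, k)
        g = gel_rates(motion, model, k)
        rng = np.random.default_rng([profile.seed, residue, 1])
        z = rng.standard_normal(6)
        nl = profile.noise_level
        fr = {
            "residue": residue,
            "R1": f.R1 * (1 + nl * z[0]),
            "R1_err": nl * f.R1,
            "R2": f.R2 * (1 + nl * z[1]),
            "R2_err": nl * f.R2,
        }
        gr = {
            "residue": residue,
            "R1": g.R1 * (1 + nl * z[3]),
            "R1_err": nl * g.R1,
            "R2": g.R2 * (1 + nl * z[4]),
            "R2_err": nl * g.R2,
        }
        if include_eta:
            fr["eta_xy"] = f.eta_xy * (1 + nl * z[2])
            fr["eta_err"] = nl * f.eta_xy
            gr["eta_xy"] = g.eta_xy * (1 + nl * z[5])
            gr["eta_err"] = nl * g.eta_xy
        free_rows.append(fr)
        gel_rows.append(gr)
        truth_rows.append(
            {
                "residue": residue,
                "R1_free": f.R1,
                "R2_free": f.R2,
                "eta_free": f.eta_xy,
                "R1_gel": g.R1,
                "R2_gel": g.R2,
                "eta_gel": g.eta_xy,
            }
        )
    cols = ["R1", "R1_err", "R2", "R2_err"] + (["eta_xy", "eta_err"] if include_eta else [])
    free = RateTable("free", pd.DataFrame(free_rows).set_index("residue")[cols])
    gel = RateTable("gel", pd.DataFrame(gel_rows).set_index("residue")[cols])
    truth = profile.data.join(pd.DataFrame(truth_rows).set_index("residue"))
    return free, gel, truth


def write_fixture_set(
    out_dir, profile: GroundTruthProfile, include_eta: bool = True
) -> dict[str, Path]:
    """Write free.tsv / gel.tsv / mask.tsv / truth.tsv / config.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    free, gel, truth = simulate_rate_tables(profile, include_eta=include_eta)
    paths = {
        "free": out_dir / "free.tsv",
        "gel": out_dir / "gel.tsv",
        "mask": out_dir / "mask.tsv",
        "truth": out_dir / "truth.tsv",
        "config": out_dir / "config.yaml",
    }
    write_rate_table(free, paths["free"])
    write_rate_table(gel, paths["gel"])
    write_mask(profile.mask, paths["mask"])
    truth.to_csv(paths["truth"], sep="\t", float_format="%.6g")
    RunConfig(
        field_mhz=profile.constants.proton_larmor_mhz,
        noise_level=profile.noise_level,
        tau_ref=profile.gel_model.tau_ref,
        tau_free_gel=profile.gel_model.tau_free_gel,
        p_b=profile.gel_model.p_b,
        k_ex=profile.gel_model.k_ex,
        seed=profile.seed,
    ).to_yaml(paths["config"])
    return paths
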