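"""Rate-table containers and the plain-text formats they travel in.

All on-disk formats are tab-separated text with ``#`` comment lines:

rate table
    columns ``residue  R1  R1_err  R2  R2_err  [eta_xy  eta_err]``; the
    condition ("free" or "gel") may be carried in a ``# condition:`` header.
calibration mask
    columns ``residue  ss_class  in_calibration`` (0/1).
config
    YAML mapping of :class:`RunConfig` fields.

Numbers are written with 6 significant digits, which round-trips all
quantities well below experimental precision.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

logger = logging.getLogger("gnasr")

__all__ = [
    "RateTable",
    "DeltaProfile",
    "OrderParameterProfile",
    "CalibrationMask",
    "RunConfig",
    "read_rate_table",
    "write_rate_table",
    "read_mask",
    "write_mask",
]

RATE_COLUMNS = ["R1", "R1_err", "R2", "R2_err"]
ETA_COLUMNS = ["eta_xy", "eta_err"]
SS_CLASSES = {"H", "E", "L"}


@dataclass
class RateTable:
    """Per-residue measured or simulated rates under one condition."""

    condition: str  # "free" | "gel"
    data: pd.DataFrame  # index: residue id; columns RATE_COLUMNS [+ ETA_COLUMNS]

    def __post_init__(self) -> None:
        if self.condition not in {"free", "gel"}:
            raise ValueError(f"condition must be 'free' or 'gel', got {self.condition!r}")
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate residue ids: {dupes}")
        missing = [c for c in RATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"rate table missing columns {missing}")
        vals = self.data[RATE_COLUMNS + ([c for c in ETA_COLUMNS if c in self.data.columns])]
        if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
            raise FormatError("rates and uncertainties must be finite")
        for c in ("R1_err", "R2_err", "eta_err"):
            if c in self.data.columns and (self.data[c] < 0).any():
                raise FormatError(f"negative uncertainties in column {c}")

    @property
    def has_eta(self) -> bool:
        return all(c in self.data.columns for c in ETA_COLUMNS)

    @property
    def residues(self) -> pd.Index:
        return self.data.index


@dataclass
class DeltaProfile:
    """Gel-minus-free differences with quadrature-propagated uncertainties."""

    data: pd.DataFrame  # delta_R1/err, delta_R2/err [, delta_eta/err]
    unmatched_free: list = field(default_factory=list)
    unmatched_gel: list = field(default_factory=list)

    @property
    def has_eta(self) -> bool:
        return "delta_eta" in self.data.columns


@dataclass
class OrderParameterProfile:
    """Per-residue S2 values with provenance.

    ``source`` is one of gNASR, eta-gNASR, MF or NASR-reference;
    ``calibration_factor_d`` (s per unit rate) is set for calibrated profiles
    and None for model-free ones.
    """

    source: str
    data: pd.DataFrame  # index residue; columns S2, S2_err [, tau_int, chi2, model_flag]
    calibration_factor_d: float | None = None
    tau_P_used: float | None = None

    @property
    def s2(self) -> pd.Series:
        return self.data["S2"]


@dataclass
class CalibrationMask:
    """Residues anchoring the S2 calibration (stable secondary structure)."""

    data: pd.DataFrame  # index residue; columns ss_class, in_calibration (bool)

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise FormatError("duplicate residue ids in mask")
        if "in_calibration" not in self.data.columns:
            raise FormatError("mask missing in_calibration column")
        self.data["in_calibration"] = self.data["in_calibration"].astype(bool)
        if int(self.data["in_calibration"].sum()) < 3:
            raise FormatError("calibration mask must flag at least 3 residues")

    @property
    def calibration_residues(self) -> pd.Index:
        return self.data.index[self.data["in_calibration"]]


@dataclass
class RunConfig:
    """Experiment-level constants and pipeline defaults."""

    field_mhz: float = 850.0
    target_s2: float = 0.85
    noise_level: float = 0.02
    tau_ref: float = 10e-9
    tau_free_gel: float = 16e-9
    p_b: float = 0.0025
    k_ex: float = 5e5
    chi2_max: float = 10.0
    seed: int = 0
    # recorded metadata only; spinlock enters r2_from_r1rho, nothing else
    spinlock_hz: float = 2000.0
    recovery_delay_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.field_mhz > 0:
            raise ValueError("field_mhz must be > 0")
        if not 0.0 < self.target_s2 <= 1.0:
            raise ValueError("target_s2 must lie in (0, 1]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# TSV readers/writers


def _parse_lines(path):
    """Yield (lineno, fields) for data lines; collect '# key: value' metadata."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip().lower()] = value.strip()
                continue
            rows.append((lineno, stripped.split("\t")))
    return meta, rows


def read_rate_table(path, condition: str | None = None) -> RateTable:
    """Read a rate-table TSV.

    The condition may come from the ``# condition:`` header or the argument;
    giving both inconsistently is an error.  Missing eta columns simply leave
    the eta channel absent.
    """
    meta, rows = _parse_lines(path)
    header_cond = meta.get("condition")
    if header_cond and condition and header_cond != condition:
        raise FormatError(
            f"{path}: condition {condition!r} (argument) conflicts with "
            f"{header_cond!r} (file header)"
        )
    cond = condition or header_cond
    if cond is None:
        raise FormatError(f"{path}: no condition given (argument or '# condition:' header)")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    lineno0, header = rows[0]
    expected = ["residue"] + RATE_COLUMNS
    if header[: len(expected)] != expected:
        raise FormatError(
            f"{path}:{lineno0}: header must start with {expected}, got {header}"
        )
    with_eta = header[len(expected) :][:2] == ETA_COLUMNS
    ncol = len(expected) + (2 if with_eta else 0)
    records = []
    for lineno, fields in rows[1:]:
        if len(fields) < ncol:
            raise FormatError(f"{path}:{lineno}: expected {ncol} columns, got {len(fields)}")
        try:
            residue = int(fields[0])
            values = [float(v) for v in fields[1:ncol]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed number ({exc})") from None
        records.append([residue] + values)
    if not records:
        raise FormatError(f"{path}: no data rows")
    columns = expected + (ETA_COLUMNS if with_eta else [])
    df = pd.DataFrame(records, columns=columns).set_index("residue")
    return RateTable(condition=cond, data=df)


def write_rate_table(table: RateTable, path) -> None:
    cols = RATE_COLUMNS + (ETA_COLUMNS if table.has_eta else [])
    with open(path, "w") as fh:
        fh.write(f"# condition: {table.condition}\n")
        fh.write("residue\t" + "\t".join(cols) + "\n")
        for residue, rec in table.data.iterrows():
            fh.write(
                f"{int(residue)}\t" + "\t".join(f"{rec[c]:.6g}" for c in cols) + "\n"
            )


def read_mask(path) -> CalibrationMask:
    """Read a calibration-mask TSV (residue, ss_class, in_calibration 0/1)."""
    _, rows = _parse_lines(path)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    lineno0, header = rows[0]
    if header[:3] != ["residue", "ss_class", "in_calibration"]:
        raise FormatError(
            f"{path}:{lineno0}: header must be residue/ss_class/in_calibration"
        )
    records = []
    for lineno, fields in rows[1:]:
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        try:
            residue = int(fields[0])
            flag = int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed value ({exc})") from None
        if flag not in (0, 1):
            raise FormatError(f"{path}:{lineno}: in_calibration must be 0 or 1")
        ss = fields[1]
        if ss not in SS_CLASSES:
            logger.warning("%s:%d: unknown ss_class %r (stored verbatim)", path, lineno, ss)
        records.append((residue, ss, bool(flag)))
    df = pd.DataFrame(records, columns=["residue", "ss_class", "in_calibration"]).set_index(
        "residue"
    )
    return CalibrationMask(data=df)


def write_mask(mask: CalibrationMask, path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tss_class\tin_calibration\n")
        for residue, rec in mask.data.iterrows():
            fh.write(f"{int(residue)}\t{rec['ss_class']}\t{int(rec['in_calibration'])}\n")
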