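"""Tidy cohort CSV readers/writers, typed records and provenance headers.

The interchange format between all pipeline stages is one long-format CSV
with a row per subject x voxel and a fixed header.  Files written by the
package carry a provenance comment header (tool version, config hash, seed)
on lines starting with ``#``; readers skip such lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .voxels import ALL_VOXELS, GROUPS

COHORT_COLUMNS = [
    "subject_id", "group", "age", "fss", "edss", "lesion_volume_cm3",
    "voxel", "region", "f_gm", "f_wm", "f_csf",
    "naa", "naa_crlb_pct", "tcr", "tcr_crlb_pct",
]

_NUMERIC = [
    "age", "fss", "edss", "lesion_volume_cm3", "f_gm", "f_wm", "f_csf",
    "naa", "naa_crlb_pct", "tcr", "tcr_crlb_pct",
]


def _FLOAT_FMT(x: float) -> str:
    """17 significant digits: every IEEE double round-trips through the CSV."""
    return format(x, ".17g")


class SchemaError(ValueError):
    """Aggregated cohort-schema violations, each with its row number."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("cohort schema violations:\n  " + "\n  ".join(violations))


@dataclass
class VoxelMeasurement:
    """One spectroscopic voxel: tissue fractions and fitted amplitudes."""

    voxel: str
    region: str
    f_gm: float
    f_wm: float
    f_csf: float
    naa: float
    naa_crlb_pct: float
    tcr: float
    tcr_crlb_pct: float


@dataclass
class SubjectRecord:
    """Clinical covariates plus the subject's 16 voxel measurements."""

    subject_id: str
    group: str
    age: float
    fss: float
    edss: float
    lesion_volume_cm3: float
    voxels: list[VoxelMeasurement] = field(default_factory=list)


def config_hash(config) -> str:
    """Short stable digest of a pydantic config, for provenance headers."""
    payload = config.model_dump_json() if hasattr(config, "model_dump_json") else json.dumps(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(seed: int, cfg_hash: str = "") -> str:
    lines = [f"# ponsmrsi {__version__}", f"# seed={seed} config_hash={cfg_hash}"]
    return "\n".join(lines) + "\n"


def write_cohort(cohort: pd.DataFrame, path, seed: int = 0, cfg_hash: str = "") -> Path:
    """Write the tidy cohort CSV with a provenance header."""
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError([f"missing columns: {', '.join(missing)}"])
    extra = [c for c in cohort.columns if c not in COHORT_COLUMNS]
    ordered = cohort[COHORT_COLUMNS + extra]
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, cfg_hash))
        ordered.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a tidy cohort CSV; all violations reported at once."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str}, float_precision="round_trip")
    violations: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing columns: {', '.join(missing)}"])

    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            violations.append(f"row {i + 2}: non-numeric {col}={df.loc[i, col]!r}")
        df[col] = coerced

    bad_vox = df.index[~df["voxel"].isin(ALL_VOXELS)]
    for i in bad_vox:
        violations.append(f"row {i + 2}: invalid voxel label {df.loc[i, 'voxel']!r}")
    bad_grp = df.index[~df["group"].isin(GROUPS)]
    for i in bad_grp:
        violations.append(f"row {i + 2}: invalid group label {df.loc[i, 'group']!r}")

    dupes = df.duplicated(subset=["subject_id", "voxel"], keep=False)
    if dupes.any():
        for (sid, vox), sub in df[dupes].groupby(["subject_id", "voxel"]):
            rows = ", ".join(str(i + 2) for i in sub.index)
            violations.append(f"duplicate subject x voxel {sid}/{vox} at rows {rows}")

    if violations:
        raise SchemaError(violations)
    return df


def records_from_frame(cohort: pd.DataFrame) -> list[SubjectRecord]:
    """Group the tidy frame into typed per-subject records."""
    records = []
    for sid, sub in cohort.groupby("subject_id", sort=False):
        first = sub.iloc[0]
        rec = SubjectRecord(
            subject_id=str(sid),
            group=str(first["group"]),
            age=float(first["age"]),
            fss=float(first["fss"]),
            edss=float(first["edss"]),
            lesion_volume_cm3=float(first["lesion_volume_cm3"]),
            voxels=[
                VoxelMeasurement(
                    voxel=str(r["voxel"]), region=str(r["region"]),
                    f_gm=float(r["f_gm"]), f_wm=float(r["f_wm"]), f_csf=float(r["f_csf"]),
                    naa=float(r["naa"]), naa_crlb_pct=float(r["naa_crlb_pct"]),
                    tcr=float(r["tcr"]), tcr_crlb_pct=float(r["tcr_crlb_pct"]),
                )
                for _, r in sub.iterrows()
            ],
        )
        records.append(rec)
    return records


def write_table(df: pd.DataFrame, path, seed: int = 0, cfg_hash: str = "") -> Path:
    """Write any intermediate table with the provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, cfg_hash))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#", float_precision="round_trip")


def write_json(payload: dict, path, seed: int = 0, cfg_hash: str = "") -> Path:
    path = Path(path)
    payload = {"provenance": {"tool": f"ponsmrsi {__version__}", "seed": seed,
                              "config_hash": cfg_hash}, **payload}
    path.write_text(json.dumps(payload, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
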