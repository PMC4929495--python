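"""Diffractogram and cohort-metadata I/O.

Diffractograms travel as two-column ASCII ``.xy`` files (2-theta in degrees,
intensity in counts; whitespace or comma delimited; ``#`` comments).  Cohort
metadata travels in a separate CSV keyed by sample_id with columns
``sample_id,patient_id,group,sex,age,file``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Diffractogram",
    "CohortTable",
    "GridError",
    "read_xy",
    "write_xy",
    "read_metadata",
    "write_metadata",
]

GROUPS = ("fracture", "non_fracture", "unknown")
SEXES = ("male", "female", "unknown")

#: tolerance on grid uniformity, degrees
GRID_TOL = 1e-9

METADATA_COLUMNS = ["sample_id", "patient_id", "group", "sex", "age", "file"]


class GridError(ValueError):
    """Raised when a 2-theta grid is non-increasing or non-uniform."""


@dataclass
class Diffractogram:
    """One sample's scatter pattern: intensity versus 2-theta on a uniform grid."""

    two_theta: np.ndarray
    intensity: np.ndarray
    sample_id: str = "unknown"
    patient_id: str = "unknown"
    group: str = "unknown"
    sex: str = "unknown"
    #: true displacement offset in degrees, set by the simulator (provenance
    #: for generator/corrector consistency checks); None for measured data
    offset: float | None = None

    def __post_init__(self):
        self.two_theta = np.asarray(self.two_theta, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.two_theta.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("two_theta and intensity must be 1-D")
        if len(self.two_theta) != len(self.intensity):
            raise ValueError("two_theta and intensity lengths differ")
        if len(self.two_theta) < 2:
            raise ValueError("a diffractogram needs at least two points")
        diffs = np.diff(self.two_theta)
        if np.any(diffs <= 0):
            raise GridError("two_theta must be strictly increasing")
        step = diffs[0]
        if np.max(np.abs(diffs - step)) >= GRID_TOL:
            raise GridError("two_theta grid is not uniform")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")

    @property
    def step(self) -> float:
        """Grid spacing in degrees."""
        return float(self.two_theta[1] - self.two_theta[0])

    def with_intensity(self, intensity: np.ndarray) -> "Diffractogram":
        """Copy with a new intensity vector on the same grid and metadata."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class CohortTable:
    """Validated sample metadata for a cohort."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        missing = [c for c in METADATA_COLUMNS[:5] if c not in t.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if len(t) == 0:
            raise ValueError("no samples in metadata table")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id values: {dups}")
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        labelled = t[t["group"] != "unknown"]
        if labelled["patient_id"].isin(["", "unknown"]).any():
            raise ValueError("labelled samples must carry a patient_id")
        per_patient = labelled.groupby("patient_id")["group"].nunique()
        mixed = per_patient[per_patient > 1].index.tolist()
        if mixed:
            raise ValueError(f"patient_id in both groups: {mixed}")

    def __len__(self) -> int:
        return len(self.table)

    def counts(self) -> dict:
        """Sample and patient counts per group, and sample counts per (group, sex)."""
        t = self.table
        out = {}
        for g in ("fracture", "non_fracture"):
            sub = t[t["group"] == g]
            out[g] = {
                "samples": int(len(sub)),
                "patients": int(sub["patient_id"].nunique()),
                "by_sex": sub.groupby("sex").size().to_dict(),
            }
        return out


def read_xy(path, metadata: dict | None = None) -> Diffractogram:
    """Read a two-column ASCII diffractogram.

    Columns may be whitespace- or comma-delimited; lines starting with ``#``
    are comments.  ``metadata`` fills the sample fields; absent fields default
    to ``"unknown"``.
    """
    path = Path(path)
    tt, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                tt.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    meta = metadata or {}
    return Diffractogram(
        two_theta=np.array(tt),
        intensity=np.array(inten),
        sample_id=meta.get("sample_id", path.stem),
        patient_id=meta.get("patient_id", "unknown"),
        group=meta.get("group", "unknown"),
        sex=meta.get("sex", "unknown"),
    )


def write_xy(d: Diffractogram, path) -> None:
    """Write a diffractogram as two-column ASCII, re-readable by :func:`read_xy`."""
    buf = _io.StringIO()
    buf.write(f"# sample_id: {d.sample_id}\n")
    for t, y in zip(d.two_theta, d.intensity):
        buf.write(f"{t:.6f} {y:.6f}\n")
    Path(path).write_text(buf.getvalue())


def read_metadata(path) -> CohortTable:
    """Read and validate the cohort metadata CSV."""
    t = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    return CohortTable(t)


def write_metadata(table: CohortTable, path) -> None:
    table.table.to_csv(path, index=False)


def write_cohort(cohort: list[Diffractogram], table: CohortTable, out_dir) -> None:
    """Write one .xy file per sample plus ``metadata.csv`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = table.table.copy()
    files = []
    by_id = {d.sample_id: d for d in cohort}
    for sid in t["sample_id"]:
        fname = f"{sid}.xy"
        write_xy(by_id[sid], out_dir / fname)
        files.append(fname)
    t["file"] = files
    t.to_csv(out_dir / "metadata.csv", index=False)


def read_cohort(directory) -> tuple[list[Diffractogram], CohortTable]:
    """Read ``metadata.csv`` plus every referenced .xy file from a directory."""
    directory = Path(directory)
    table = read_metadata(directory / "metadata.csv")
    cohort = []
    for row in table.table.itertuples(index=False):
        meta = {
            "sample_id": row.sample_id,
            "patient_id": row.patient_id,
            "group": row.group,
            "sex": row.sex,
        }
        cohort.append(read_xy(directory / row.file, metadata=meta))
    return cohort, table
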