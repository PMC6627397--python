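"""Data model and portable I/O for GC-IMS chromatograms and cohorts.

A GC-IMS measurement is a 2-D intensity map: rows follow the gas-chromatography
retention axis (seconds), columns the ion-mobility drift axis (milliseconds).
Vendor formats are proprietary, so this package defines an open on-disk layout:

* ``<sample>.csv``   — the intensity matrix, plain numeric CSV, no header,
  rows = retention bins, columns = drift bins;
* ``<sample>.json``  — a sidecar carrying ``sample_id``, ``retention_axis``,
  ``drift_axis`` and ``units``;
* ``manifest.json``  — the cohort manifest listing, per sample, the group
  label, covariates and the two file paths (relative to the manifest).

Values are written with 9 significant digits, which exceeds the dynamic range
of the detector, so a write→read round trip is the identity for all practical
purposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "SampleRecord",
    "Cohort",
    "FormatError",
    "read_chromatogram",
    "write_chromatogram",
    "read_cohort",
    "write_cohort",
]

#: Covariate keys recognised by the cohort statistics module.
COVARIATE_KEYS = (
    "age",
    "sex",
    "bmi",
    "bristol_stool_score",
    "smoking",
    "ppi",
    "antibiotics",
    "immunosuppressants",
)


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the portable format."""


@dataclass
class Chromatogram:
    """A single GC-IMS intensity map with its physical axes.

    Parameters
    ----------
    sample_id:
        Opaque sample identifier.
    intensity:
        ``(n_ret, n_drift)`` matrix in arbitrary detector units.
    retention_axis:
        Strictly increasing GC retention times, seconds, length ``n_ret``.
    drift_axis:
        Strictly increasing IMS drift times, milliseconds, length ``n_drift``.
    meta:
        Free-form provenance (e.g. realignment shifts); not part of equality.
    """

    sample_id: str
    intensity: np.ndarray
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.retention_axis = np.asarray(self.retention_axis, dtype=float)
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        if self.intensity.ndim != 2:
            raise FormatError("intensity must be a 2-D matrix")
        n_ret, n_drift = self.intensity.shape
        if self.retention_axis.shape != (n_ret,):
            raise FormatError(
                f"retention axis length {self.retention_axis.size} does not "
                f"match matrix height {n_ret}"
            )
        if self.drift_axis.shape != (n_drift,):
            raise FormatError(
                f"drift axis length {self.drift_axis.size} does not match "
                f"matrix width {n_drift}"
            )
        for name, ax in (("retention", self.retention_axis),
                         ("drift", self.drift_axis)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise FormatError(f"{name} axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("intensity contains non-finite values")

    @property
    def n_ret(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_drift(self) -> int:
        return self.intensity.shape[1]

    def copy(self) -> "Chromatogram":
        return Chromatogram(
            sample_id=self.sample_id,
            intensity=self.intensity.copy(),
            retention_axis=self.retention_axis.copy(),
            drift_axis=self.drift_axis.copy(),
            meta=dict(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromatogram):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.intensity.shape == other.intensity.shape
            and np.array_equal(self.intensity, other.intensity)
            and np.array_equal(self.retention_axis, other.retention_axis)
            and np.array_equal(self.drift_axis, other.drift_axis)
        )


@dataclass
class SampleRecord:
    """Group label and optional clinical covariates for one sample."""

    sample_id: str
    group: str
    covariates: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """Sample records joined to their chromatograms.

    Invariant: exactly one chromatogram per record.  Identical axes across
    samples are *not* required at load time; they are enforced by
    :func:`gcimsvoc.preprocess.to_feature_matrix`.
    """

    records: list
    chromatograms: dict

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample id(s): {dupes}")
        missing = [i for i in ids if i not in self.chromatograms]
        if missing:
            raise FormatError(f"missing chromatogram(s) for: {missing}")
        extra = [i for i in self.chromatograms if i not in set(ids)]
        if extra:
            raise FormatError(f"chromatogram(s) without record: {extra}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list:
        return [r.sample_id for r in self.records]

    @property
    def groups(self) -> list:
        return [r.group for r in self.records]

    def subset(self, groups) -> "Cohort":
        """Restrict to samples whose group is in ``groups`` (order kept)."""
        wanted = set(groups)
        recs = [r for r in self.records if r.group in wanted]
        if not recs:
            raise ValueError(f"no samples in groups {sorted(wanted)}")
        chroms = {r.sample_id: self.chromatograms[r.sample_id] for r in recs}
        return Cohort(records=recs, chromatograms=chroms)

    def map_chromatograms(self, fn) -> "Cohort":
        """Return a new cohort with ``fn`` applied to every chromatogram."""
        return Cohort(
            records=list(self.records),
            chromatograms={sid: fn(c) for sid, c in self.chromatograms.items()},
        )


# --------------------------------------------------------------------------
# chromatogram files

def write_chromatogram(chrom: Chromatogram, matrix_path, sidecar_path) -> None:
    """Write a chromatogram as CSV matrix + JSON sidecar (9 sig. digits)."""
    matrix_path, sidecar_path = Path(matrix_path), Path(sidecar_path)
    np.savetxt(matrix_path, chrom.intensity, delimiter=",", fmt="%.9g")
    sidecar = {
        "sample_id": chrom.sample_id,
        "retention_axis": [float(f"{v:.9g}") for v in chrom.retention_axis],
        "drift_axis": [float(f"{v:.9g}") for v in chrom.drift_axis],
        "units": {"retention": "s", "drift": "ms", "intensity": "arbitrary"},
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))


def read_chromatogram(matrix_path, sidecar_path) -> Chromatogram:
    """Read a chromatogram written by :func:`write_chromatogram`.

    Raises
    ------
    FormatError
        On a dimension mismatch between matrix and axes (names both sizes)
        or a non-numeric cell (names row and column).
    """
    matrix_path, sidecar_path = Path(matrix_path), Path(sidecar_path)
    raw = pd.read_csv(matrix_path, header=None, dtype=str)
    try:
        matrix = raw.to_numpy(dtype=float)
    except ValueError:
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise FormatError(
            f"non-numeric cell {raw.iat[r, c]!r} at row {r}, column {c} "
            f"in {matrix_path}"
        ) from None
    sidecar = json.loads(sidecar_path.read_text())
    return Chromatogram(
        sample_id=sidecar["sample_id"],
        intensity=matrix,
        retention_axis=np.asarray(sidecar["retention_axis"], dtype=float),
        drift_axis=np.asarray(sidecar["drift_axis"], dtype=float),
    )


# --------------------------------------------------------------------------
# cohort manifest

def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort to ``out_dir``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = []
    for rec in cohort.records:
        chrom = cohort.chromatograms[rec.sample_id]
        matrix = f"{rec.sample_id}.csv"
        sidecar = f"{rec.sample_id}.json"
        write_chromatogram(chrom, out_dir / matrix, out_dir / sidecar)
        samples.append({
            "sample_id": rec.sample_id,
            "group": rec.group,
            "covariates": rec.covariates,
            "matrix": matrix,
            "sidecar": sidecar,
        })
    manifest = {
        "groups": sorted({r.group for r in cohort.records}),
        "samples": samples,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    records, chroms = [], {}
    for entry in manifest["samples"]:
        sid = entry["sample_id"]
        records.append(SampleRecord(
            sample_id=sid,
            group=entry["group"],
            covariates=dict(entry.get("covariates", {})),
        ))
        matrix = base / entry["matrix"]
        sidecar = base / entry["sidecar"]
        if not matrix.exists():
            raise IOError(f"chromatogram matrix missing for sample {sid!r}: "
                          f"{matrix}")
        if not sidecar.exists():
            raise IOError(f"sidecar missing for sample {sid!r}: {sidecar}")
        chroms[sid] = read_chromatogram(matrix, sidecar)
    return Cohort(records=records, chromatograms=chroms)
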