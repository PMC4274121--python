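"""NIfTI and cohort-table I/O.

Images are NIfTI-1 (.nii / .nii.gz) read through nibabel; the voxel
volume in cm^3 is derived from the affine for downstream MTV/TLG.
Cohorts are TSV with required columns ``id``, ``time_months``,
``event`` and any number of numeric covariate columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

REPORT_SCHEMA_VERSION = 1


@dataclass
class Image:
    """Voxel data plus affine; spacing and voxel volume derive from the affine."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in cm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])) / 1000.0)


def read_image(path: str | Path) -> Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    img = nib.load(str(path))
    return Image(data=np.asarray(img.get_fdata()), affine=img.affine)


def write_image(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


REQUIRED_COHORT_COLS = ("id", "time_months", "event")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV; unknown columns are kept as covariates."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COHORT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate patient ids: {dup}")
    try:
        df["time_months"] = pd.to_numeric(df["time_months"])
    except (ValueError, TypeError) as exc:
        bad = df.loc[pd.to_numeric(df["time_months"], errors="coerce").isna(), "id"].tolist()
        raise ValueError(f"non-numeric time_months for ids {bad}") from exc
    if (df["time_months"] <= 0).any():
        bad = df.loc[df["time_months"] <= 0, "id"].tolist()
        raise ValueError(f"non-positive time_months for ids {bad}")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "id"].tolist()
        raise ValueError(f"event flag must be 0/1; offending ids {bad}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(results: dict, path: str | Path) -> None:
    """Versioned JSON report."""
    payload = {"schema_version": REPORT_SCHEMA_VERSION, "results": _jsonable(results)}
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
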