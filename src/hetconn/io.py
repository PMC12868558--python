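"""Readers and writers for the on-disk formats.

All tables are comma-separated text with header rows; derived results are
JSON; NIfTI-1 is the only binary standard (label volumes).  Cohort matrices
carry a sidecar JSON with the edge-map convention so no module has to assume
the edge ordering.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._utils import DataError
from .connectome import CohortMatrix, EdgeIndexMap, LabelVolume
from .synth import SubjectBold
from .transcriptomics import RegionProfileMatrix

__all__ = [
    "write_bold_dir", "read_bold_dir",
    "write_region_table", "read_region_table",
    "write_cohort", "read_cohort",
    "write_profiles", "read_profiles",
    "write_label_volume", "read_label_volume",
    "write_json", "read_json",
]

_META_COLS = ["subject_id", "group"]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=1))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_bold_dir(subjects: list[SubjectBold], path: str | Path) -> None:
    """One CSV per subject (regions as rows, timepoints as columns)."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        np.savetxt(p / f"{s.subject_id}.csv", s.values, delimiter=",")


def read_bold_dir(path: str | Path) -> list[SubjectBold]:
    p = Path(path)
    files = sorted(p.glob("*.csv"))
    if not files:
        raise DataError(f"no BOLD CSV files in {p}")
    return [SubjectBold(f.stem, np.loadtxt(f, delimiter=",", ndmin=2))
            for f in files]


def write_region_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_region_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["id", "name", "network", "x", "y", "z"]
    for col in required:
        if col not in df.columns:
            raise DataError(
                f"region table {path} is missing column '{col}'")
    return df


def write_cohort(cohort: CohortMatrix, path: str | Path) -> None:
    """Cohort CSV (metadata + edge columns) with a sidecar edge-map JSON."""
    p = Path(path)
    meta = pd.DataFrame({"subject_id": cohort.subject_ids,
                         "group": cohort.groups})
    if cohort.covariates is not None:
        meta = pd.concat([meta, cohort.covariates.reset_index(drop=True)],
                         axis=1)
    edges = pd.DataFrame(
        cohort.edges,
        columns=[f"edge_{i:06d}" for i in range(cohort.n_edges)])
    pd.concat([meta, edges], axis=1).to_csv(p, index=False)
    write_json({"n_regions": cohort.edge_map.n_regions,
                "ordering": "upper-triangle row-major, 0-based",
                "standardized": bool(cohort.standardized)},
               p.with_suffix(".edgemap.json"))


def read_cohort(path: str | Path) -> CohortMatrix:
    p = Path(path)
    df = pd.read_csv(p)
    sidecar = read_json(p.with_suffix(".edgemap.json"))
    edge_cols = [c for c in df.columns if c.startswith("edge_")]
    meta_cols = [c for c in df.columns if not c.startswith("edge_")]
    cov_cols = [c for c in meta_cols if c not in _META_COLS]
    return CohortMatrix(
        edges=df[edge_cols].to_numpy(float),
        subject_ids=df["subject_id"].astype(str).tolist(),
        groups=df["group"].to_numpy(),
        covariates=df[cov_cols] if cov_cols else None,
        edge_map=EdgeIndexMap(int(sidecar["n_regions"])),
        standardized=bool(sidecar.get("standardized", False)),
    )


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path)


def read_profiles(path: str | Path,
                  coordinates: pd.DataFrame | None = None
                  ) -> RegionProfileMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        raise DataError(f"profile table {path} contains missing values")
    return RegionProfileMatrix.from_frames(df, coordinates)


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.int32), affine)
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int64)
    vsize = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels, vsize)
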