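"""Connectivity construction and edge-space plumbing.

Per-subject functional connectivity (FC) is the Pearson correlation between
region time series.  All edge-space mathematics in the package runs on
vectorized upper triangles; :class:`EdgeIndexMap` pins the single canonical
ordering (0-based, row-major upper triangle) so modules never assume it
implicitly.  The module also holds the cohort container used by the PLS
stages, covariate regression, and the atlas label-merge utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import DataError, DimensionError, check_finite

__all__ = [
    "EdgeIndexMap",
    "SubjectConnectome",
    "CohortMatrix",
    "LabelVolume",
    "compute_fc",
    "fisher_z",
    "vectorize_upper",
    "devectorize",
    "regress_covariates",
    "merge_label_volumes",
]


@dataclass(frozen=True)
class EdgeIndexMap:
    """Canonical bijection between edge index and region pair (i < j)."""

    n_regions: int

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column index arrays in row-major upper-triangle order."""
        return np.triu_indices(self.n_regions, k=1)

    def edge_index(self, i: int, j: int) -> int:
        if i == j or not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
            raise DimensionError(f"invalid region pair ({i}, {j})")
        if i > j:
            i, j = j, i
        # offset of row i plus position of j in that row
        return i * (2 * self.n_regions - i - 1) // 2 + (j - i - 1)


@dataclass
class SubjectConnectome:
    subject_id: str
    group: str
    covariates: dict
    edges: np.ndarray


@dataclass
class CohortMatrix:
    """Subjects x edges connectivity table with labels and covariates."""

    edges: np.ndarray              # (n_subjects, n_edges)
    subject_ids: list[str]
    groups: np.ndarray             # group label per subject
    covariates: pd.DataFrame | None
    edge_map: EdgeIndexMap
    standardized: bool = False
    zero_variance_edges: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_subjects(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def subset(self, mask: np.ndarray) -> "CohortMatrix":
        cov = self.covariates.iloc[mask].reset_index(drop=True) \
            if self.covariates is not None else None
        return replace(
            self,
            edges=self.edges[mask],
            subject_ids=[s for s, m in zip(self.subject_ids, mask) if m],
            groups=self.groups[mask],
            covariates=cov,
        )

    def standardize(self, ddof: int = 1) -> "CohortMatrix":
        """Z-score every edge column across subjects.

        Columns with zero variance are flagged and left at zero (after
        centering) rather than producing NaNs.
        """
        mu = self.edges.mean(axis=0)
        sd = self.edges.std(axis=0, ddof=ddof)
        zero = np.flatnonzero(sd == 0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        z = (self.edges - mu) / sd_safe
        return replace(self, edges=z, standardized=True,
                       zero_variance_edges=zero)


@dataclass
class LabelVolume:
    """Integer-labelled parcellation volume (0 = background)."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_table: dict[int, str] = field(default_factory=dict)

    def voxel_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels[self.labels > 0],
                                 return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def compute_fc(signal: np.ndarray) -> np.ndarray:
    """Pearson-correlation FC matrix of a region x time signal.

    Constant rows have undefined correlations; their entries are set to 0
    (diagonal kept at 1) and a warning is emitted.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[1] < 3:
        raise DimensionError("signal must be 2-D with at least 3 timepoints")
    check_finite(signal, "signal")
    sd = signal.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant region(s); their correlations "
            "are set to 0", stacklevel=2)
        safe = signal.copy()
        # substitute a dummy series to avoid divide-by-zero, then zero out
        safe[constant] = np.arange(signal.shape[1], dtype=float)
        fc = np.corrcoef(safe)
        fc[constant, :] = 0.0
        fc[:, constant] = 0.0
        np.fill_diagonal(fc, 1.0)
    else:
        fc = np.corrcoef(signal)
    return np.clip(fc, -1.0, 1.0)


def fisher_z(fc: np.ndarray, clip: float = 1e-7) -> np.ndarray:
    """Entrywise Fisher r-to-z transform; |r| clipped to 1 - clip, diag 0."""
    fc = np.asarray(fc, dtype=float)
    z = np.arctanh(np.clip(fc, -1.0 + clip, 1.0 - clip))
    np.fill_diagonal(z, 0.0)
    return z


def vectorize_upper(matrix: np.ndarray, edge_map: EdgeIndexMap) -> np.ndarray:
    matrix = np.asarray(matrix)
    if matrix.shape != (edge_map.n_regions, edge_map.n_regions):
        raise DimensionError(
            f"matrix shape {matrix.shape} does not match edge map with "
            f"{edge_map.n_regions} regions")
    iu, ju = edge_map.pairs
    return matrix[iu, ju].copy()


def devectorize(vector: np.ndarray, edge_map: EdgeIndexMap) -> np.ndarray:
    vector = np.asarray(vector)
    if vector.shape != (edge_map.n_edges,):
        raise DimensionError(
            f"vector length {vector.shape} does not match "
            f"{edge_map.n_edges} edges")
    out = np.zeros((edge_map.n_regions, edge_map.n_regions),
                   dtype=vector.dtype)
    iu, ju = edge_map.pairs
    out[iu, ju] = vector
    out[ju, iu] = vector
    return out


def _build_design(covariates: pd.DataFrame,
                  covariate_names: list[str]) -> np.ndarray:
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in covariate_names:
        if name not in covariates.columns:
            raise DataError(f"covariate '{name}' missing from covariate table")
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = pd.unique(col)
            if len(levels) < 2:
                warnings.warn(
                    f"covariate '{name}' has a single level; dropped",
                    stacklevel=3)
                continue
            dummies = pd.get_dummies(col, drop_first=True)
            for lev in dummies.columns:
                cols.append(dummies[lev].to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError(
            f"rank-deficient covariate design; columns: {names}")
    return X


def regress_covariates(cohort: CohortMatrix,
                       covariate_names: list[str]) -> CohortMatrix:
    """OLS-residualize every edge column on intercept + encoded covariates.

    The original column means are added back, so only covariate-explained
    variation is removed.  Categorical covariates (site, sex) are dummy-coded;
    single-level factors are dropped with a warning.  Applying the operation
    twice is a no-op up to floating point.
    """
    if cohort.covariates is None:
        raise DataError("cohort has no covariate table")
    X = _build_design(cohort.covariates, covariate_names)
    Y = cohort.edges
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid + Y.mean(axis=0, keepdims=True)
    return replace(cohort, edges=out)


def merge_label_volumes(volumes: list[LabelVolume],
                        min_voxels: int = 10) -> tuple[LabelVolume,
                                                       pd.DataFrame]:
    """Merge parcellation volumes into one unified labelling.

    The second and later volumes have their (nonzero) labels offset by the
    running maximum so labels stay unique; overlapping voxels keep the larger
    label value; labels covering fewer than ``min_voxels`` voxels are removed
    (set to background).  Returns the merged volume and a region table with
    final voxel counts.
    """
    if not volumes:
        raise DimensionError("need at least one volume")
    shape = volumes[0].labels.shape
    vsize = volumes[0].voxel_size
    for v in volumes[1:]:
        if v.labels.shape != shape:
            raise DimensionError("label volumes have mismatched shapes")
        if tuple(v.voxel_size) != tuple(vsize):
            raise DimensionError("label volumes have mismatched voxel sizes")

    merged = np.zeros(shape, dtype=np.int64)
    table: dict[int, str] = {}
    offset = 0
    for vol in volumes:
        lab = vol.labels.astype(np.int64)
        shifted = np.where(lab > 0, lab + offset, 0)
        merged = np.maximum(merged, shifted)
        for old, name in vol.label_table.items():
            table[old + offset] = name
        if shifted.max() > 0:
            offset = max(offset, int(shifted.max()))

    vals, counts = np.unique(merged[merged > 0], return_counts=True)
    small = vals[counts < min_voxels]
    if small.size:
        merged[np.isin(merged, small)] = 0

    vals, counts = np.unique(merged[merged > 0], return_counts=True)
    region_table = pd.DataFrame({
        "label": vals,
        "name": [table.get(int(v), f"region_{int(v)}") for v in vals],
        "voxel_count": counts,
    })
    return LabelVolume(merged, vsize, {int(v): table.get(int(v), f"region_{int(v)}")
                                       for v in vals}), region_table
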