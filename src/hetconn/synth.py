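"""Synthetic data generators for every pipeline input.

Each generator emulates the statistical structure a downstream stage assumes:

* :func:`gen_bold_cohort` — multi-subject BOLD matrices that are a low-rank
  shared component plus orthogonal subject-specific components plus Gaussian
  noise, the additive superposition model the factorization stage estimates.
* :func:`gen_cohort_fc` — subjects x edges cohort matrices with a planted
  group-separating direction and per-disorder deviation directions of
  prescribed pairwise cosine geometry, plus clinical scores coupled to the
  deviation scores at a target Spearman strength.
* :func:`gen_spatial_profiles` — spatially autocorrelated region x variable
  maps whose expected inter-region profile correlation decays exponentially
  with distance, A·exp(-d/scale) + B.
* :func:`gen_label_volumes` — integer parcellation volumes with known voxel
  counts, a deliberately tiny label, and optional overlaps for the atlas
  merge.

Determinism contract: one global integer seed fans out to fixed, named
substreams (see ``_utils.STREAM_TAGS``); identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import (DimensionError, GeometryError, ParameterError,
                     substream)
from .connectome import CohortMatrix, EdgeIndexMap, LabelVolume

__all__ = [
    "SubjectBold",
    "BoldGroundTruth",
    "CohortGroundTruth",
    "closed_deviation_geometry",
    "gen_bold_cohort",
    "gen_cohort_fc",
    "gen_spatial_profiles",
    "gen_label_volumes",
]


@dataclass
class SubjectBold:
    """One subject's standardized region x time signal matrix."""

    subject_id: str
    values: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class BoldGroundTruth:
    """Planted factors behind a synthetic BOLD cohort (pre-standardization)."""

    shared_basis: np.ndarray                   # regions x rank_shared
    specific_bases: list[np.ndarray]           # per subject, regions x rank_specific
    shared_coeffs: list[np.ndarray]            # per subject, time x rank_shared
    specific_coeffs: list[np.ndarray]          # per subject, time x rank_specific
    noise_sd: float
    raw_signals: list[np.ndarray]              # pre-standardization matrices


@dataclass
class CohortGroundTruth:
    planted_direction: np.ndarray
    deviation_directions: dict[str, np.ndarray]
    effect_size: float
    deviation_magnitudes: dict[str, float]
    clinical_coupling: float
    deviation_scores: dict[str, np.ndarray]    # realized per-subject scores


def _orthonormal(rng: np.random.Generator, n: int, r: int,
                 complement_of: np.ndarray | None = None) -> np.ndarray:
    """QR-orthonormalized Gaussian draw, optionally inside a complement."""
    if r == 0:
        return np.zeros((n, 0))
    g = rng.standard_normal((n, r))
    if complement_of is not None and complement_of.shape[1] > 0:
        g = g - complement_of @ (complement_of.T @ g)
    q, _ = np.linalg.qr(g)
    return q[:, :r]


def gen_bold_cohort(n_subjects: int, n_regions: int,
                    n_timepoints: int | list[int],
                    rank_shared: int, rank_specific: int,
                    noise_sd: float = 0.0, *,
                    noise_fraction: float | None = None,
                    specific_fraction: float = 0.01,
                    standardize: bool = True,
                    seed: int = 0) -> tuple[list[SubjectBold],
                                            BoldGroundTruth]:
    """Simulate a cohort of BOLD matrices with shared + specific structure.

    Each subject's raw matrix is ``U_g @ V_gi.T + U_li @ V_li.T + noise``
    with the specific basis drawn inside the orthogonal complement of the
    shared basis, so the orthogonality constraint of the factorization model
    holds exactly in truth.  By default the subject-specific part is scaled
    to ``specific_fraction`` of the shared-signal variance (the regime the
    method targets: individual components are minor modulations of a
    dominant shared signal).

    Parameters
    ----------
    noise_sd
        Absolute noise standard deviation; ignored if ``noise_fraction`` is
        given.
    noise_fraction
        If set, per-subject noise is rescaled so its empirical variance is
        exactly this fraction of the subject's signal variance.
    standardize
        Z-score each region row over time after noise injection (default).
        Disable to obtain the exact planted low-rank matrices.
    """
    tps = ([int(n_timepoints)] * n_subjects
           if np.isscalar(n_timepoints) else [int(t) for t in n_timepoints])
    if len(tps) != n_subjects:
        raise DimensionError("per-subject timepoint list length mismatch")
    if rank_shared + rank_specific >= min(n_regions, min(tps)):
        raise DimensionError(
            f"rank_shared + rank_specific = {rank_shared + rank_specific} "
            f"must be < min(n_regions, min timepoints) = "
            f"{min(n_regions, min(tps))}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")

    rng = substream(seed, "bold")
    U_g = _orthonormal(rng, n_regions, rank_shared)

    subjects, spec_bases, sh_coeffs, sp_coeffs, raws = [], [], [], [], []
    for i, m in enumerate(tps):
        V_g = rng.standard_normal((m, rank_shared))
        U_l = _orthonormal(rng, n_regions, rank_specific, complement_of=U_g)
        V_l = rng.standard_normal((m, rank_specific))
        shared_part = U_g @ V_g.T
        specific_part = U_l @ V_l.T
        if rank_specific > 0 and specific_part.any():
            target = specific_fraction * shared_part.var()
            scale = np.sqrt(target / specific_part.var())
            specific_part = specific_part * scale
            V_l = V_l * scale
        signal = shared_part + specific_part
        noise = rng.standard_normal((n_regions, m))
        if noise_fraction is not None:
            sd_i = np.sqrt(noise_fraction * signal.var() / noise.var())
        else:
            sd_i = noise_sd
        raw = signal + sd_i * noise
        raws.append(raw)
        if standardize:
            mu = raw.mean(axis=1, keepdims=True)
            sd = raw.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            vals = (raw - mu) / sd
        else:
            vals = raw
        subjects.append(SubjectBold(f"sub-{i:03d}", vals))
        spec_bases.append(U_l)
        sh_coeffs.append(V_g)
        sp_coeffs.append(V_l)

    truth = BoldGroundTruth(U_g, spec_bases, sh_coeffs, sp_coeffs,
                            float(noise_sd if noise_fraction is None
                                  else np.nan), raws)
    return subjects, truth


def _gram_directions(rng: np.random.Generator, n_edges: int,
                     gram: np.ndarray,
                     orthogonal_to: np.ndarray) -> np.ndarray:
    """Unit vectors with exact pairwise Gram matrix, all orthogonal to w."""
    gram = np.asarray(gram, dtype=float)
    k = gram.shape[0]
    if gram.shape != (k, k) or not np.allclose(gram, gram.T):
        raise GeometryError("deviation Gram matrix must be square symmetric")
    if not np.allclose(np.diag(gram), 1.0):
        raise GeometryError("deviation Gram matrix must have unit diagonal")
    evals, evecs = np.linalg.eigh(gram)
    if evals.min() < -1e-10:
        raise GeometryError(
            f"deviation Gram matrix is not positive semidefinite "
            f"(min eigenvalue {evals.min():.3g})")
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))
    # orthonormal frame in the complement of the planted direction
    Q = _orthonormal(rng, n_edges, k,
                     complement_of=orthogonal_to[:, None])
    # columns of D have Gram D.T D = L L.T = gram
    return Q @ L.T


def closed_deviation_geometry(pair_cosine: float, magnitude: float = 4.0,
                              n_per_disorder: tuple[int, int, int] =
                              (150, 150, 150)
                              ) -> tuple[np.ndarray, list[float]]:
    """Three-disorder deviation geometry the residual pipeline can recover.

    Deviation profiles estimated downstream are means of residuals of a
    column-centered patient cohort, so they always satisfy the weighted
    sum-to-zero constraint sum_g n_g * DSCD_g = 0.  An arbitrary planted
    Gram matrix is therefore not estimable: only geometries whose
    magnitude- and size-weighted direction sum vanishes survive centering
    unchanged.  This helper builds the closed three-disorder geometry in
    which the first two deviation directions have the requested pairwise
    cosine and the third is the (negatively scaled) weighted sum of the
    first two, returning the full unit-direction Gram matrix and the
    per-disorder magnitudes.
    """
    c = float(pair_cosine)
    if not -1.0 < c < 1.0:
        raise GeometryError("pair_cosine must be in (-1, 1)")
    n1, n2, n3 = n_per_disorder
    a, b = n1 * magnitude, n2 * magnitude
    s = np.sqrt(a * a + b * b + 2 * a * b * c)
    c13 = -(a + b * c) / s
    c23 = -(a * c + b) / s
    gram = np.array([[1.0, c, c13],
                     [c, 1.0, c23],
                     [c13, c23, 1.0]])
    return gram, [magnitude, magnitude, float(s / n3)]


def _calibrate_clinical(rng: np.random.Generator, scores: np.ndarray,
                        target_rho: float, tol: float = 0.03,
                        max_iter: int = 60) -> np.ndarray:
    """Noisy monotone transform of scores hitting a target Spearman rho.

    A fixed Gaussian noise draw is scaled by bisection until the realized
    Spearman correlation is within ``tol`` of the target.
    """
    base = np.exp(scores / max(scores.std(), 1e-12))  # monotone, nonlinear
    if target_rho >= 1.0:
        return base
    noise = rng.standard_normal(len(scores)) * base.std()

    def rho_at(lam: float) -> float:
        return stats.spearmanr(scores, base + lam * noise).statistic

    lo, hi = 0.0, 1.0
    while rho_at(hi) > target_rho and hi < 1e6:
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rho_at(mid)
        if abs(r - target_rho) <= tol:
            return base + mid * noise
        if r > target_rho:
            lo = mid
        else:
            hi = mid
    return base + 0.5 * (lo + hi) * noise


def gen_cohort_fc(n_per_group: dict[str, int], n_edges: int = 45,
                  effect_size: float = 0.8,
                  deviation_gram: np.ndarray | None = None,
                  deviation_magnitudes: dict[str, float] | None = None,
                  noise_sd: float = 1.0,
                  clinical_coupling: float = 0.5,
                  subject_magnitude_sd: float = 1.0,
                  hc_label: str = "HC",
                  seed: int = 0) -> tuple[CohortMatrix, pd.DataFrame,
                                          CohortGroundTruth]:
    """Simulate a subjects x edges cohort with planted latent geometry.

    Every subject's edge vector is ``baseline + patient_indicator *
    effect_size * w + c_i * d_g + noise`` where ``w`` is the planted
    group-separating direction, ``d_g`` the subject's disorder deviation
    direction (orthogonal to ``w``, pairwise cosines set by
    ``deviation_gram``), and ``c_i ~ N(magnitude_g, subject_magnitude_sd)``
    the subject's deviation strength.  Clinical scores are a noisy monotone
    transform of each patient's realized deviation score, calibrated to the
    requested Spearman coupling within +/-0.03.
    """
    groups = [g for g in n_per_group if n_per_group[g] > 0]
    disorders = [g for g in groups if g != hc_label]
    if hc_label not in groups or not disorders:
        raise GeometryError(
            "design needs a non-empty HC group and at least one disorder")

    rng = substream(seed, "cohort_fc")
    w = rng.standard_normal(n_edges)
    w /= np.linalg.norm(w)

    k = len(disorders)
    if deviation_gram is None:
        deviation_gram = np.eye(k)
    if deviation_magnitudes is None:
        deviation_magnitudes = {d: 4.0 for d in disorders}
    D = _gram_directions(rng, n_edges, np.asarray(deviation_gram), w)
    dev_dirs = {d: D[:, j] for j, d in enumerate(disorders)}

    baseline = rng.standard_normal(n_edges)
    rows, labels, subj_ids = [], [], []
    dev_scores: dict[str, list[float]] = {d: [] for d in disorders}
    sid = 0
    for g in groups:
        for _ in range(n_per_group[g]):
            x = baseline.copy()
            if g != hc_label:
                x = x + effect_size * w
                c = deviation_magnitudes[g] + \
                    subject_magnitude_sd * rng.standard_normal()
                x = x + c * dev_dirs[g]
            x = x + noise_sd * rng.standard_normal(n_edges)
            if g != hc_label:
                dev_scores[g].append(float((x - baseline) @ dev_dirs[g]))
            rows.append(x)
            labels.append(g)
            subj_ids.append(f"sub-{sid:04d}")
            sid += 1

    n_regions = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n_regions * (n_regions - 1) // 2 != n_edges:
        # edge count not triangular: fall back to a map that only records it
        n_regions = n_edges + 1  # degenerate but consistent length bookkeeping
    edge_map = EdgeIndexMap(n_regions)

    covariates = pd.DataFrame({
        "site": ["site1"] * len(rows),
        "sex": [("F" if i % 2 else "M") for i in range(len(rows))],
        "age": rng.uniform(8, 18, len(rows)),
    })
    cohort = CohortMatrix(np.array(rows), subj_ids, np.array(labels),
                          covariates, edge_map)

    crng = substream(seed, "clinical")
    clin_rows = []
    for d in disorders:
        s = np.asarray(dev_scores[d])
        vals = _calibrate_clinical(crng, s, clinical_coupling)
        ids = [sidv for sidv, lab in zip(subj_ids, labels) if lab == d]
        for i, v in zip(ids, vals):
            clin_rows.append({"subject_id": i, "group": d,
                              "clinical_score": float(v)})
    clinical = pd.DataFrame(clin_rows)

    truth = CohortGroundTruth(w, dev_dirs, float(effect_size),
                              {d: float(deviation_magnitudes[d])
                               for d in disorders},
                              float(clinical_coupling),
                              {d: np.asarray(v) for d, v in
                               dev_scores.items()})
    return cohort, clinical, truth


def gen_spatial_profiles(n_regions: int, n_variables: int,
                         box_size: float = 100.0,
                         decay_amplitude: float = 0.8,
                         decay_offset: float = 0.05,
                         decay_scale: float = 20.0,
                         noise_sd: float = 0.0,
                         seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spatially autocorrelated region x variable profile maps.

    Regions are placed uniformly in a cube of side ``box_size`` (mm).
    Profiles are built as ``K^{1/2} @ W`` with iid Gaussian ``W`` and kernel
    ``K_ij = amplitude * exp(-d_ij/scale) + offset`` (unit diagonal), so the
    expected inter-region profile correlation follows the exponential decay
    curve the annotation stage fits.  Optional white noise attenuates the
    realized correlations by 1/(1 + noise_sd^2) uniformly.

    Returns (profiles table indexed by region id, coordinates table with
    columns x, y, z).
    """
    if decay_scale <= 0:
        raise ParameterError("decay_scale must be > 0")
    if n_variables < 3:
        raise ParameterError("need at least 3 variables")
    rng = substream(seed, "spatial")
    coords = rng.uniform(0, box_size, size=(n_regions, 3))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))

    K = decay_amplitude * np.exp(-dist / decay_scale) + decay_offset
    np.fill_diagonal(K, 1.0)
    evals, evecs = np.linalg.eigh(K)
    if evals.min() < -1e-8:
        raise ParameterError(
            f"decay kernel is not positive semidefinite (min eigenvalue "
            f"{evals.min():.3g}); reduce decay_amplitude + decay_offset "
            "below 1 or increase decay_scale")
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    X = root @ rng.standard_normal((n_regions, n_variables))
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)

    region_ids = [f"roi-{i:03d}" for i in range(n_regions)]
    profiles = pd.DataFrame(
        X, index=pd.Index(region_ids, name="region_id"),
        columns=[f"var_{j:04d}" for j in range(n_variables)])
    coord_tab = pd.DataFrame(coords, columns=["x", "y", "z"],
                             index=pd.Index(region_ids, name="region_id"))
    return profiles, coord_tab


def gen_label_volumes(shape: tuple[int, int, int] = (24, 24, 24),
                      regions_per_volume: list[int] = (6, 5),
                      seed: int = 0,
                      small_label_voxels: int = 9,
                      n_overlap_voxels: int = 0
                      ) -> list[LabelVolume]:
    """Integer label volumes with known voxel counts for merge testing.

    Labels are placed in disjoint grid cells across volumes (so volumes do
    not overlap unless requested).  The last label of the first volume gets
    exactly ``small_label_voxels`` voxels to exercise the small-region
    filter.  If ``n_overlap_voxels`` > 0, the first label of the second
    volume also claims that many voxels inside the first volume's first
    label.
    """
    rng = substream(seed, "labels")
    total_regions = int(np.sum(regions_per_volume))
    cell = 6
    grid = [s // cell for s in shape]
    n_cells = int(np.prod(grid))
    if total_regions > n_cells:
        raise DimensionError(
            f"{total_regions} regions do not fit {n_cells} grid cells")
    cell_order = rng.permutation(n_cells)[:total_regions]

    volumes = []
    label = 0
    cell_ptr = 0
    first_label_voxels: list[tuple[int, ...]] | None = None
    for vi, n_reg in enumerate(regions_per_volume):
        arr = np.zeros(shape, dtype=np.int32)
        table = {}
        for ri in range(n_reg):
            label += 1
            c = int(cell_order[cell_ptr]); cell_ptr += 1
            cz, cy, cx = np.unravel_index(c, grid)
            z0, y0, x0 = cz * cell, cy * cell, cx * cell
            block = [(z0 + dz, y0 + dy, x0 + dx)
                     for dz in range(cell) for dy in range(cell)
                     for dx in range(cell)]
            is_small = (vi == 0 and ri == n_reg - 1)
            n_vox = small_label_voxels if is_small else \
                int(rng.integers(20, cell ** 3))
            chosen = [block[k] for k in
                      rng.permutation(len(block))[:n_vox]]
            for idx in chosen:
                arr[idx] = ri + 1
            table[ri + 1] = f"vol{vi}_region{ri + 1}"
            if vi == 0 and ri == 0:
                first_label_voxels = chosen
        if vi == 1 and n_overlap_voxels > 0 and first_label_voxels:
            for idx in first_label_voxels[:n_overlap_voxels]:
                arr[idx] = 1
        volumes.append(LabelVolume(arr, (1.0, 1.0, 1.0), table))
        label = 0
    return volumes
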