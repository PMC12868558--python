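"""Shared transdiagnostic pattern and disorder-specific deviations.

The shared transdiagnostic abnormal connectivity pattern (STACP) is the first
partial-least-squares weight vector in edge space separating pooled patients
from healthy controls.  With a single centered binary response the first PLS
direction has the closed form w proportional to X^T y — the covariance between
each edge and the diagnosis label — which is exactly the separation-maximizing
first component; no deflation is needed because only component 1 defines the
pattern.

Disorder-specific connectivity deviations (DSCDs) are obtained by projecting
each patient's (restandardized) edge vector onto the STACP, forming the
residual r_i = x_i - (x_i . w) w, and averaging residuals within each
disorder.  The geometry between DSCDs (pairwise cosine similarity) is the
substantive readout.  High-contribution edges are profiled by taking the top
fraction of |weights|, counting network pairs, summarizing subjects with the
first principal component over those edges, and associating it with clinical
scores by Spearman correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import DataError, DimensionError
from .connectome import CohortMatrix, EdgeIndexMap

__all__ = [
    "LatentDirection",
    "EdgePLS",
    "ProjectionResult",
    "DeviationProfile",
    "EdgeProfile",
    "fit_direction",
    "project_residualize",
    "compute_dscd",
    "cosine_similarity",
    "top_edges",
    "network_pair_counts",
    "edge_pc1_scores",
    "spearman_assoc",
]


@dataclass
class LatentDirection:
    """Unit edge-space weight vector of the first PLS component."""

    weights: np.ndarray
    explained_covariance: float
    training_meta: dict = field(default_factory=dict)


@dataclass
class ProjectionResult:
    subject_ids: list[str]
    scores: np.ndarray          # t_i = x_i . w
    residuals: np.ndarray       # r_i = x_i - t_i w  (n_subjects x n_edges)


@dataclass
class DeviationProfile:
    disorder: str
    vector: np.ndarray
    n_subjects: int


@dataclass
class EdgeProfile:
    edge_indices: np.ndarray
    signed_weights: np.ndarray
    fraction: float
    network_pair_counts: pd.DataFrame | None = None


def fit_direction(cohort: CohortMatrix,
                  patient_mask: np.ndarray) -> LatentDirection:
    """First PLS weight vector separating patients from controls.

    ``patient_mask`` flags the pooled patient group (response +1; controls
    -1).  Requires an edgewise-standardized cohort.  The direction is
    normalized to unit length with its sign fixed so the patient-group mean
    projection is positive.  Zero-variance columns get zero weight.
    """
    y = np.where(np.asarray(patient_mask, bool), 1.0, -1.0)
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present")
    X = cohort.edges
    if X.shape[0] != len(y):
        raise DimensionError("labels do not match cohort")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = Xc.T @ yc
    if cohort.zero_variance_edges.size:
        w[cohort.zero_variance_edges] = 0.0
        warnings.warn(f"{cohort.zero_variance_edges.size} zero-variance "
                      "edge(s) given zero weight", stacklevel=2)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise DataError("degenerate direction: X^T y is the zero vector")
    w = w / nrm
    t = Xc @ w
    if t[np.asarray(patient_mask, bool)].mean() < 0:
        w = -w
        t = -t
    cov_ty = float(np.cov(t, yc)[0, 1])
    denom = math.sqrt(float(np.var(t, ddof=1) * np.var(yc, ddof=1)))
    expl = float((cov_ty / denom) ** 2) if denom > 0 else 0.0
    meta = {
        "n_patients": int(np.sum(patient_mask)),
        "n_controls": int(len(y) - np.sum(patient_mask)),
        "standardized": bool(cohort.standardized),
    }
    return LatentDirection(w, expl, meta)


class EdgePLS:
    """Model object for the transdiagnostic edge-space PLS fit.

    Thin statsmodels-style wrapper: built from a cohort and a healthy-control
    label, ``fit()`` returns an :class:`EdgePLSResults` carrying the latent
    direction plus projection/deviation methods.
    """

    def __init__(self, cohort: CohortMatrix, hc_label: str = "HC",
                 standardize: bool = True):
        self.cohort = cohort.standardize() if standardize and not \
            cohort.standardized else cohort
        self.hc_label = hc_label

    def fit(self) -> "EdgePLSResults":
        mask = self.cohort.groups != self.hc_label
        direction = fit_direction(self.cohort, mask)
        return EdgePLSResults(self, direction)


@dataclass
class EdgePLSResults:
    model: EdgePLS
    direction: LatentDirection

    def project_residualize(self,
                            cohort: CohortMatrix | None = None
                            ) -> ProjectionResult:
        if cohort is None:
            mask = self.model.cohort.groups != self.model.hc_label
            cohort = self.model.cohort.subset(mask).standardize()
        return project_residualize(cohort, self.direction)

    def deviation_profiles(self) -> list[DeviationProfile]:
        mask = self.model.cohort.groups != self.model.hc_label
        patients = self.model.cohort.subset(mask).standardize()
        proj = project_residualize(patients, self.direction)
        return compute_dscd(proj, patients.groups)

    def summary(self) -> str:
        d = self.direction
        lines = [
            "Edge-space PLS (first component)",
            "=" * 40,
            f"patients / controls:  {d.training_meta['n_patients']} / "
            f"{d.training_meta['n_controls']}",
            f"edges:                {len(d.weights)}",
            f"explained covariance: {d.explained_covariance:.4f}",
            f"|w|:                  {np.linalg.norm(d.weights):.6f}",
        ]
        profs = self.deviation_profiles()
        if len(profs) > 1:
            lines.append("DSCD cosine similarities:")
            for a in range(len(profs)):
                for b in range(a + 1, len(profs)):
                    c = cosine_similarity(profs[a].vector, profs[b].vector)
                    lines.append(f"  {profs[a].disorder} vs "
                                 f"{profs[b].disorder}: {c:+.3f}")
        return "\n".join(lines)


def project_residualize(cohort: CohortMatrix,
                        direction: LatentDirection) -> ProjectionResult:
    """Project subjects onto the latent direction and form residuals.

    t_i = x_i . w and r_i = x_i - t_i w; residuals are orthogonal to w and
    satisfy ||x||^2 = t^2 + ||r||^2.
    """
    w = direction.weights
    X = cohort.edges
    if X.shape[1] != len(w):
        raise DimensionError("cohort and direction edge counts differ")
    t = X @ w
    R = X - np.outer(t, w)
    return ProjectionResult(list(cohort.subject_ids), t, R)


def compute_dscd(result: ProjectionResult,
                 disorder_labels: np.ndarray) -> list[DeviationProfile]:
    """Per-disorder mean residual vectors (the DSCDs)."""
    labels = np.asarray(disorder_labels)
    if len(labels) != len(result.scores):
        raise DimensionError("one disorder label per subject required")
    out = []
    for d in pd.unique(labels):
        mask = labels == d
        if not mask.any():
            warnings.warn(f"empty disorder group '{d}' excluded",
                          stacklevel=2)
            continue
        out.append(DeviationProfile(str(d),
                                    result.residuals[mask].mean(axis=0),
                                    int(mask.sum())))
    return out


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("cosine similarity undefined for zero vectors")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def top_edges(vector: np.ndarray, fraction: float = 0.01) -> EdgeProfile:
    """Edges with the largest |value|; ties broken by ascending index."""
    if not 0 < fraction <= 1:
        raise DataError("fraction must be in (0, 1]")
    v = np.asarray(vector, float)
    k = math.ceil(fraction * len(v))
    order = np.lexsort((np.arange(len(v)), -np.abs(v)))
    idx = np.sort(order[:k])
    return EdgeProfile(idx, v[idx], float(fraction))


def network_pair_counts(profile: EdgeProfile,
                        region_networks: dict[int, str] | list[str],
                        edge_map: EdgeIndexMap) -> pd.DataFrame:
    """Unordered network-pair frequency table of a profile's edges."""
    if isinstance(region_networks, dict):
        nets = [region_networks.get(i) for i in range(edge_map.n_regions)]
    else:
        nets = list(region_networks)
    if len(nets) < edge_map.n_regions or any(n is None for n in nets):
        raise DataError("every region must map to a network")
    names = sorted(set(nets))
    table = pd.DataFrame(0, index=names, columns=names, dtype=int)
    iu, ju = edge_map.pairs
    for e in profile.edge_indices:
        a, b = nets[iu[e]], nets[ju[e]]
        a, b = sorted((a, b))
        table.loc[a, b] += 1
        if a != b:
            table.loc[b, a] += 1
    profile.network_pair_counts = table
    return table


def edge_pc1_scores(edge_submatrix: np.ndarray) -> np.ndarray:
    """Subject scores on the first PC of a column-centered edge submatrix.

    The loading sign is fixed so the largest-|.| loading entry is positive.
    """
    X = np.asarray(edge_submatrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("need at least 2 subjects")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = Vt[0]
    j = np.argmax(np.abs(load))
    sign = 1.0 if load[j] >= 0 else -1.0
    return sign * U[:, 0] * s[0]


def spearman_assoc(scores: np.ndarray, clinical: np.ndarray,
                   n_boot: int = 1000,
                   seed: int = 0) -> tuple[float, float, float, float]:
    """Spearman association with a bootstrap-percentile 95% CI.

    Pairs with missing clinical values are dropped; requires n >= 5 after
    dropping.  Returns (rho, two-sided p, ci_low, ci_high).
    """
    s = np.asarray(scores, float)
    c = np.asarray(clinical, float)
    keep = np.isfinite(s) & np.isfinite(c)
    s, c = s[keep], c[keep]
    if len(s) < 5:
        raise DataError("need at least 5 complete pairs")
    if len(np.unique(c)) == 1:
        raise DataError("clinical values are all tied; rho undefined")
    res = stats.spearmanr(s, c)
    rho, p = float(res.statistic), float(res.pvalue)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(s), len(s))
        if len(np.unique(c[idx])) == 1 or len(np.unique(s[idx])) == 1:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(s[idx], c[idx]).statistic
    boots = boots[np.isfinite(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots.size
              else (np.nan, np.nan))
    return rho, p, float(lo), float(hi)
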