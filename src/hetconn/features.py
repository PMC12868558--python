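"""Neurotransmitter / mitochondrial edge annotation via precision perturbation.

With only a handful of feature maps (19 neurotransmitter, 6 mitochondrial),
plain inter-regional correlation estimates are unstable, so the
region-by-region covariance S (features as observations) is regularized with
the Ledoit-Wolf shrinkage estimator

    Sigma_hat = (1 - alpha) * S + alpha * (tr(S)/p) * I,

where p is the dimension of S (number of regions) and alpha is the analytic
optimal shrinkage intensity clipped to [0, 1].  Normalizing Sigma_hat to a
correlation matrix gives the feature co-expression network (CNE/CME), whose
distance decay is modelled by the same exponential curve as CGE and collected
into a theoretical matrix E_ij = A*exp(-d_ij/scale) + B (diagonal 0).

Feature contributions to each edge use leave-one-feature-out precision
perturbation: with P_full the precision (inverse) of the full-feature
Sigma_hat and P_-f the precision after dropping feature f,

    S_{ij,f} = R_full[ij] - R_-f[ij] = P_full[ij] - P_-f[ij],

where R = P - E; the theoretical matrix cancels exactly in the difference
(asserted at 1e-12), so contributions are pure precision perturbations.
Positive values mean the feature adds conditional coupling to that edge.
Stacking S_{.,f} over features yields the contribution matrix fed to the same
PLS annotation machinery as the transcriptomic stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from ._utils import DataError, DimensionError
from .connectome import EdgeIndexMap, vectorize_upper
from .transcriptomics import ContributionMatrix, DecayModel, \
    RegionProfileMatrix

__all__ = [
    "ShrunkCovariance",
    "PerturbationScores",
    "shrunk_covariance",
    "to_correlation",
    "theoretical_matrix",
    "loo_feature_scores",
    "assemble_contributions",
]


@dataclass
class ShrunkCovariance:
    sigma_hat: np.ndarray
    sample_cov: np.ndarray
    alpha: float
    target_scale: float        # tr(S)/p


def _lw_alpha(X: np.ndarray, S: np.ndarray, center: bool) -> float:
    """Analytic Ledoit-Wolf optimal shrinkage intensity.

    ``X`` is regions x features; observations are the feature columns.
    Follows the standard estimator: alpha = min(b^2, d^2) / d^2 with
    d^2 = ||S - mu I||_F^2 / p and b^2 the average squared Frobenius
    distance of per-observation outer products from S, divided by n^2.
    """
    p, n = X.shape
    mu = np.trace(S) / p
    d2 = float(np.sum((S - mu * np.eye(p)) ** 2)) / p
    if d2 == 0:
        return 0.0
    Xc = X - X.mean(axis=1, keepdims=True) if center else X
    b2_sum = 0.0
    for k in range(n):
        xk = Xc[:, k]
        b2_sum += float(np.sum((np.outer(xk, xk) - S) ** 2)) / p
    b2 = b2_sum / n ** 2
    return float(np.clip(min(b2, d2) / d2, 0.0, 1.0))


def shrunk_covariance(profiles: RegionProfileMatrix,
                      alpha: float | None = None,
                      center: bool = True) -> ShrunkCovariance:
    """Ledoit-Wolf shrunk covariance between regions.

    The covariance is computed across features (each feature map is one
    observation of the region vector).  ``alpha=None`` estimates the optimal
    intensity analytically; passing a value fixes it.  ``center=False``
    uses raw second moments (appropriate when profiles are already
    centered), which also makes the estimate exactly invariant to removing
    a duplicate feature column.
    """
    X = np.asarray(profiles.values, float)
    p, n = X.shape
    if n < 2:
        raise DataError("need at least 2 feature columns")
    Xc = X - X.mean(axis=1, keepdims=True) if center else X
    S = (Xc @ Xc.T) / n
    a = _lw_alpha(X, S, center) if alpha is None else float(alpha)
    if not 0.0 <= a <= 1.0:
        raise DataError("alpha must lie in [0, 1]")
    mu = float(np.trace(S)) / p
    sigma = (1.0 - a) * S + a * mu * np.eye(p)
    return ShrunkCovariance(sigma, S, a, mu)


def to_correlation(cov: ShrunkCovariance | np.ndarray) -> np.ndarray:
    """Normalize a covariance matrix to a correlation matrix."""
    C = cov.sigma_hat if isinstance(cov, ShrunkCovariance) else \
        np.asarray(cov, float)
    d = np.diag(C)
    if np.any(d <= 0):
        raise DataError("covariance has non-positive diagonal entries")
    inv_sd = 1.0 / np.sqrt(d)
    R = C * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def theoretical_matrix(distances: np.ndarray,
                       model: DecayModel) -> np.ndarray:
    """Distance-predicted connectivity E_ij = A*exp(-d_ij/scale) + B.

    The diagonal is set to 0 (the curve is defined for distinct regions
    only).
    """
    D = np.asarray(distances, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise DimensionError("distances must be a symmetric square matrix")
    E = model.predict(D)
    np.fill_diagonal(E, 0.0)
    return E


@dataclass
class PerturbationScores:
    values: np.ndarray                  # edges x features
    feature_names: list[str]
    full_precision: np.ndarray
    theoretical_matrix: np.ndarray
    edge_map: EdgeIndexMap
    condition_number: float = np.nan


def _precision(sigma: np.ndarray) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(sigma)
    except linalg.LinAlgError as exc:
        raise DataError(
            "shrunk covariance is not positive definite; increase the "
            "shrinkage intensity") from exc
    return linalg.cho_solve((c, low), np.eye(sigma.shape[0]))


def loo_feature_scores(profiles: RegionProfileMatrix,
                       model: DecayModel,
                       alpha_policy: str = "reestimate",
                       alpha: float | None = None,
                       center: bool = True) -> PerturbationScores:
    """Leave-one-feature-out precision-perturbation contribution scores.

    ``alpha_policy='reestimate'`` re-estimates the shrinkage intensity for
    every reduced feature set; ``'frozen'`` reuses the full-set intensity
    (which can itself be fixed via ``alpha``).
    The scores are S_{ij,f} = P_full[ij] - P_-f[ij]; the residual form
    R_full - R_-f (with the theoretical matrix E subtracted from both) is
    identical because E cancels, which is asserted at 1e-12.
    """
    if alpha_policy not in ("reestimate", "frozen"):
        raise ValueError("alpha_policy must be 'reestimate' or 'frozen'")
    X = np.asarray(profiles.values, float)
    p, n_feat = X.shape
    if n_feat < 3:
        raise DataError("need at least 3 features")
    if profiles.coordinates is None:
        raise DataError("profiles need coordinates for the theoretical "
                        "matrix")
    full = shrunk_covariance(profiles, alpha=alpha, center=center)
    P_full = _precision(full.sigma_hat)
    cond = float(np.linalg.cond(full.sigma_hat))

    diff = profiles.coordinates[:, None, :] - profiles.coordinates[None, :, :]
    D = np.sqrt((diff ** 2).sum(-1))
    E = theoretical_matrix(D, model)
    R_full = P_full - E

    emap = EdgeIndexMap(p)
    scores = np.empty((emap.n_edges, n_feat))
    for f in range(n_feat):
        keep = [j for j in range(n_feat) if j != f]
        sub = RegionProfileMatrix(X[:, keep],
                                  [profiles.variable_names[j] for j in keep],
                                  profiles.region_ids,
                                  profiles.coordinates)
        alpha_f = None if alpha_policy == "reestimate" else full.alpha
        red = shrunk_covariance(sub, alpha=alpha_f, center=center)
        P_f = _precision(red.sigma_hat)
        R_f = P_f - E
        delta_R = R_full - R_f
        delta_P = P_full - P_f
        if not np.allclose(delta_R, delta_P, atol=1e-12, rtol=0):
            raise AssertionError(
                "theoretical-matrix cancellation identity violated")
        scores[:, f] = vectorize_upper(delta_P, emap)

    return PerturbationScores(scores, list(profiles.variable_names),
                              P_full, E, emap, cond)


def assemble_contributions(scores: PerturbationScores,
                           kind: str = "neurotransmitter"
                           ) -> ContributionMatrix:
    """Package perturbation scores as an edge x feature contribution matrix."""
    return ContributionMatrix(scores.values.copy(),
                              list(scores.feature_names),
                              kind, False, scores.edge_map)
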