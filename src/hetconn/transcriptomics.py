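"""Edge-level transcriptomic annotation of connectivity patterns.

Correlated gene expression (CGE) between two regions is the Pearson
correlation of their normalized expression profiles.  CGE decays with
anatomical distance, modelled as ``r(d) = A * exp(-d/scale) + B``; the fitted
curve is removed so residuals are distance-free.

Per-gene contribution scores use the exact additive decomposition of the
Pearson correlation: with profiles row-standardized (per region across
genes), CGE(i, j) = sum_g z_ig * z_jg / (G - 1), so the contribution of gene
g to edge (i, j) is z_ig * z_jg / (G - 1).  This is the unique linear
decomposition whose gene-sum reproduces CGE exactly — a conservation law the
tests assert.

The contribution matrix (edges x genes) is related to an edge-weight vector
(a connectivity pattern) by PLS regression with edges as observations.  The
component count maximizes 5-fold cross-validated explained variance (capped);
significance comes from spatially constrained permutations — region
identities are shuffled within distance-quantile swap sets so surrogate
patterns retain the gross spatial autocorrelation of the original (a
declared stand-in for variogram-matched surrogate maps; an alternative null
generator can be plugged in).  Bootstrap resampling of edges yields
per-variable z scores and Benjamini-Hochberg significance flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from ._utils import (DataError, DecayFitError, DimensionError, substream)
from .connectome import EdgeIndexMap

__all__ = [
    "RegionProfileMatrix",
    "DecayModel",
    "ContributionMatrix",
    "PlsAnnotationResult",
    "cge_matrix",
    "pairwise_distances",
    "fit_decay",
    "spatial_residualize",
    "gene_contributions",
    "pls_annotation",
]


@dataclass
class RegionProfileMatrix:
    """Region x variable profile matrix with region coordinates."""

    values: np.ndarray
    variable_names: list[str]
    region_ids: list[str]
    coordinates: np.ndarray | None = None   # (n_regions, 3) mm

    @classmethod
    def from_frames(cls, profiles: pd.DataFrame,
                    coordinates: pd.DataFrame | None = None
                    ) -> "RegionProfileMatrix":
        coords = None
        if coordinates is not None:
            coords = coordinates.loc[profiles.index,
                                     ["x", "y", "z"]].to_numpy(float)
        return cls(profiles.to_numpy(float),
                   [str(c) for c in profiles.columns],
                   [str(i) for i in profiles.index],
                   coords)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


@dataclass
class DecayModel:
    """Exponential distance-decay curve A*exp(-d/scale) + B."""

    amplitude: float
    offset: float
    scale: float
    fit_rmse: float = 0.0

    def predict(self, distances: np.ndarray) -> np.ndarray:
        return (self.amplitude * np.exp(-np.asarray(distances, float)
                                        / self.scale) + self.offset)


@dataclass
class ContributionMatrix:
    values: np.ndarray              # edges x variables
    variable_names: list[str]
    kind: str = "gene"
    centered: bool = False
    edge_map: EdgeIndexMap | None = None


@dataclass
class PlsAnnotationResult:
    variable_weights: np.ndarray         # variables x components
    explained_variance: np.ndarray       # CV R^2 per candidate count
    n_components: int
    permutation_p: float | None
    bootstrap_z: np.ndarray | None
    q_values: np.ndarray | None
    variable_names: list[str] = field(default_factory=list)
    r2_insample: float = 0.0

    def ranked_variables(self, positive: bool = True) -> pd.DataFrame:
        """Variables ranked by first-component weight (or bootstrap z)."""
        score = (self.bootstrap_z if self.bootstrap_z is not None
                 else self.variable_weights[:, 0])
        df = pd.DataFrame({
            "variable": self.variable_names,
            "weight": self.variable_weights[:, 0],
            "z": (self.bootstrap_z if self.bootstrap_z is not None
                  else np.nan),
            "q": (self.q_values if self.q_values is not None else np.nan),
        })
        df = df[df["weight"] > 0] if positive else df[df["weight"] < 0]
        key = np.abs(df["z"] if self.bootstrap_z is not None
                     else df["weight"])
        return df.iloc[np.argsort(-key.to_numpy())].reset_index(drop=True)


def _row_standardize(X: np.ndarray) -> np.ndarray:
    """Per-region z-score across variables (ddof=1, Pearson convention)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = sd[:, 0] == 0
    sd[bad] = 1.0
    Z = (X - mu) / sd
    Z[bad] = 0.0
    return Z


def _normalize_columns(X: np.ndarray, normalize: str) -> np.ndarray:
    if normalize == "none":
        return X
    if normalize != "zscore":
        raise ValueError("normalize must be 'zscore' or 'none'")
    col_sd = X.std(axis=0, ddof=1)
    col_sd[col_sd == 0] = 1.0
    return (X - X.mean(axis=0)) / col_sd


def cge_matrix(profiles: RegionProfileMatrix,
               normalize: str = "zscore") -> np.ndarray:
    """Pearson correlation of normalized profiles between region pairs.

    With ``normalize='zscore'`` (the convention for expression data, where
    variables live on incommensurate scales) each variable is first z-scored
    across regions, then regions are correlated across variables.  Note the
    cross-region centering slightly deflates correlations when regions are
    strongly spatially correlated; ``normalize='none'`` skips it and
    correlates raw profiles (appropriate when variables are already on a
    common scale).  Constant region profiles get zero correlations with a
    warning.
    """
    X = np.asarray(profiles.values, float)
    if X.shape[1] < 3:
        raise DimensionError("need at least 3 variables")
    Z = _row_standardize(_normalize_columns(X, normalize))
    G = X.shape[1]
    C = (Z @ Z.T) / (G - 1)
    constant = np.all(Z == 0, axis=1)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant region profile(s); "
                      "correlations set to 0", stacklevel=2)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    c = np.asarray(coords, float)
    diff = c[:, None, :] - c[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def fit_decay(edge_values: np.ndarray, distances: np.ndarray) -> DecayModel:
    """Nonlinear least-squares fit of the exponential decay curve.

    Initialization: amplitude = value range, offset = minimum value,
    scale = median distance; scale is bounded in (0, 10 * max distance].
    """
    v = np.asarray(edge_values, float)
    d = np.asarray(distances, float)
    if len(v) != len(d):
        raise DimensionError("values and distances differ in length")
    if len(v) < 10:
        raise DataError("need at least 10 region pairs to fit the decay")
    if np.any(d <= 0):
        raise DataError("distances must be positive")

    def f(x, A, B, scale):
        return A * np.exp(-x / scale) + B

    p0 = [float(v.max() - v.min()) or 1.0, float(v.min()),
          float(np.median(d))]
    bounds = ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 10 * float(d.max())])
    try:
        popt, _ = optimize.curve_fit(f, d, v, p0=p0, bounds=bounds,
                                     xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                     maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise DecayFitError(
            f"decay fit failed (init={p0}, n={len(v)}, "
            f"value range=({v.min():.3g}, {v.max():.3g}), "
            f"distance range=({d.min():.3g}, {d.max():.3g})): {exc}"
        ) from exc
    pred = f(d, *popt)
    rmse = float(np.sqrt(np.mean((v - pred) ** 2)))
    return DecayModel(float(popt[0]), float(popt[1]), float(popt[2]), rmse)


def spatial_residualize(edge_values: np.ndarray, distances: np.ndarray,
                        model: DecayModel) -> np.ndarray:
    """Remove the fitted distance-decay trend; residuals are distance-free."""
    v = np.asarray(edge_values, float)
    d = np.asarray(distances, float)
    if len(v) != len(d):
        raise DimensionError("values and distances differ in length")
    return v - model.predict(d)


def gene_contributions(profiles: RegionProfileMatrix,
                       edge_map: EdgeIndexMap | None = None,
                       normalize: str = "zscore") -> ContributionMatrix:
    """Per-variable additive contributions to each region pair's CGE.

    contribution(i, j, g) = z_ig * z_jg / (G - 1) with z the doubly
    normalized profiles used by :func:`cge_matrix`; summing over variables
    reproduces CGE(i, j) exactly.
    """
    if profiles.n_variables < 2:
        raise DimensionError("need at least 2 variables")
    if edge_map is None:
        edge_map = EdgeIndexMap(profiles.n_regions)
    if edge_map.n_regions != profiles.n_regions:
        raise DimensionError("edge map does not match profile regions")
    X = np.asarray(profiles.values, float)
    Z = _row_standardize(_normalize_columns(X, normalize))
    iu, ju = edge_map.pairs
    G = profiles.n_variables
    contrib = Z[iu] * Z[ju] / (G - 1)
    return ContributionMatrix(contrib, list(profiles.variable_names),
                              "gene", False, edge_map)


def _quantile_swap_permutation(rng: np.random.Generator,
                               distances: np.ndarray,
                               n_bins: int = 5) -> np.ndarray:
    """Region permutation restricted to mean-distance quantile bins.

    Regions are binned by their mean distance to all other regions and
    shuffled only within bins, preserving the gross spatial profile of the
    map while destroying region identity.
    """
    mean_d = distances.mean(axis=1)
    n = len(mean_d)
    order = np.argsort(mean_d, kind="stable")
    perm = np.arange(n)
    edges_ = np.array_split(order, n_bins)
    for bin_idx in edges_:
        perm[bin_idx] = rng.permutation(bin_idx)
    return perm


def _cv_r2(X: np.ndarray, y: np.ndarray, n_comp: int, seed: int) -> float:
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    press, tss = 0.0, 0.0
    for tr, te in kf.split(X):
        pls = PLSRegression(n_components=n_comp, scale=False)
        pls.fit(X[tr], y[tr])
        pred = pls.predict(X[te]).ravel()
        press += float(np.sum((y[te] - pred) ** 2))
        tss += float(np.sum((y[te] - y[tr].mean()) ** 2))
    return 1.0 - press / tss if tss > 0 else 0.0


def pls_annotation(contributions: ContributionMatrix,
                   edge_weights: np.ndarray,
                   coordinates: np.ndarray | None = None,
                   n_perm: int = 1000, n_boot: int = 1000,
                   max_components: int = 10,
                   null_generator=None,
                   seed: int = 0) -> PlsAnnotationResult:
    """PLS regression of an edge-weight pattern on a contribution matrix.

    Rows (observations) are edges; predictors are per-variable contribution
    scores; the response is the connectivity pattern's edge weight.  See the
    module docstring for component selection, the spatial null, and the
    bootstrap.  With ``n_boot=0`` weights are returned without z scores.
    """
    X = np.asarray(contributions.values, float)
    y = np.asarray(edge_weights, float)
    if X.shape[0] != len(y):
        raise DimensionError("contribution rows must match edge weights")
    cap = int(min(max_components, X.shape[1], X.shape[0] - 1))
    if cap < 1:
        raise DimensionError("fewer edges than components")
    rng = substream(seed, "pls_annotation")
    cv_seed = int(rng.integers(2 ** 31))

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    cv_r2 = np.array([_cv_r2(Xc, yc, k, cv_seed) for k in range(1, cap + 1)])
    n_comp = int(np.argmax(cv_r2) + 1)

    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(Xc, yc)
    weights = pls.x_weights_.copy()
    # orient each component so its score covaries positively with y
    for k in range(n_comp):
        if pls.x_scores_[:, k] @ yc < 0:
            weights[:, k] = -weights[:, k]
    pred = pls.predict(Xc).ravel()
    ss_res = float(np.sum((yc - pred) ** 2))
    ss_tot = float(np.sum(yc ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    # spatially constrained permutation test on in-sample explained variance
    perm_p = None
    if n_perm > 0:
        emap = contributions.edge_map
        if null_generator is None and (coordinates is None or emap is None):
            raise DataError("coordinates and edge map required for the "
                            "spatial permutation null")
        if null_generator is None:
            D = pairwise_distances(coordinates)
            iu, ju = emap.pairs
            W = np.zeros((emap.n_regions, emap.n_regions))
            W[iu, ju] = y
            W[ju, iu] = y

            def null_generator(r):
                perm = _quantile_swap_permutation(r, D)
                return W[np.ix_(perm, perm)][iu, ju]

        null_stats = np.empty(n_perm)
        for i in range(n_perm):
            y_surr = np.asarray(null_generator(rng), float)
            ysc = y_surr - y_surr.mean()
            p2 = PLSRegression(n_components=n_comp, scale=False)
            p2.fit(Xc, ysc)
            pr = p2.predict(Xc).ravel()
            sst = float(np.sum(ysc ** 2))
            null_stats[i] = (1.0 - float(np.sum((ysc - pr) ** 2)) / sst
                             if sst > 0 else 0.0)
        perm_p = (1.0 + float(np.sum(null_stats >= r2))) / (n_perm + 1.0)

    boot_z = q_vals = None
    if n_boot > 0:
        n_edges = X.shape[0]
        w0 = weights[:, 0]
        boots = np.empty((n_boot, X.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, n_edges, n_edges)
            Xb = X[idx] - X[idx].mean(axis=0)
            yb = y[idx] - y[idx].mean()
            pb = PLSRegression(n_components=n_comp, scale=False)
            pb.fit(Xb, yb)
            wb = pb.x_weights_[:, 0]
            if wb @ w0 < 0:       # align bootstrap sign with original
                wb = -wb
            boots[b] = wb
        sd = boots.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        boot_z = w0 / sd
        pvals = 2.0 * stats.norm.sf(np.abs(boot_z))
        q_vals = _bh_fdr(pvals)

    return PlsAnnotationResult(
        variable_weights=weights,
        explained_variance=np.clip(cv_r2, 0.0, 1.0),
        n_components=n_comp,
        permutation_p=perm_p,
        bootstrap_z=boot_z,
        q_values=q_vals,
        variable_names=list(contributions.variable_names),
        r2_insample=r2,
    )


def _bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
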