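"""Heterogeneous matrix factorization (HMF) of multi-subject BOLD signal.

Each subject's standardized region x time matrix M_i is modelled as a linear
superposition of a group-shared low-rank component and a subject-specific
low-rank component,

    M_i = U_g V_gi^T + U_li V_li^T + E_i,      U_g^T U_li = 0 for all i,

fitted by minimizing 0.5 * sum_i ||M_i - U_g V_gi^T - U_li V_li^T||_F^2.
``U_g`` spans the "meta-BOLD" subspace — signal structure shared across the
cohort — while the orthogonality constraint keeps subject-specific structure
from leaking into it.

The solver is alternating least squares in which every step is an exact
constrained minimizer:

1. given U_g, set V_gi = M_i^T U_g and take (U_li, V_li) from the rank-r_l
   truncated SVD of the projected residual (I - U_g U_g^T) M_i — this makes
   U_g^T U_li = 0 hold by construction;
2. update U_g (and V_gi) as the top-r_g left singular subspace of the
   column-concatenation of (M_i - U_li V_li^T).

Both steps can only decrease the loss, so the loss trace is non-increasing.
Bases are kept orthonormal with scale absorbed into the coefficient matrices,
and a deterministic sign convention (largest-|entry| of each basis column
positive) removes the sign ambiguity; U_g is still identified only up to
rotation within the shared subspace, so comparisons should use projectors or
principal angles, never raw columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import DataError, DimensionError, check_finite
from .connectome import compute_fc, vectorize_upper, EdgeIndexMap
from .synth import SubjectBold

__all__ = [
    "HeterogeneousFactorization",
    "HmfResults",
    "within_group_variability",
    "snr_metric",
]


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    if U.shape[1] == 0:
        return U
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _as_subjects(data) -> list[SubjectBold]:
    out = []
    for i, d in enumerate(data):
        if isinstance(d, SubjectBold):
            out.append(d)
        else:
            out.append(SubjectBold(f"sub-{i:03d}", np.asarray(d, float)))
    return out


class HeterogeneousFactorization:
    """HMF model of a list of subject BOLD matrices.

    Parameters
    ----------
    data
        List of :class:`~hetconn.synth.SubjectBold` (or plain arrays);
        all subjects must share the region dimension.
    rank_shared, rank_specific
        Ranks r_g >= 1 and r_l >= 0 of the shared and per-subject
        components.  Rank selection is deliberately left to the user;
        :meth:`rank_curve` reports reconstruction-MSE-vs-rank to inform it.
    max_iter, rel_tol
        ALS stopping rule: relative loss change below ``rel_tol`` or
        ``max_iter`` iterations.
    seed
        Only used for optional random restarts; the default initialization
        (top left singular vectors of the concatenated data) is
        deterministic.
    """

    def __init__(self, data, rank_shared: int, rank_specific: int = 0,
                 max_iter: int = 200, rel_tol: float = 1e-6,
                 seed: int | None = None):
        self.data = _as_subjects(data)
        if not self.data:
            raise DimensionError("no subjects")
        n = self.data[0].n_regions
        for s in self.data:
            check_finite(s.values, f"subject {s.subject_id}")
            if s.n_regions != n:
                raise DimensionError("subjects disagree on n_regions")
        if rank_shared < 1 or rank_specific < 0:
            raise DimensionError("rank_shared >= 1 and rank_specific >= 0")
        total = rank_shared + rank_specific
        if total > min(n, min(s.n_timepoints for s in self.data)):
            raise DimensionError(
                f"total rank {total} infeasible for dimensions")
        if rel_tol <= 0:
            raise DimensionError("rel_tol must be > 0")
        self.rank_shared = rank_shared
        self.rank_specific = rank_specific
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.seed = seed

    # -- solver ----------------------------------------------------------

    def _loss(self, Ug, Uls, Vls) -> float:
        total = 0.0
        for s, Ul, Vl in zip(self.data, Uls, Vls):
            M = s.values
            Vg = M.T @ Ug
            R = M - Ug @ Vg.T - Ul @ Vl.T
            total += 0.5 * float(np.sum(R * R))
        return total

    def fit(self) -> "HmfResults":
        r_g, r_l = self.rank_shared, self.rank_specific
        mats = [s.values for s in self.data]
        concat = np.concatenate(mats, axis=1)
        U, _, _ = np.linalg.svd(concat, full_matrices=False)
        Ug = _fix_signs(U[:, :r_g])

        n = mats[0].shape[0]
        Uls = [np.zeros((n, r_l)) for _ in mats]
        Vls = [np.zeros((m.shape[1], r_l)) for m in mats]

        loss_trace: list[float] = []
        converged = False
        for it in range(self.max_iter):
            # subject-specific step: exact constrained minimizer given Ug
            for i, M in enumerate(mats):
                if r_l == 0:
                    continue
                R = M - Ug @ (Ug.T @ M)
                Uf, sf, Vtf = np.linalg.svd(R, full_matrices=False)
                Ul = _fix_signs(Uf[:, :r_l])
                # re-project for exact orthogonality against Ug
                Ul = Ul - Ug @ (Ug.T @ Ul)
                # renormalize columns (projection is a no-op up to fp)
                norms = np.linalg.norm(Ul, axis=0)
                norms[norms == 0] = 1.0
                Ul = Ul / norms
                Vls[i] = (R.T @ Ul)
                Uls[i] = Ul

            loss = self._loss(Ug, Uls, Vls)
            loss_trace.append(loss)
            if len(loss_trace) >= 2:
                prev = loss_trace[-2]
                rel = abs(prev - loss) / max(prev, 1e-300)
                if rel < self.rel_tol:
                    converged = True
                    break
            elif loss == 0.0:
                converged = True
                break

            # shared step: top-r_g left singular subspace of deflated data
            deflated = np.concatenate(
                [M - Ul @ Vl.T for M, Ul, Vl in zip(mats, Uls, Vls)], axis=1)
            U, _, _ = np.linalg.svd(deflated, full_matrices=False)
            Ug = _fix_signs(U[:, :r_g])

        # final subject-specific refresh so invariants hold exactly
        shared_coeffs, spec_bases, spec_coeffs = {}, {}, {}
        for s, M in zip(self.data, mats):
            if r_l > 0:
                R = M - Ug @ (Ug.T @ M)
                Uf, sf, Vtf = np.linalg.svd(R, full_matrices=False)
                Ul = _fix_signs(Uf[:, :r_l])
                Ul = Ul - Ug @ (Ug.T @ Ul)
                norms = np.linalg.norm(Ul, axis=0)
                norms[norms == 0] = 1.0
                Ul = Ul / norms
                Vl = R.T @ Ul
            else:
                Ul = np.zeros((n, 0))
                Vl = np.zeros((M.shape[1], 0))
            shared_coeffs[s.subject_id] = M.T @ Ug
            spec_bases[s.subject_id] = Ul
            spec_coeffs[s.subject_id] = Vl
        final_loss = self._loss(Ug, [spec_bases[s.subject_id] for s in self.data],
                                [spec_coeffs[s.subject_id] for s in self.data])
        if not loss_trace or final_loss <= loss_trace[-1] + 1e-10:
            loss_trace.append(final_loss)

        return HmfResults(
            model=self,
            shared_basis=Ug,
            shared_coeffs=shared_coeffs,
            specific_bases=spec_bases,
            specific_coeffs=spec_coeffs,
            loss_trace=loss_trace,
            converged=converged,
        )

    def rank_curve(self, ranks: list[int],
                   rank_specific: int | None = None) -> dict[int, float]:
        """Mean meta-only reconstruction MSE for each candidate shared rank."""
        out = {}
        r_l = self.rank_specific if rank_specific is None else rank_specific
        for r in ranks:
            res = HeterogeneousFactorization(
                self.data, r, r_l, self.max_iter, self.rel_tol).fit()
            out[r] = res.reconstruction_mse(mode="meta_only")[1]
        return out


@dataclass
class HmfResults:
    """Fitted HMF factors with reconstruction and diagnostic methods."""

    model: HeterogeneousFactorization
    shared_basis: np.ndarray
    shared_coeffs: dict[str, np.ndarray]
    specific_bases: dict[str, np.ndarray]
    specific_coeffs: dict[str, np.ndarray]
    loss_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def subject_ids(self) -> list[str]:
        return list(self.shared_coeffs)

    def reconstruct(self, subject_id: str,
                    mode: str = "meta_only") -> np.ndarray:
        """Reconstruct a subject's signal from the fitted factors.

        ``meta_only`` returns the shared component U_g V_gi^T (the meta-BOLD
        reconstruction); ``full`` adds the subject-specific component.
        """
        if subject_id not in self.shared_coeffs:
            raise KeyError(f"unknown subject '{subject_id}'")
        rec = self.shared_basis @ self.shared_coeffs[subject_id].T
        if mode == "full":
            rec = rec + (self.specific_bases[subject_id]
                         @ self.specific_coeffs[subject_id].T)
        elif mode != "meta_only":
            raise ValueError("mode must be 'meta_only' or 'full'")
        return rec

    def reconstruction_mse(self, data: list[SubjectBold] | None = None,
                           mode: str = "meta_only"
                           ) -> tuple[dict[str, float], float]:
        """Per-subject and mean squared reconstruction error.

        In ``meta_only`` mode this is the fidelity of the shared component
        alone — how much of each standardized signal the meta-BOLD
        reconstruction explains.
        """
        data = self.model.data if data is None else _as_subjects(data)
        per = {}
        for s in data:
            rec = self.reconstruct(s.subject_id, mode)
            per[s.subject_id] = float(np.mean((s.values - rec) ** 2))
        return per, float(np.mean(list(per.values())))

    def summary(self) -> str:
        per, mean_mse = self.reconstruction_mse(mode="meta_only")
        _, full_mse = self.reconstruction_mse(mode="full")
        lines = [
            "Heterogeneous Matrix Factorization",
            "=" * 40,
            f"subjects:            {len(self.subject_ids)}",
            f"regions:             {self.shared_basis.shape[0]}",
            f"rank (shared):       {self.model.rank_shared}",
            f"rank (specific):     {self.model.rank_specific}",
            f"iterations:          {len(self.loss_trace)}",
            f"converged:           {self.converged}",
            f"final loss:          {self.loss_trace[-1]:.6g}",
            f"mean MSE meta-only:  {mean_mse:.6g}",
            f"mean MSE full:       {full_mse:.6g}",
        ]
        return "\n".join(lines)


def within_group_variability(signals: list[np.ndarray]) -> float:
    """Mean across-subject SD of FC edge values.

    Computes each subject's region x region Pearson FC, vectorizes the upper
    triangle, and returns the mean over edges of the across-subject standard
    deviation — the within-group heterogeneity of the connectome.
    """
    if len(signals) < 2:
        raise DataError("within-group variability needs >= 2 subjects")
    n = np.asarray(signals[0]).shape[0]
    emap = EdgeIndexMap(n)
    edges = np.array([vectorize_upper(compute_fc(s), emap) for s in signals])
    return float(edges.std(axis=0, ddof=1).mean())


def snr_metric(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Edgewise between-group separation over pooled within-group variance.

    For each edge, (mean_a - mean_b)^2 / pooled variance; the mean over
    edges is returned.  Edges with zero pooled variance are excluded with a
    warning.
    """
    A = np.atleast_2d(np.asarray(group_a, float))
    B = np.atleast_2d(np.asarray(group_b, float))
    if A.shape[0] < 1 or B.shape[0] < 1:
        raise DataError("both groups must be non-empty")
    na, nb = A.shape[0], B.shape[0]
    diff2 = (A.mean(axis=0) - B.mean(axis=0)) ** 2
    if na + nb > 2:
        pooled = ((na - 1) * A.var(axis=0, ddof=1 if na > 1 else 0)
                  + (nb - 1) * B.var(axis=0, ddof=1 if nb > 1 else 0)) \
            / (na + nb - 2)
    else:
        pooled = np.zeros_like(diff2)
    ok = pooled > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance edge(s) excluded "
                      "from SNR", stacklevel=2)
    if not ok.any():
        raise DataError("no edges with positive pooled variance")
    return float(np.mean(diff2[ok] / pooled[ok]))
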