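"""Stability and reproducibility machinery for the latent direction.

Four complementary procedures:

* bootstrap resampling of subjects (stratified by class) with refitting of
  the PLS direction; cosine similarity to the original direction measures
  stability;
* stratified k-fold cross-validated discrimination — the direction is refit
  on each training fold, held-out subjects are projected, and a univariate
  logistic model on the training projections yields held-out AUC and
  accuracy (fold-wise refitting keeps the held-out estimates leakage-free,
  possibly stricter than common practice);
* a permutation group test: labels are shuffled, the direction re-estimated,
  and the between-group mean projection difference recomputed to build the
  null; the add-one p-value formula keeps p strictly positive;
* split-half reliability of group-mean edge vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._utils import DataError, substream
from .connectome import CohortMatrix
from .stacp import cosine_similarity, fit_direction

__all__ = [
    "ValidationReport",
    "bootstrap_direction",
    "crossval_discrimination",
    "permutation_group_test",
    "split_half_reliability",
    "validate",
]


@dataclass
class ValidationReport:
    bootstrap_cosines: np.ndarray
    cv_auc: np.ndarray
    cv_accuracy: np.ndarray
    permutation_p: float
    null_distribution: np.ndarray
    split_half_correlations: np.ndarray
    seeds: dict = field(default_factory=dict)

    def summary(self) -> str:
        bc, auc, acc = (self.bootstrap_cosines, self.cv_auc,
                        self.cv_accuracy)
        lines = [
            "Validation report",
            "=" * 40,
            f"bootstrap cosine:  {bc.mean():.3f} +/- {bc.std(ddof=1):.3f} "
            f"(n={len(bc)})" if bc.size else "bootstrap cosine:  (empty)",
            f"CV AUC:            {auc.mean():.3f} +/- {auc.std(ddof=1):.3f}",
            f"CV accuracy:       {acc.mean():.3f} +/- {acc.std(ddof=1):.3f}",
            f"permutation p:     {self.permutation_p:.4g}",
        ]
        if self.split_half_correlations.size:
            sh = self.split_half_correlations
            lines.append(f"split-half r:      {sh.mean():.3f} "
                         f"(min {sh.min():.3f})")
        return "\n".join(lines)


def _patient_mask(cohort: CohortMatrix, hc_label: str) -> np.ndarray:
    mask = cohort.groups != hc_label
    if mask.all() or not mask.any():
        raise DataError("both patient and control classes must be present")
    return mask


def bootstrap_direction(cohort: CohortMatrix, hc_label: str = "HC",
                        n_boot: int = 1000, seed: int = 0) -> np.ndarray:
    """Cosine similarity of refit directions over stratified resamples."""
    mask = _patient_mask(cohort, hc_label)
    base = fit_direction(cohort, mask)
    rng = substream(seed, "bootstrap")
    pat_idx = np.flatnonzero(mask)
    hc_idx = np.flatnonzero(~mask)
    cosines = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pat_idx, len(pat_idx), replace=True),
            rng.choice(hc_idx, len(hc_idx), replace=True),
        ])
        d = fit_direction(_take(cohort, idx), mask[idx])
        cosines[b] = cosine_similarity(d.weights, base.weights)
    return cosines


def _take(cohort: CohortMatrix, idx: np.ndarray) -> CohortMatrix:
    from dataclasses import replace
    cov = cohort.covariates.iloc[idx].reset_index(drop=True) \
        if cohort.covariates is not None else None
    return replace(cohort,
                   edges=cohort.edges[idx],
                   subject_ids=[cohort.subject_ids[i] for i in idx],
                   groups=cohort.groups[idx],
                   covariates=cov)


def crossval_discrimination(cohort: CohortMatrix, hc_label: str = "HC",
                            k: int = 5, seed: int = 0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified k-fold held-out AUC and accuracy of the direction."""
    mask = _patient_mask(cohort, hc_label)
    y = mask.astype(int)
    if k > len(y):
        raise DataError(f"k={k} exceeds n={len(y)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(substream(seed, "crossval")
                                           .integers(2 ** 31)))
    aucs, accs = [], []
    for train, test in skf.split(cohort.edges, y):
        d = fit_direction(_take(cohort, train), mask[train])
        t_train = cohort.edges[train] @ d.weights
        t_test = cohort.edges[test] @ d.weights
        clf = LogisticRegression().fit(t_train[:, None], y[train])
        prob = clf.predict_proba(t_test[:, None])[:, 1]
        aucs.append(roc_auc_score(y[test], prob))
        accs.append(float(np.mean((prob >= 0.5).astype(int) == y[test])))
    return np.asarray(aucs), np.asarray(accs)


def permutation_group_test(cohort: CohortMatrix, hc_label: str = "HC",
                           n_perm: int = 1000, seed: int = 0
                           ) -> tuple[float, np.ndarray]:
    """Permutation test of the between-group projection difference.

    The observed statistic is |mean t(patients) - mean t(controls)| under
    the fitted direction; each null draw shuffles the labels, refits the
    direction, and recomputes the statistic.  p uses the add-one formula so
    it is never exactly zero.
    """
    mask = _patient_mask(cohort, hc_label)

    def statistic(m: np.ndarray) -> float:
        d = fit_direction(cohort, m)
        t = cohort.edges @ d.weights
        return abs(float(t[m].mean() - t[~m].mean()))

    observed = statistic(mask)
    rng = substream(seed, "permutation")
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = statistic(rng.permutation(mask))
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return p, null


def split_half_reliability(cohort: CohortMatrix, group: str,
                           n_splits: int = 100, seed: int = 0) -> np.ndarray:
    """Pearson correlation between random half-group mean edge vectors."""
    idx = np.flatnonzero(cohort.groups == group)
    if len(idx) < 2:
        raise DataError(f"group '{group}' needs >= 2 subjects")
    rng = substream(seed, "split_half")
    X = cohort.edges[idx]
    n = len(idx)
    out = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        a = X[perm[:half]].mean(axis=0)
        b = X[perm[half:]].mean(axis=0)
        out[s] = np.corrcoef(a, b)[0, 1]
    return out


def validate(cohort: CohortMatrix, hc_label: str = "HC",
             n_boot: int = 1000, k: int = 5, n_perm: int = 1000,
             n_splits: int = 100, seed: int = 0) -> ValidationReport:
    """Run the full stability battery and assemble a report."""
    cosines = bootstrap_direction(cohort, hc_label, n_boot, seed)
    auc, acc = crossval_discrimination(cohort, hc_label, k, seed)
    p, null = permutation_group_test(cohort, hc_label, n_perm, seed)
    groups = [g for g in np.unique(cohort.groups) if g != hc_label]
    sh = []
    for g in groups:
        if np.sum(cohort.groups == g) >= 4:
            sh.append(split_half_reliability(cohort, g, n_splits, seed))
    return ValidationReport(
        bootstrap_cosines=cosines,
        cv_auc=auc,
        cv_accuracy=acc,
        permutation_p=p,
        null_distribution=null,
        split_half_correlations=(np.concatenate(sh) if sh
                                 else np.zeros(0)),
        seeds={"seed": seed, "n_boot": n_boot, "k": k, "n_perm": n_perm},
    )
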