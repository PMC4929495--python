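"""Principal-component-fed linear discriminant analysis (PC-LDA).

The model mirrors the chemometric workflow for two-group diffractogram
classification: mean-centre the cohort matrix, extract principal components,
keep the components whose scores separate the groups at one-way ANOVA
p < alpha, and fit Fisher's linear discriminant on the retained scores.
Cross-validation re-runs the *entire* chain — centring, PCA, ANOVA selection,
LDA — inside every fold so that no statistic of the held-out sample leaks
into training ("full recalculation" leave-one-out).

Conventions
-----------
* fracture is the positive class: sensitivity counts fractures found;
* the discriminant axis is oriented so the fracture group scores negative;
* the decision threshold is the midpoint of the two group-mean scores
  (equal priors); exact ties predict non_fracture.

``PCLDA`` is the model object; ``PCLDA.fit`` returns ``PCLDAResults`` with
the estimated mean spectrum, loadings, per-component ANOVA p-values, LD
weights and threshold, plus ``predict`` and ``summary``.  ``cross_validate``
returns a ``CVResult`` with per-sample scores, the confusion matrix and
sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CohortMatrix

__all__ = [
    "PCLDA",
    "PCLDAResults",
    "CVResult",
    "fit_pca",
    "anova_select",
    "fit_lda",
    "cross_validate",
    "subset_by_sex",
    "permutation_null_accuracies",
]

POSITIVE = "fracture"
NEGATIVE = "non_fracture"

#: column means above this are treated as a non-centred matrix
CENTER_TOL = 1e-8


def fit_pca(X: np.ndarray, max_components: int | None = None):
    """PCA of a mean-centred matrix via thin SVD.

    Returns (loadings, explained_variance, scores) with ``loadings`` of shape
    n_channels x k (orthonormal columns, sign fixed so each component's
    largest-magnitude element is positive), ``explained_variance`` the
    non-increasing sample variances of the scores, and ``scores = X @
    loadings``.  k is capped at min(n - 1, n_channels, max_components).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    if np.max(np.abs(X.mean(axis=0))) > CENTER_TOL * max(1.0, np.abs(X).max()):
        raise ValueError("matrix is not mean-centred")
    k = min(n - 1, X.shape[1])
    if max_components is not None:
        k = min(k, max_components)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[:k].T
    # deterministic sign: dominant element of each loading is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    explained = (s[:k] ** 2) / (n - 1)
    return loadings, explained, X @ loadings


def anova_select(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05):
    """Per-component one-way ANOVA of scores against the two group labels.

    Returns (F, p, selected) where F and p are per-column arrays computed
    from F = MS_between / MS_within on (1, n-2) degrees of freedom, and
    ``selected`` indexes the components with p < alpha.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = scores[labels == groups[0]]
    b = scores[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    n = len(a) + len(b)
    grand = scores.mean(axis=0)
    ss_between = len(a) * (a.mean(axis=0) - grand) ** 2 + len(b) * (
        b.mean(axis=0) - grand
    ) ** 2
    ss_within = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + (
        (b - b.mean(axis=0)) ** 2
    ).sum(axis=0)
    ms_within = ss_within / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ms_within > 0, ss_between / np.where(ms_within > 0, ms_within, 1.0), np.inf)
    F = np.where((ss_between == 0) & (ms_within == 0), 0.0, F)
    p = stats.f.sf(F, 1, n - 2)
    selected = np.flatnonzero(p < alpha)
    return F, p, selected


def fit_lda(selected_scores: np.ndarray, labels: np.ndarray):
    """Fisher LDA on the selected component scores.

    Returns (weights, threshold).  ``weights`` is the unit-norm direction
    proportional to pooled_within_cov^{-1} (mean_fracture - mean_non_fracture),
    oriented so the fracture mean projects below the non-fracture mean;
    ``threshold`` is the midpoint of the projected group means.
    """
    S = np.atleast_2d(np.asarray(selected_scores, dtype=float))
    if S.shape[1] < 1:
        raise ValueError("need at least one selected component")
    labels = np.asarray(labels)
    pos = S[labels == POSITIVE]
    neg = S[labels == NEGATIVE]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("one group is empty")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    n = len(pos) + len(neg)
    scatter = np.zeros((S.shape[1], S.shape[1]))
    for grp, mu in ((pos, mu_p), (neg, mu_n)):
        dev = grp - mu
        scatter += dev.T @ dev
    sw = scatter / max(n - 2, 1)
    diff = mu_p - mu_n
    try:
        w = np.linalg.solve(sw, diff)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(sw) / sw.shape[0] + 1e-12
        w = np.linalg.solve(sw + ridge * np.eye(sw.shape[0]), diff)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant direction")
    w = w / norm
    if w @ mu_p > w @ mu_n:  # fracture scores negative by convention
        w = -w
    threshold = float((w @ mu_p + w @ mu_n) / 2.0)
    return w, threshold


@dataclass
class PCLDAResults:
    """Fitted PC-LDA model: estimates, selection and decision rule."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    scores: np.ndarray
    pc_pvalues: np.ndarray
    pc_fvalues: np.ndarray
    selected: np.ndarray
    ld_weights: np.ndarray
    threshold: float
    channel_grid: np.ndarray
    fallback_used: bool = False
    alpha: float = 0.05

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """LD score of raw (normalized, uncentred) sample vectors."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.mean_spectrum):
            raise ValueError("channel-grid mismatch")
        pc = (X - self.mean_spectrum) @ self.loadings[:, self.selected]
        return pc @ self.ld_weights

    def predict(self, X: np.ndarray):
        """(LD scores, predicted labels); fracture lies below the threshold."""
        s = self.decision_scores(X)
        labels = np.where(s < self.threshold, POSITIVE, NEGATIVE)
        return s, labels

    def summary(self) -> str:
        lines = [
            "PC-fed LDA (two-group, fracture negative on the LD axis)",
            f"  channels:            {len(self.mean_spectrum)}",
            f"  components tested:   {self.n_components}",
            f"  selected (p<{self.alpha:g}):   {[int(j) for j in self.selected]}"
            + ("  [fallback: lowest p]" if self.fallback_used else ""),
            f"  decision threshold:  {self.threshold:+.4f}",
            "",
            "  PC   var.expl.   ANOVA F      p        LD weight",
        ]
        wmap = dict(zip(self.selected, self.ld_weights))
        total = self.explained_variance.sum()
        for j in range(self.n_components):
            wtxt = f"{wmap[j]:+.3f}" if j in wmap else "    -"
            lines.append(
                f"  {j:3d}   {100 * self.explained_variance[j] / total:7.2f}%"
                f"   {self.pc_fvalues[j]:9.2f}  {self.pc_pvalues[j]:8.2e}  {wtxt}"
            )
        return "\n".join(lines)


class PCLDA:
    """PC-fed LDA model over a normalized (uncentred) cohort matrix.

    Parameters
    ----------
    matrix : CohortMatrix
        Per-sample normalized intensities; centring happens inside ``fit``.
    alpha : float
        ANOVA selection level for component inclusion (default 0.05,
        uncorrected: no multiplicity adjustment is applied).
    max_components : int, optional
        Cap on the number of components tested; default min(n - 2, 50).
    """

    def __init__(
        self,
        matrix: CohortMatrix,
        alpha: float = 0.05,
        max_components: int | None = None,
    ):
        if matrix.centered:
            raise ValueError(
                "pass the uncentred matrix; PCLDA.fit centres internally"
            )
        labels = matrix.labels
        present = set(labels)
        if not {POSITIVE, NEGATIVE} <= present:
            raise ValueError("both fracture and non_fracture must be present")
        self.matrix = matrix
        self.alpha = alpha
        n = matrix.matrix.shape[0]
        self.max_components = (
            min(n - 2, 50) if max_components is None else min(max_components, n - 1)
        )

    def fit(self) -> PCLDAResults:
        X = self.matrix.matrix
        labels = self.matrix.labels
        mean = X.mean(axis=0)
        loadings, explained, scores = fit_pca(X - mean, self.max_components)
        F, p, selected = anova_select(scores, labels, self.alpha)
        fallback = False
        if selected.size == 0:
            selected = np.array([int(np.argmin(p))])
            fallback = True
        w, threshold = fit_lda(scores[:, selected], labels)
        return PCLDAResults(
            mean_spectrum=mean,
            loadings=loadings,
            explained_variance=explained,
            scores=scores,
            pc_pvalues=p,
            pc_fvalues=F,
            selected=selected,
            ld_weights=w,
            threshold=threshold,
            channel_grid=self.matrix.channel_grid,
            fallback_used=fallback,
            alpha=self.alpha,
        )


@dataclass
class CVResult:
    """Cross-validation outcome: per-sample records and summary rates."""

    records: pd.DataFrame
    mode: str

    def __post_init__(self):
        needed = {"sample_id", "patient_id", "true_group", "ld_score", "predicted", "fold"}
        if not needed <= set(self.records.columns):
            raise ValueError(f"records missing columns {needed - set(self.records.columns)}")

    @property
    def confusion(self) -> dict:
        t, p = self.records["true_group"], self.records["predicted"]
        return {
            "TP": int(((t == POSITIVE) & (p == POSITIVE)).sum()),
            "FN": int(((t == POSITIVE) & (p == NEGATIVE)).sum()),
            "TN": int(((t == NEGATIVE) & (p == NEGATIVE)).sum()),
            "FP": int(((t == NEGATIVE) & (p == POSITIVE)).sum()),
        }

    @property
    def sensitivity(self) -> float:
        c = self.confusion
        return 100.0 * c["TP"] / (c["TP"] + c["FN"])

    @property
    def specificity(self) -> float:
        c = self.confusion
        return 100.0 * c["TN"] / (c["TN"] + c["FP"])

    @property
    def accuracy(self) -> float:
        c = self.confusion
        n = sum(c.values())
        return 100.0 * (c["TP"] + c["TN"]) / n

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def summary(self) -> str:
        c = self.confusion
        return "\n".join(
            [
                f"Cross-validation ({self.mode}), {self.records['fold'].nunique()} folds,"
                f" {len(self.records)} samples",
                f"  confusion (fracture positive): TP={c['TP']} FN={c['FN']}"
                f" TN={c['TN']} FP={c['FP']}",
                f"  sensitivity: {self.sensitivity:.1f}%",
                f"  specificity: {self.specificity:.1f}%",
            ]
        )


def cross_validate(
    matrix: CohortMatrix,
    mode: str = "sample",
    alpha: float = 0.05,
    max_components: int | None = None,
) -> CVResult:
    """Leakage-free leave-one-out cross-validation of the PC-LDA chain.

    ``mode="sample"`` holds out one sample per fold; ``mode="patient"`` holds
    out every sample of one patient per fold, so nothing from the test
    patient informs training.  Centring, PCA, ANOVA selection and LDA are all
    recomputed on each fold's training set.
    """
    if mode not in ("sample", "patient"):
        raise ValueError("mode must be 'sample' or 'patient'")
    t = matrix.table.table
    labels = matrix.labels
    if mode == "sample":
        fold_keys = t["sample_id"].to_numpy()
        fold_of = fold_keys
    else:
        fold_of = t["patient_id"].to_numpy()
        fold_keys = pd.unique(fold_of)
    records = []
    for fold in fold_keys:
        test_mask = fold_of == fold
        train_mask = ~test_mask
        train_labels = labels[train_mask]
        for g in (POSITIVE, NEGATIVE):
            if (train_labels == g).sum() < 2:
                raise ValueError(
                    f"fold {fold!r} leaves group {g!r} with fewer than 2 training samples"
                )
        res = PCLDA(
            matrix.subset(train_mask), alpha=alpha, max_components=max_components
        ).fit()
        s, pred = res.predict(matrix.matrix[test_mask])
        for row, score, label in zip(
            t[test_mask].itertuples(index=False), s, pred
        ):
            records.append(
                {
                    "sample_id": row.sample_id,
                    "patient_id": row.patient_id,
                    "true_group": row.group,
                    "sex": row.sex,
                    "ld_score": float(score),
                    "predicted": label,
                    "fold": fold,
                }
            )
    return CVResult(records=pd.DataFrame(records), mode=f"leave_one_{mode}_out")


def subset_by_sex(matrix: CohortMatrix, sex: str) -> CohortMatrix:
    """Restrict the cohort to one sex; each group must keep >= 3 samples."""
    mask = matrix.table.table["sex"].to_numpy() == sex
    if not mask.any():
        raise ValueError(f"no samples with sex {sex!r}")
    sub = matrix.subset(mask)
    for g in (POSITIVE, NEGATIVE):
        if (sub.labels == g).sum() < 3:
            raise ValueError(f"sex subset leaves group {g!r} with < 3 samples")
    return sub


def permutation_null_accuracies(
    matrix: CohortMatrix,
    n_permutations: int,
    seed: int,
    mode: str = "sample",
    alpha: float = 0.05,
    max_components: int | None = None,
) -> np.ndarray:
    """CV accuracies (%) under random relabelling of the group column.

    Labels are permuted at the patient level (every sample of a patient keeps
    one common label), which preserves the patient->group invariant and
    respects the exchangeability unit.  Permutation breaks any
    label/spectrum association, so a leakage-free pipeline must score near
    chance on every permutation.
    """
    from .io import CohortTable

    rng = np.random.default_rng(seed)
    base = matrix.table.table
    patients = base.drop_duplicates("patient_id")[["patient_id", "group"]]
    pids = patients["patient_id"].to_numpy()
    pgroups = patients["group"].to_numpy()
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted = dict(zip(pids, rng.permutation(pgroups)))
        perm = base.copy()
        perm["group"] = perm["patient_id"].map(permuted)
        m = CohortMatrix(
            matrix=matrix.matrix,
            channel_grid=matrix.channel_grid,
            table=CohortTable(perm),
            mean_spectrum=None,
        )
        out[i] = cross_validate(
            m, mode=mode, alpha=alpha, max_components=max_components
        ).accuracy
    return out
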