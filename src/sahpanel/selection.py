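"""Key-gene screening: SVM-RFE, t/F testing, cross-arm intersection, SPCA.

The workflow that narrows a genome-wide matrix to a compact biomarker
panel has three modules:

1. *Disease-arm screen*: a strict moderated-t filter (fold change >= 2,
   p < 0.05) intersected with the top-k genes of an SVM recursive feature
   elimination ranking, the intersection then tested by t/F tests, and
   probe ids mapped to gene ids.
2. *Intervention-arm screen*: t/F tests of the stage-1 genes in each
   treatment-vs-control contrast, then the intersection across contrasts.
3. *Dimension reduction*: sparse PCA over the intersection genes; the
   union of nonzero-loading genes is the candidate panel. A final
   curated allow-list (standing in for manual literature review) may
   further restrict it.

SVM-RFE scores each surviving feature by the drop in the margin
objective when the feature is removed from the kernel,
``DJ(i) = 1/2 a'Ka - 1/2 a'K(-i)a`` with the dual coefficients ``a``
frozen from the full fit (the classic RFE approximation); for a linear
kernel this reduces to half the squared primal weight.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.svm import SVC

from .datasets import ExpressionDataset, map_probes_to_genes
from .diffexpr import Contrast, moderated_t_test, select_de_genes


# ---------------------------------------------------------------------------
# SVM-RFE


@dataclasses.dataclass
class RFEState:
    """Outcome of a recursive-elimination run."""

    surviving_features: list[str]
    alpha: np.ndarray
    kernel: str
    dj_scores: np.ndarray
    removal_log: list[tuple[int, list[str]]]
    ranking: list[str]  # best first; reconstructed from survivors + removal log


class SVMRFE(BaseEstimator):
    """Recursive feature elimination driven by a maximum-margin classifier.

    Parameters
    ----------
    kernel : {"linear", "rbf"}
    k_keep : int
        Stop when this many features survive.
    step : int or float
        Features removed per iteration; a float in (0, 1) removes that
        fraction of the surviving features (at least one) per iteration.
    C, gamma
        Passed to the underlying SVC.
    standardize : bool
        Standardize each feature to zero mean / unit variance before
        training (constant features are left at zero).

    Attributes (after fit): ``ranking_`` (feature names, best first),
    ``surviving_``, ``dj_scores_``, ``removal_log_``, ``state_``.
    """

    def __init__(self, kernel="linear", k_keep=100, step=1, C=1.0, gamma="scale", standardize=True):
        self.kernel = kernel
        self.k_keep = k_keep
        self.step = step
        self.C = C
        self.gamma = gamma
        self.standardize = standardize

    def _dj(self, X: np.ndarray, y_pm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Margin-objective drop per feature, with the dual coefficients
        frozen from the full-feature fit. Returns (dj, dual coefficients)."""
        svc = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
        svc.fit(X, y_pm)
        a = svc.dual_coef_.ravel()  # alpha_s * y_s over support vectors
        sv = X[svc.support_]
        if self.kernel == "linear":
            w = sv.T @ a
            return 0.5 * w**2, a
        gamma = svc._gamma
        sq = (sv[:, None, :] - sv[None, :, :]) ** 2
        K = np.exp(-gamma * sq.sum(axis=2))
        base = a @ K @ a
        dj = np.empty(X.shape[1])
        for i in range(X.shape[1]):
            K_wo = np.exp(-gamma * (sq.sum(axis=2) - sq[:, :, i]))
            dj[i] = 0.5 * (base - a @ K_wo @ a)
        return dj, a

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"SVM-RFE needs exactly two classes, got {classes.size}")
        y_pm = np.where(y == classes[1], 1, -1)
        n, p = X.shape
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(p)]
        feature_names = list(feature_names)

        if self.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            X = (X - mu) / sd

        if self.k_keep >= p:
            warnings.warn("k_keep >= number of features; ranking without elimination")

        surviving = list(range(p))
        removal_log: list[tuple[int, list[str]]] = []
        removed_order: list[int] = []
        iteration = 0
        dj = np.zeros(p)
        a = np.zeros(0)
        while True:
            dj, a = self._dj(X[:, surviving], y_pm)
            n_remove = len(surviving) - self.k_keep
            if n_remove <= 0:
                break
            if isinstance(self.step, float) and 0 < self.step < 1:
                step = max(1, int(self.step * len(surviving)))
            else:
                step = max(1, int(self.step))
            n_remove = min(step, n_remove)
            # lowest DJ first; ties broken by feature name ascending
            order = sorted(
                range(len(surviving)), key=lambda j: (dj[j], feature_names[surviving[j]])
            )
            drop = sorted(order[:n_remove], reverse=True)
            removed_names = []
            for j in drop:
                removed_order.append(surviving[j])
                removed_names.append(feature_names[surviving[j]])
            removal_log.append((iteration, sorted(removed_names)))
            for j in drop:
                del surviving[j]
            iteration += 1

        surv_order = sorted(
            range(len(surviving)),
            key=lambda j: (-dj[j], feature_names[surviving[j]]),
        )
        ranking_idx = [surviving[j] for j in surv_order] + removed_order[::-1]

        self.surviving_ = [feature_names[i] for i in surviving]
        self.dj_scores_ = dj
        self.removal_log_ = removal_log
        self.ranking_ = [feature_names[i] for i in ranking_idx]
        self.state_ = RFEState(
            surviving_features=list(self.surviving_),
            alpha=a,
            kernel=self.kernel,
            dj_scores=dj,
            removal_log=removal_log,
            ranking=list(self.ranking_),
        )
        return self


def svm_rfe_rank(
    dataset: ExpressionDataset,
    labels: Mapping[str, int] | Sequence[int],
    kernel: str = "linear",
    k_keep: int = 100,
    step: int | float = 1,
) -> RFEState:
    """Rank the dataset's genes (features) for separating the two sample
    classes. ``labels`` is per-sample, either a sequence aligned with the
    sample order or a mapping sample id -> label."""
    if isinstance(labels, Mapping):
        y = np.array([labels[s] for s in dataset.sample_ids])
    else:
        y = np.asarray(list(labels))
    X = dataset.values.to_numpy(dtype=float).T  # samples x genes
    rfe = SVMRFE(kernel=kernel, k_keep=k_keep, step=step)
    rfe.fit(X, y, feature_names=dataset.gene_ids)
    return rfe.state_


# ---------------------------------------------------------------------------
# t / F testing


def t_and_f_test(
    dataset: ExpressionDataset,
    contrast: Contrast,
    genes: Iterable[str] | None = None,
    alpha_level: float = 0.05,
    require_both: bool = False,
) -> pd.DataFrame:
    """Variance-routed two-sample testing per gene.

    A two-sided F test compares group variances; where it rejects at
    ``alpha_level`` the unequal-variance (Welch) t is used, otherwise the
    pooled t. A gene is significant when its t-test p < ``alpha_level``
    (and, with ``require_both``, the F test also rejects).
    """
    if genes is not None:
        dataset = dataset.subset_genes(genes)
    ids_a = dataset.samples_in_group(contrast.group_a)
    ids_b = dataset.samples_in_group(contrast.group_b)
    na, nb = len(ids_a), len(ids_b)
    if na < 2 or nb < 2:
        raise ValueError(f"contrast {contrast.name}: need >=2 samples per group")
    a = dataset.values[ids_a].to_numpy(dtype=float)
    b = dataset.values[ids_b].to_numpy(dtype=float)

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = var_a / var_b
    f_cdf = stats.f.cdf(F, na - 1, nb - 1)
    f_p = np.clip(2.0 * np.minimum(f_cdf, 1.0 - f_cdf), 0.0, 1.0)
    both_flat = (var_a == 0) & (var_b == 0)
    f_p = np.where(both_flat, 1.0, f_p)

    welch = f_p < alpha_level
    with np.errstate(divide="ignore", invalid="ignore"):
        t_pool, p_pool = stats.ttest_ind(a, b, axis=1, equal_var=True)
        t_welch, p_welch = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.where(welch, t_welch, t_pool)
    t_p = np.where(welch, p_welch, p_pool)
    flat_equal = both_flat & (a.mean(axis=1) == b.mean(axis=1))
    t = np.where(flat_equal, 0.0, t)
    t_p = np.where(flat_equal, 1.0, np.nan_to_num(t_p, nan=1.0))

    significant = t_p < alpha_level
    if require_both:
        significant &= welch | both_flat
    return pd.DataFrame(
        {
            "t_stat": t,
            "t_p": t_p,
            "f_p": f_p,
            "variance_mode": np.where(welch, "welch", "pooled"),
            "significant": significant,
        },
        index=dataset.gene_ids,
    )


# ---------------------------------------------------------------------------
# Stage 1 (disease-arm screen)


@dataclasses.dataclass
class Stage1Result:
    ebayes_probes: set[str]
    rfe_top_probes: set[str]
    rfe_significant_probes: set[str]
    stage1_probes: set[str]
    stage1_genes: list[str]
    rfe_state: RFEState | None


def stage1_select(
    dataset_chip: ExpressionDataset,
    contrast: Contrast,
    annotation: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    top_k: int = 100,
    rfe_step: int | float = 0.5,
    alpha_level: float = 0.05,
    rfe_on: str = "ebayes",
) -> Stage1Result:
    """Strict moderated-t filter intersected with the SVM-RFE screen.

    ``rfe_on`` controls the domain of the elimination: ``"ebayes"``
    (default) ranks only the probes passing the strict moderated-t
    filter — with ten samples against tens of thousands of probes a
    whole-matrix elimination ranks mostly noise, so the margin ranking is
    applied where it is informative; ``"all"`` ranks the full matrix
    (fractional ``rfe_step`` keeps that tractable). t/F tests are run on
    the top ``top_k`` ranked probes, and probes significant in both
    routes are mapped to de-duplicated gene ids.
    """
    de_table = moderated_t_test(dataset_chip, contrast)
    annotated, _, _ = select_de_genes(de_table, fc_threshold, p_threshold, use_adjusted=False)
    ebayes_probes = set(annotated.index[annotated["passes_filter"]])

    labels = {
        s: 1 if g == contrast.group_a else 0
        for s, g in zip(dataset_chip.metadata["sample_id"], dataset_chip.metadata["group"])
    }
    if rfe_on == "ebayes":
        rfe_input = dataset_chip.subset_genes(sorted(ebayes_probes))
        if rfe_input.n_genes == 0:
            warnings.warn("stage-1 intersection is empty")
            return Stage1Result(ebayes_probes, set(), set(), set(), [], None)
    elif rfe_on == "all":
        rfe_input = dataset_chip
    else:
        raise ValueError("rfe_on must be 'ebayes' or 'all'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k_keep >= n_features is routine here
        state = svm_rfe_rank(rfe_input, labels, kernel="linear", k_keep=top_k, step=rfe_step)
    rfe_top = state.ranking[:top_k]

    tf = t_and_f_test(dataset_chip, contrast, genes=rfe_top, alpha_level=alpha_level)
    rfe_sig = set(tf.index[tf["significant"]])

    stage1_probes = ebayes_probes & rfe_sig
    if not stage1_probes:
        warnings.warn("stage-1 intersection is empty")
    ordered = [p for p in rfe_top if p in stage1_probes]
    genes = map_probes_to_genes(ordered, annotation)
    return Stage1Result(
        ebayes_probes=ebayes_probes,
        rfe_top_probes=set(rfe_top),
        rfe_significant_probes=rfe_sig,
        stage1_probes=stage1_probes,
        stage1_genes=genes,
        rfe_state=state,
    )


def cross_arm_intersect(per_arm_sets: Mapping[str, Iterable[str]]) -> list[str]:
    """Intersection of per-contrast significant gene sets, sorted by id."""
    if len(per_arm_sets) < 2:
        raise ValueError("need at least two contrasts to intersect")
    sets = [set(s) for s in per_arm_sets.values()]
    out = set.intersection(*sets)
    return sorted(out)


# ---------------------------------------------------------------------------
# Sparse PCA


@dataclasses.dataclass
class SparseLoadings:
    components: np.ndarray  # n_components x n_genes
    sparsity: float
    selected_genes: list[str]
    explained_variance_ratio: np.ndarray
    converged: bool


def _soft(z: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


class SparsePCA(BaseEstimator, TransformerMixin):
    """Sparse principal components by alternating minimization.

    The elastic-net reformulation of PCA is solved in its
    covariance form: with ``S = X'X / n`` and an orthonormal ``A``
    fixed, each loading vector is a penalized regression whose
    ridge-dominant solution is the soft-thresholded projection
    ``b_j = soft(S a_j, sparsity)``; with ``B`` fixed, ``A`` is updated
    from the SVD of ``S B`` (the Procrustes step). ``sparsity = 0``
    recovers ordinary PCA loadings.

    Attributes after fit: ``components_`` (n_components x n_features,
    unit-norm rows where nonzero), ``selected_`` (boolean feature mask),
    ``explained_variance_ratio_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, n_components=2, sparsity=0.0, max_iter=500, tol=1e-8):
        self.n_components = n_components
        self.sparsity = sparsity
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        k = self.n_components
        if k > min(n, p):
            raise ValueError("n_components exceeds matrix rank bound")
        Xc = X - X.mean(axis=0)
        S = (Xc.T @ Xc) / n
        # initialize A with the ordinary principal directions
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        A = Vt[:k].T  # p x k
        B = np.zeros((p, k))
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            B_new = _soft(S @ A, self.sparsity)
            if not np.any(B_new):
                B = B_new
                converged = True
                break
            M = S @ B_new
            U, _, Vt_m = np.linalg.svd(M, full_matrices=False)
            A = U @ Vt_m
            delta = np.max(np.abs(_normalize_cols(B_new) - _normalize_cols(B)))
            B = B_new
            if delta < self.tol:
                converged = True
                break
        B = _normalize_cols(B)
        self.components_ = B.T
        self.selected_ = np.any(B != 0, axis=1)
        scores = Xc @ B
        total = np.sum(Xc**2)
        self.explained_variance_ratio_ = (
            np.sum(scores**2, axis=0) / total if total > 0 else np.zeros(k)
        )
        self.n_iter_ = it
        self.converged_ = converged
        self.mean_ = X.mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


def _normalize_cols(B: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(B, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return B / norms


def spca_reduce(
    dataset: ExpressionDataset,
    genes: Sequence[str],
    n_components: int = 2,
    sparsity: float | None = None,
    max_genes: int = 5,
) -> SparseLoadings:
    """Sparse-PCA reduction of a gene panel.

    Samples are observations, the listed genes are features (centered,
    not rescaled, so genes with larger between-group swing carry larger
    loadings). When ``sparsity`` is None a descending grid is searched
    and the smallest penalty whose support has at most ``max_genes``
    genes is kept (maximizing explained variance subject to the support
    budget).
    """
    sub = dataset.subset_genes(genes)
    if sub.n_genes < n_components:
        raise ValueError("gene set smaller than n_components")
    X = sub.values.to_numpy(dtype=float).T  # samples x genes

    if sparsity is None:
        Xc = X - X.mean(axis=0)
        lam_max = float(np.abs((Xc.T @ Xc) / X.shape[0]).max()) or 1.0
        grid = lam_max * np.linspace(0.02, 1.0, 40)
        chosen = grid[-1]
        for lam in grid:
            est = SparsePCA(n_components=n_components, sparsity=float(lam)).fit(X)
            if int(est.selected_.sum()) <= max_genes:
                chosen = float(lam)
                break
        sparsity = chosen

    est = SparsePCA(n_components=n_components, sparsity=float(sparsity)).fit(X)
    selected = [g for g, keep in zip(sub.gene_ids, est.selected_) if keep]
    return SparseLoadings(
        components=est.components_,
        sparsity=float(sparsity),
        selected_genes=selected,
        explained_variance_ratio=est.explained_variance_ratio_,
        converged=est.converged_,
    )


# ---------------------------------------------------------------------------
# Panel report


@dataclasses.dataclass
class PanelReport:
    """All intermediate gene sets of the screening workflow.

    Invariant (checked by :meth:`validate`):
    ``final_panel <= spca_candidates <= intersection_set <= stage1_set``.
    """

    ebayes_set: set[str]
    rfe_top_set: set[str]
    stage1_set: set[str]
    per_arm_significant: dict[str, set[str]]
    intersection_set: set[str]
    spca_candidates: set[str]
    final_panel: set[str]

    def validate(self) -> None:
        assert self.final_panel <= self.spca_candidates, "final panel not within SPCA candidates"
        assert self.spca_candidates <= self.intersection_set, "SPCA candidates not within intersection"
        assert self.intersection_set <= self.stage1_set, "intersection not within stage-1 set"

    def to_json(self) -> dict:
        return {
            "ebayes_set": sorted(self.ebayes_set),
            "rfe_top_set": sorted(self.rfe_top_set),
            "stage1_set": sorted(self.stage1_set),
            "per_arm_significant": {c: sorted(s) for c, s in self.per_arm_significant.items()},
            "intersection_set": sorted(self.intersection_set),
            "spca_candidates": sorted(self.spca_candidates),
            "final_panel": sorted(self.final_panel),
        }


def apply_allowlist(candidates: Iterable[str], allowlist: Iterable[str] | None) -> list[str]:
    """Curated filter standing in for manual literature review; ``None``
    keeps every candidate."""
    candidates = sorted(candidates)
    if allowlist is None:
        return candidates
    allowed = set(allowlist)
    return [g for g in candidates if g in allowed]
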