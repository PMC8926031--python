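"""Outcome classification with a multi-kernel SVM under nested LOOCV.

Three feature blocks per subject feed three linear kernels:

* connection weights -- the n(n-1)/2 upper-triangle entries of the
  individual metabolic network (4005 at the 90-region parcellation),
* global graph metrics -- the 11 sparsity-AUC global features,
* nodal graph metrics -- the 5 x n nodal sparsity-AUC features.

The multi-kernel SVM (MK-SVM) solves the standard SVM dual on the
convex kernel combination K = sum_m beta_m K_m (beta_m >= 0, sum = 1);
the decision function is f(x) = sign(sum_i y_i alpha_i sum_m beta_m
k_m(x_i, x) + b). Hyperparameters (C in 2^-5..2^5, beta on a simplex
grid) are chosen by an inner leave-one-out loop on each outer training
set; feature selection (two-sample t test, p < 0.05) and per-feature
standardization are computed on outer-training data only, so the
held-out subject never influences any training-fold computation.

The positive class is SZF (seizure free), encoded +1.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

try:  # low-level libsvm binding: same solver as SVC, ~25x less overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - exercised only on older sklearn
    _libsvm = None

__all__ = [
    "FeatureBundle",
    "MKSVMModel",
    "CVResult",
    "ttest_select",
    "linear_kernel",
    "beta_simplex_grid",
    "default_C_grid",
    "mksvm_train",
    "mksvm_predict",
    "nested_loocv",
    "consensus_connections",
    "performance",
    "delong_test",
    "bundle_from_network",
]

POSITIVE_LABEL = 1   # SZF
NEGATIVE_LABEL = -1  # SZR

GROUP_TO_LABEL = {"SZF": POSITIVE_LABEL, "SZR": NEGATIVE_LABEL}


@dataclass
class FeatureBundle:
    """One subject's three feature blocks and outcome label."""

    subject_id: str
    connection: np.ndarray  # x1: upper-triangle connection weights
    global_metrics: np.ndarray  # x2: 11 global AUC features
    nodal: np.ndarray  # x3: 5 x n_nodes nodal AUC features
    label: int  # +1 = SZF, -1 = SZR

    def __post_init__(self) -> None:
        self.connection = np.asarray(self.connection, dtype=np.float64).ravel()
        self.global_metrics = np.asarray(self.global_metrics,
                                         dtype=np.float64).ravel()
        self.nodal = np.asarray(self.nodal, dtype=np.float64).ravel()
        if self.label not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ValueError("label must be +1 (SZF) or -1 (SZR)")
        for name, block in (("connection", self.connection),
                            ("global_metrics", self.global_metrics),
                            ("nodal", self.nodal)):
            if not np.all(np.isfinite(block)):
                raise ValueError(f"non-finite values in {name} block")


def bundle_from_network(
    network,
    group: str,
    n_nulls: int = 20,
    seed: int = 0,
) -> FeatureBundle:
    """Assemble a FeatureBundle from a MetabolicNetwork via the
    sparsity-AUC feature extraction."""
    from .graphmetrics import GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES, auc_features

    global_auc, nodal_auc = auc_features(network, n_nulls=n_nulls, seed=seed)
    return FeatureBundle(
        subject_id=getattr(network, "subject_id", "subject"),
        connection=network.upper_triangle(),
        global_metrics=np.array([global_auc[m] for m in GLOBAL_METRIC_NAMES]),
        nodal=np.concatenate([nodal_auc[m] for m in NODAL_METRIC_NAMES]),
        label=GROUP_TO_LABEL[group],
    )


def ttest_select(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Mask of features with two-sample pooled-variance t-test p < alpha.

    Computed column-wise on training data only; features with no
    between-group variance (undefined t) are excluded.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    pos, neg = X[y == POSITIVE_LABEL], X[y == NEGATIVE_LABEL]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to run the t test")
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # constant features trigger a precision warning and a NaN p;
        # both resolve to "not selected"
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(pos, neg, axis=0, equal_var=True)
    p = np.asarray(p)
    mask = np.zeros(X.shape[1], dtype=bool)
    valid = np.isfinite(p)
    mask[valid] = p[valid] < alpha
    return mask


def linear_kernel(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """k(x, x') = x^T x', entrywise over the rows of A and B."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    return A @ B.T


def default_C_grid() -> np.ndarray:
    """Powers of two from 2^-5 to 2^5 (11 values)."""
    return 2.0 ** np.arange(-5, 6)


def beta_simplex_grid(step: float = 0.1) -> list[tuple[float, float, float]]:
    """Kernel-weight triples (b1, b2, b3) >= 0 with b1+b2+b3 = 1 on a
    regular simplex lattice (66 points at step 0.1, 15 at step 0.25)."""
    k = int(round(1.0 / step))
    grid = []
    for i in range(k + 1):
        for j in range(k - i + 1):
            grid.append((i / k, j / k, (k - i - j) / k))
    return grid


@dataclass
class MKSVMModel:
    """Trained MK-SVM: dual coefficients on the combined kernel."""

    alphas: np.ndarray  # alpha_i >= 0, one per training sample
    bias: float
    betas: tuple[float, ...]
    C: float
    train_labels: np.ndarray
    support: np.ndarray  # indices with alpha_i > 0

    def __post_init__(self) -> None:
        if np.any(self.alphas < -1e-9) or np.any(self.alphas > self.C + 1e-6):
            raise ValueError("dual coefficients violate 0 <= alpha <= C")
        balance = float(np.dot(self.alphas, self.train_labels))
        if abs(balance) > 1e-6:
            raise ValueError(f"sum alpha_i y_i = {balance} not ~ 0")


def _combine(kernels: Sequence[np.ndarray], betas: Sequence[float]) -> np.ndarray:
    if len(kernels) != len(betas):
        raise ValueError("one beta per kernel required")
    betas = np.asarray(betas, dtype=np.float64)
    if np.any(betas < 0) or abs(betas.sum() - 1.0) > 1e-9:
        raise ValueError("betas must be non-negative and sum to 1")
    out = np.zeros_like(np.asarray(kernels[0], dtype=np.float64))
    for b, K in zip(betas, kernels):
        if b:
            out = out + b * np.asarray(K, dtype=np.float64)
    return out


def mksvm_train(
    kernels: Sequence[np.ndarray],
    y: np.ndarray,
    betas: Sequence[float],
    C: float,
) -> MKSVMModel:
    """Solve the MK-SVM dual on the combined kernel K = sum_m beta_m K_m."""
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if C <= 0:
        raise ValueError("C must be positive")
    K = _combine(kernels, betas)
    if np.abs(K - K.T).max() > 1e-8:
        raise ValueError("combined kernel is not symmetric")
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(K, y)
    alphas = np.zeros(len(y))
    # dual_coef_ stores y_i * alpha_i for support vectors
    alphas[svc.support_] = np.abs(svc.dual_coef_[0])
    return MKSVMModel(
        alphas=alphas,
        bias=float(svc.intercept_[0]),
        betas=tuple(float(b) for b in betas),
        C=float(C),
        train_labels=y.astype(int),
        support=svc.support_.copy(),
    )


def mksvm_predict(
    model: MKSVMModel, test_kernels: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and labels for test samples.

    ``test_kernels[m]`` has shape (n_test, n_train): the m-th kernel
    between each test sample and every training sample. sign(0) maps
    to +1.
    """
    K = _combine(test_kernels, model.betas)
    if K.shape[1] != len(model.alphas):
        raise ValueError("test kernel does not match training set size")
    coef = model.alphas * model.train_labels
    decision = K @ coef + model.bias
    labels = np.where(decision >= 0, POSITIVE_LABEL, NEGATIVE_LABEL)
    return labels, decision


@dataclass
class FoldRecord:
    test_index: int
    subject_id: str
    true_label: int
    predicted: int
    decision: float
    C: float
    betas: tuple[float, float, float]
    connection_mask: np.ndarray
    nodal_mask: np.ndarray


@dataclass
class CVResult:
    """Nested-LOOCV output: per-fold records and pooled performance."""

    folds: list[FoldRecord]
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray]
    consensus: list[tuple[int, int]]
    region_names: Optional[list[str]] = None
    config: dict = field(default_factory=dict)

    @property
    def predictions(self) -> np.ndarray:
        return np.array([f.predicted for f in self.folds])

    @property
    def decisions(self) -> np.ndarray:
        return np.array([f.decision for f in self.folds])

    @property
    def labels(self) -> np.ndarray:
        return np.array([f.true_label for f in self.folds])

    def consensus_names(self) -> list[tuple[str, str]]:
        if self.region_names is None:
            return [(f"ROI{i + 1:03d}", f"ROI{j + 1:03d}")
                    for i, j in self.consensus]
        return [(self.region_names[i], self.region_names[j])
                for i, j in self.consensus]

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "config": self.config,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "consensus": [list(pair) for pair in self.consensus],
            "consensus_names": [list(p) for p in self.consensus_names()],
            "folds": [
                {
                    "test_index": f.test_index,
                    "subject_id": f.subject_id,
                    "true_label": f.true_label,
                    "predicted": f.predicted,
                    "decision": f.decision,
                    "C": f.C,
                    "betas": list(f.betas),
                    "n_connections_selected": int(f.connection_mask.sum()),
                    "n_nodal_selected": int(f.nodal_mask.sum()),
                }
                for f in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _svm_dual_fit(K: np.ndarray, y: np.ndarray, C: float):
    """(y_i alpha_i coefficient vector, bias) of an SVM on kernel K.

    Uses the low-level libsvm binding when available (identical solver
    to SVC with the wrapper overhead stripped); falls back to SVC. The
    decision value of a test row k is ``k @ coef + bias``.
    """
    if _libsvm is not None:
        yenc = np.where(y > 0, 1.0, 0.0)
        model = _libsvm.fit(np.ascontiguousarray(K), yenc, svm_type=0,
                            kernel="precomputed", C=float(C))
        coef = np.zeros(len(y))
        coef[model[0]] = -model[3][0]
        return coef, -float(model[4][0])
    svc = SVC(C=C, kernel="precomputed").fit(K, y)
    coef = np.zeros(len(y))
    coef[svc.support_] = svc.dual_coef_[0]
    return coef, float(svc.intercept_[0])


def _fit_predict_subset(K, y, train_idx, test_idx, C):
    """Fit an SVM on the kernel restricted to train_idx, predict test_idx."""
    ytr = y[train_idx]
    if len(np.unique(ytr)) < 2:
        # degenerate inner fold: predict the only class seen
        return np.full(len(test_idx), int(ytr[0]))
    coef, bias = _svm_dual_fit(K[np.ix_(train_idx, train_idx)], ytr, C)
    dec = K[np.ix_(test_idx, train_idx)] @ coef + bias
    return np.where(dec >= 0, POSITIVE_LABEL, NEGATIVE_LABEL)


def nested_loocv(
    cohort: Sequence[FeatureBundle],
    C_grid: Optional[np.ndarray] = None,
    beta_grid: Optional[Sequence[tuple[float, float, float]]] = None,
    alpha: float = 0.05,
    region_names: Optional[list[str]] = None,
) -> CVResult:
    """Nested leave-one-out cross-validation of the MK-SVM.

    Outer loop: each subject held out once. Per outer training set:
    t-test masks (connection and nodal blocks; the global block is
    always retained), per-feature z-scoring with training statistics,
    then an inner LOOCV grid search over (C, beta) choosing the highest
    inner accuracy (ties: smaller C, then earlier beta in grid order).
    The final model is refit on the full outer-training set and scored
    on the held-out subject.
    """
    n = len(cohort)
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    y = np.array([s.label for s in cohort])
    if len(np.unique(y)) < 2:
        raise ValueError("cohort contains a single class")
    if C_grid is None:
        C_grid = default_C_grid()
    if beta_grid is None:
        beta_grid = beta_simplex_grid(0.1)

    Xc = np.vstack([s.connection for s in cohort])
    Xg = np.vstack([s.global_metrics for s in cohort])
    Xn = np.vstack([s.nodal for s in cohort])

    folds: list[FoldRecord] = []
    for held_out in range(n):
        train = np.array([i for i in range(n) if i != held_out])
        ytr = y[train]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"outer training fold {held_out} is single-class")

        conn_mask = ttest_select(Xc[train], ytr, alpha)
        nodal_mask = ttest_select(Xn[train], ytr, alpha)
        blocks_tr, blocks_te = [], []
        for X, mask in ((Xc, conn_mask), (Xg, None), (Xn, nodal_mask)):
            cols = X[:, mask] if mask is not None else X
            tr, te = _standardize(cols[train], cols[[held_out]])
            blocks_tr.append(tr)
            blocks_te.append(te)

        train_kernels = [linear_kernel(b, b) for b in blocks_tr]
        m = len(train)
        inner_idx = np.arange(m)
        best = None  # (accuracy, C, betas)
        for betas in beta_grid:
            K = _combine(train_kernels, betas)
            for C in C_grid:
                correct = 0
                for j in range(m):
                    tr_j = np.delete(inner_idx, j)
                    pred = _fit_predict_subset(K, ytr, tr_j, [j], C)
                    correct += int(pred[0] == ytr[j])
                acc = correct / m
                if best is None or acc > best[0] + 1e-12 or (
                    abs(acc - best[0]) <= 1e-12
                    and (C < best[1] - 1e-12)
                ):
                    best = (acc, float(C), betas)
        _, C_star, betas_star = best

        model = mksvm_train(train_kernels, ytr, betas_star, C_star)
        test_kernels = [linear_kernel(te, tr)
                        for te, tr in zip(blocks_te, blocks_tr)]
        pred, dec = mksvm_predict(model, test_kernels)
        folds.append(FoldRecord(
            test_index=held_out,
            subject_id=cohort[held_out].subject_id,
            true_label=int(y[held_out]),
            predicted=int(pred[0]),
            decision=float(dec[0]),
            C=C_star,
            betas=betas_star,
            connection_mask=conn_mask,
            nodal_mask=nodal_mask,
        ))

    perf = performance(
        np.array([f.predicted for f in folds]),
        np.array([f.decision for f in folds]),
        y,
    )
    consensus = consensus_connections([f.connection_mask for f in folds])
    return CVResult(
        folds=folds,
        accuracy=perf["accuracy"],
        sensitivity=perf["sensitivity"],
        specificity=perf["specificity"],
        auc=perf["auc"],
        roc=perf["roc"],
        consensus=consensus,
        region_names=region_names,
        config={
            "C_grid": [float(c) for c in C_grid],
            "n_beta_grid": len(beta_grid),
            "alpha": alpha,
        },
    )


def consensus_connections(
    fold_masks: Sequence[np.ndarray],
) -> list[tuple[int, int]]:
    """Connections selected by the t test in every outer fold.

    Returns 0-based (region_i, region_j) index pairs, i < j, decoded
    from the row-major upper-triangle feature layout.
    """
    masks = np.asarray(fold_masks, dtype=bool)
    common = masks.all(axis=0)
    n_pairs = common.size
    # invert n(n-1)/2 to recover the region count
    n = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    if n * (n - 1) // 2 != n_pairs:
        raise ValueError(f"{n_pairs} is not a triangular number")
    iu = np.triu_indices(n, k=1)
    return [(int(iu[0][k]), int(iu[1][k])) for k in np.flatnonzero(common)]


def performance(
    predictions: np.ndarray,
    decision_values: np.ndarray,
    labels: np.ndarray,
) -> dict:
    """Accuracy, sensitivity, specificity (SZF = positive), ROC and AUC.

    The ROC curve is a threshold sweep over the decision values and the
    AUC is the trapezoid area, which equals the normalized Mann-Whitney
    statistic.
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve

    predictions = np.asarray(predictions)
    decision_values = np.asarray(decision_values, dtype=np.float64)
    labels = np.asarray(labels)
    if not (len(predictions) == len(decision_values) == len(labels)):
        raise ValueError("inputs must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to compute performance")
    tp = int(np.sum((predictions == POSITIVE_LABEL) & (labels == POSITIVE_LABEL)))
    fn = int(np.sum((predictions == NEGATIVE_LABEL) & (labels == POSITIVE_LABEL)))
    tn = int(np.sum((predictions == NEGATIVE_LABEL) & (labels == NEGATIVE_LABEL)))
    fp = int(np.sum((predictions == POSITIVE_LABEL) & (labels == NEGATIVE_LABEL)))
    fpr, tpr, _ = roc_curve(labels, decision_values,
                            pos_label=POSITIVE_LABEL)
    return {
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "confusion": {"TP": tp, "FN": fn, "TN": tn, "FP": fp},
        "roc": (fpr, tpr),
        "auc": float(sk_auc(fpr, tpr)),
    }


def _placements(decisions: np.ndarray, labels: np.ndarray):
    x = decisions[labels == POSITIVE_LABEL]
    y = decisions[labels == NEGATIVE_LABEL]
    psi = (x[:, None] > y[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == y[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def delong_test(
    decisions_A: np.ndarray,
    decisions_B: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, float]:
    """DeLong's paired test for the difference of two correlated AUCs.

    Returns (z, two-sided p). The variance of the AUC difference comes
    from the empirical covariance of the placement values; a
    zero-variance difference yields (0, 1) by convention.
    """
    decisions_A = np.asarray(decisions_A, dtype=np.float64)
    decisions_B = np.asarray(decisions_B, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    v10_a, v01_a, auc_a = _placements(decisions_A, labels)
    v10_b, v01_b, auc_b = _placements(decisions_B, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
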