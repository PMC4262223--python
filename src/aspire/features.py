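"""Sample characterization and anomaly detection from cluster proportions.

Once global clusters are recovered, each sample is summarized by the vector
of its global-cluster proportions — a point on the (K-1)-simplex.  Anomaly
detection is a one-class problem solved by *resampling*: a large set of
proportion vectors drawn uniformly from the simplex (a Dirichlet(1,...,1)
sample) forms an artificial positive class, the normal samples form the
negative class, and a linear-kernel support vector machine learns to
separate them.  A test sample whose composition lies outside the region
occupied by normal samples scores positive-like, i.e. anomalous.
Performance is summarized by the area under the ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import MinCovDet
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

from .sampler import ClusteringResult

DEFAULT_N_POSITIVE = 50_000
DEFAULT_COST_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_HOLDOUT_FRACTION = 0.25


@dataclass(eq=False)
class ProportionMatrix:
    """Samples-by-clusters compositional feature matrix (rows sum to 1)."""

    values: np.ndarray
    sample_ids: list[str]
    class_ids: list[int]
    totals: np.ndarray | None = None    # per-sample event totals, if known

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.class_ids)):
            raise ValueError("values shape inconsistent with ids")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")
        rows = self.values.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            bad = self.sample_ids[int(np.argmax(np.abs(rows - 1)))]
            raise ValueError(f"rows must sum to 1 (sample {bad!r})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids: list[str]) -> "ProportionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        totals = None if self.totals is None else self.totals[idx]
        return ProportionMatrix(self.values[idx], list(sample_ids),
                                list(self.class_ids), totals)


@dataclass(eq=False)
class OneClassModel:
    """Linear one-class decision function over proportion vectors.

    The score is affine in the features; higher scores mean more
    anomalous (closer to the uniform-simplex positive class).
    """

    weights: np.ndarray
    bias: float
    cost: float
    n_positive: int
    train_seed: int
    class_ids: list[int] = field(default_factory=list)

    def score(self, features: ProportionMatrix | np.ndarray) -> np.ndarray:
        x = (features.values if isinstance(features, ProportionMatrix)
             else np.asarray(features, dtype=float))
        return x @ self.weights + self.bias


def compute_proportions(result: ClusteringResult,
                        prune_threshold: float = 0.0) -> ProportionMatrix:
    """Per-sample proportions of events over surviving global clusters.

    Classes already pruned in ``result`` and classes below
    ``prune_threshold`` (fraction of all events) are excluded and the rows
    renormalized over the survivors.
    """
    labels = result.labels
    total = labels.size
    ids, counts = np.unique(labels, return_counts=True)
    keep = [int(i) for i, c in zip(ids, counts)
            if c >= prune_threshold * total and i not in result.pruned_class_ids]
    if not keep:
        raise ValueError("pruning removed every class")
    J = result.n_samples
    mat = np.zeros((J, len(keep)))
    col = {k: idx for idx, k in enumerate(keep)}
    for j in range(J):
        seg = labels[result.sample_start[j]:result.sample_start[j + 1]]
        for lab, cnt in zip(*np.unique(seg, return_counts=True)):
            if int(lab) in col:
                mat[j, col[int(lab)]] = cnt
        row = mat[j].sum()
        if row == 0:
            raise ValueError(
                f"sample {result.sample_ids[j]!r} has no events in any "
                f"surviving class")
        mat[j] /= row
    totals = np.diff(result.sample_start).astype(int)
    return ProportionMatrix(mat, list(result.sample_ids), keep, totals)


def sample_uniform_simplex(K: int, N: int = DEFAULT_N_POSITIVE,
                           seed: int = 0) -> np.ndarray:
    """N i.i.d. draws from the uniform distribution on the (K-1)-simplex,
    i.e. Dirichlet with all concentration parameters equal to one."""
    if K < 1 or N < 1:
        raise ValueError("K and N must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(K), size=N)


def train_one_class(normal_features: ProportionMatrix,
                    K: int | None = None,
                    N_pos: int = DEFAULT_N_POSITIVE,
                    cost_grid=DEFAULT_COST_GRID,
                    holdout_fraction: float = DEFAULT_HOLDOUT_FRACTION,
                    seed: int = 0,
                    validation_metric: str = "auc") -> OneClassModel:
    """Train the simplex-resampling one-class classifier.

    ``N_pos`` uniform-simplex draws are labeled positive (anomalous-like),
    the normal samples' proportion vectors negative.  A linear-kernel SVM is
    fitted for each cost in ``cost_grid``; the cost with the best held-out
    validation score (AUC by default, accuracy via
    ``validation_metric="accuracy"``) is retrained on all data.  Class
    weights are balanced to compensate the extreme positive:negative ratio.
    """
    X_neg = normal_features.values
    if X_neg.shape[0] < 2:
        raise ValueError("need at least two normal samples to train")
    K = K or X_neg.shape[1]
    if K != X_neg.shape[1]:
        raise ValueError("K does not match the feature dimension")
    if validation_metric not in ("auc", "accuracy"):
        raise ValueError("validation_metric must be 'auc' or 'accuracy'")
    if np.allclose(X_neg, X_neg[0], atol=1e-12):
        warnings.warn("all normal samples have identical proportion vectors; "
                      "the one-class boundary is poorly determined")
    X_pos = sample_uniform_simplex(K, N_pos, seed)
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(N_pos), np.zeros(X_neg.shape[0])])
    costs = list(cost_grid)
    if len(costs) > 1:
        Xtr, Xval, ytr, yval = train_test_split(
            X, y, test_size=holdout_fraction, random_state=seed, stratify=y)
        scored = []
        for cost in costs:
            clf = LinearSVC(C=cost, class_weight="balanced", dual="auto",
                            max_iter=20000, random_state=seed)
            clf.fit(Xtr, ytr)
            sc = clf.decision_function(Xval)
            if validation_metric == "auc":
                score = roc_auc_score(yval, sc)
            else:
                score = float(np.mean((sc > 0) == (yval == 1)))
            scored.append((score, -abs(np.log10(cost)), cost))
        # ties in the validation score are broken toward the default cost 1
        best_cost = max(scored)[2]
    else:
        best_cost = costs[0]
    clf = LinearSVC(C=best_cost, class_weight="balanced", dual="auto",
                    max_iter=20000, random_state=seed)
    clf.fit(X, y)
    w = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    # ensure higher score == more positive-like (sklearn already orients
    # decision_function toward the positive class label 1)
    return OneClassModel(weights=w, bias=b, cost=float(best_cost),
                         n_positive=N_pos, train_seed=seed,
                         class_ids=list(normal_features.class_ids))


def score_and_auc(model: OneClassModel,
                  test_features: ProportionMatrix,
                  anomaly_flags) -> tuple[np.ndarray, float]:
    """Score test samples and compute the ROC AUC against the given flags.

    The AUC is the Mann-Whitney rank statistic: the probability that a
    random anomalous sample outscores a random normal one, ties counted 1/2.
    """
    flags = np.asarray([bool(f) for f in anomaly_flags])
    if flags.size != test_features.n_samples:
        raise ValueError("anomaly flags do not align with test samples")
    if flags.all() or not flags.any():
        raise ValueError("AUC is undefined with a single class of flags")
    scores = model.score(test_features)
    return scores, float(roc_auc_score(flags.astype(int), scores))


def repeated_one_class_auc(normal_features: ProportionMatrix,
                           test_features: ProportionMatrix,
                           anomaly_flags,
                           n_repeats: int = 10,
                           seed: int = 0,
                           **train_kwargs) -> tuple[float, float, list[float]]:
    """The ten-repetition protocol: retrain with fresh positive draws
    (seeds ``seed .. seed+n_repeats-1``) and report mean and sd of the AUC."""
    aucs = []
    for r in range(n_repeats):
        model = train_one_class(normal_features, seed=seed + r, **train_kwargs)
        _, auc = score_and_auc(model, test_features, anomaly_flags)
        aucs.append(auc)
    return float(np.mean(aucs)), float(np.std(aucs)), aucs


def clr_pca_2d(features: ProportionMatrix,
               zero_replacement: float | None = None,
               robust: bool = True) -> np.ndarray:
    """Two-dimensional compositional PCA coordinates for visualization.

    Zeros are replaced multiplicatively, by default with half of one
    event's worth of that sample's total (``0.5 / n_events``) when totals
    are known and ``0.5 / (10 K)`` otherwise; rows are renormalized, centered-log-ratio transformed, and projected onto
    the top two eigenvectors of a robust (minimum covariance determinant)
    covariance estimate; ``robust=False`` falls back to the sample
    covariance.
    """
    X = features.values.copy()
    J, K = X.shape
    if K < 3:
        raise ValueError("compositional PCA needs at least 3 parts")
    if zero_replacement is None:
        if features.totals is not None:
            repl = 0.5 / np.maximum(features.totals.astype(float), 1.0)
            repl = np.broadcast_to(repl[:, None], X.shape)
        else:
            repl = np.full_like(X, 0.5 / (10 * K))
    else:
        repl = np.full_like(X, float(zero_replacement))
    zero_mask = X <= 0
    if zero_mask.any():
        X[zero_mask] = repl[zero_mask]
    X /= X.sum(axis=1, keepdims=True)
    logx = np.log(X)
    clr = logx - logx.mean(axis=1, keepdims=True)
    center = clr.mean(axis=0)
    Y = clr - center
    if robust and J > K + 2:
        try:
            cov = MinCovDet(random_state=0).fit(clr).covariance_
        except Exception:
            cov = np.cov(clr, rowvar=False)
    else:
        cov = np.cov(clr, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    top = vecs[:, np.argsort(vals)[::-1][:2]]
    return Y @ top


def supervised_classify(features: ProportionMatrix, labels,
                        test_fraction: float = 0.25,
                        n_repeats: int = 10,
                        cost: float = 1.0,
                        seed: int = 0) -> tuple[float, float, list[dict]]:
    """Supervised two-class mode: linear SVM on labeled proportion vectors.

    Repeats a stratified train/test split ``n_repeats`` times with seeds
    ``seed..seed+n_repeats-1`` and reports mean and sd of held-out accuracy
    (in percent) plus a per-split report.
    """
    y = np.asarray([int(bool(l)) for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("supervised mode requires both classes present")
    X = features.values
    reports = []
    accs = []
    for r in range(n_repeats):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_fraction, random_state=seed + r, stratify=y)
        clf = LinearSVC(C=cost, dual="auto", max_iter=20000,
                        random_state=seed + r)
        clf.fit(Xtr, ytr)
        acc = float(clf.score(Xte, yte)) * 100.0
        accs.append(acc)
        reports.append({"repeat": r, "accuracy_percent": acc,
                        "n_train": len(ytr), "n_test": len(yte)})
    return float(np.mean(accs)), float(np.std(accs)), reports
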