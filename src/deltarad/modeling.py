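"""SVM-RFE model selection and ROC evaluation.

Ranking uses recursive feature elimination with a Gaussian-kernel support
vector classifier: at each round the classifier is refit and each remaining
feature is scored by how much the margin objective
``W^2 = sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j)`` changes when that
feature is removed from the kernel (dual coefficients held fixed); the
least influential block of features is eliminated.  Model selection adds
top-ranked features one at a time, tuning (cost, gamma) by stratified
10-fold cross-validated AUC on the development arm only.

AUC uses the trapezoidal rank rule; its standard error the Hanley-McNeil
formula; the operating point maximizes Youden's J (sensitivity +
specificity - 1); model AUCs are compared with DeLong's paired test, with a
paired-bootstrap alternative behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import pairwise, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ModelConfig",
    "FittedModel",
    "EvalResult",
    "svm_rfe_rank",
    "tune_and_select",
    "evaluate_roc",
    "compare_auc",
]


@dataclass(frozen=True)
class ModelConfig:
    """Gaussian-kernel SVM search space and CV layout."""

    cost_grid: tuple[float, ...] = tuple(2.0**k for k in range(-5, 11))
    gamma_grid: tuple[float, ...] = tuple(2.0**k for k in range(-10, 4))
    n_folds: int = 10
    fold_seed: int = 0
    rfe_step: float = 0.1  # fraction of remaining features dropped per round
    max_features: int = 10

    def __post_init__(self):
        if not self.cost_grid or not self.gamma_grid:
            raise ValueError("grids must be nonempty")
        if self.n_folds < 2:
            raise ValueError("need >= 2 CV folds")


@dataclass
class FittedModel:
    feature_names: list[str]  # selected subset, RFE-rank order
    ranking: list[str]  # full ranking, best first
    cost: float
    gamma: float
    cv_curve: pd.DataFrame  # columns: k, cost, gamma, cv_auc
    classifier: SVC
    orientation: float = 1.0  # multiply decision scores so responders score high

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.orientation * self.classifier.decision_function(
            X[self.feature_names].to_numpy()
        )

    def to_dict(self) -> dict:
        """JSON-serializable model state (support vectors included)."""
        clf = self.classifier
        return {
            "feature_names": list(self.feature_names),
            "ranking": list(self.ranking),
            "cost": self.cost,
            "gamma": self.gamma,
            "orientation": self.orientation,
            "support_vectors": clf.support_vectors_.tolist(),
            "dual_coef": clf.dual_coef_[0].tolist(),
            "intercept": float(clf.intercept_[0]),
        }

    @staticmethod
    def score_from_dict(state: dict, X: pd.DataFrame) -> np.ndarray:
        """Decision scores from a serialized model: sum_i a_i K(sv_i, x) + b."""
        sv = np.asarray(state["support_vectors"], dtype=np.float64)
        dual = np.asarray(state["dual_coef"], dtype=np.float64)
        k = pairwise.rbf_kernel(
            X[state["feature_names"]].to_numpy(dtype=np.float64), sv,
            gamma=state["gamma"],
        )
        return state["orientation"] * (k @ dual + state["intercept"])


@dataclass
class EvalResult:
    auc: float
    auc_se: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    scores: np.ndarray
    labels: np.ndarray


def _check_xy(X, y):
    y = np.asarray(y, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    return y


def _w2_criteria(X: np.ndarray, y: np.ndarray, cost: float, gamma: float) -> np.ndarray:
    """Per-feature elimination criterion |W^2 - W^2_without_feature|."""
    clf = SVC(kernel="rbf", C=cost, gamma=gamma)
    clf.fit(X, 2.0 * y - 1.0)
    sv = clf.support_
    beta = clf.dual_coef_[0]  # alpha_i * y_i over support vectors
    Xs = X[sv]
    K = pairwise.rbf_kernel(Xs, gamma=gamma)
    w2 = float(beta @ K @ beta)
    # removing feature f multiplies K elementwise by exp(gamma * d_f^2)
    crit = np.empty(X.shape[1])
    for f in range(X.shape[1]):
        d = Xs[:, f, None] - Xs[None, :, f]
        Kf = K * np.exp(gamma * d**2)
        crit[f] = abs(w2 - float(beta @ Kf @ beta))
    return crit


def svm_rfe_rank(
    X: pd.DataFrame,
    y,
    config: ModelConfig | None = None,
    cost: float | None = None,
    gamma: float | None = None,
    step: float | int | None = None,
) -> list[str]:
    """Rank all columns of ``X`` by recursive elimination, best first.

    Deterministic given the inputs.  Ties break toward the larger
    criterion, then toward the earlier column (earlier column survives
    longer and therefore ranks better).  Features whose criteria are
    exactly tied at the elimination boundary — e.g. duplicated columns —
    are eliminated together, so they occupy adjacent ranks.
    """
    config = config or ModelConfig()
    y = _check_xy(X, y)
    cost = float(cost) if cost is not None else 1.0
    gamma = float(gamma) if gamma is not None else 1.0 / X.shape[1]
    step = step if step is not None else config.rfe_step

    cols = list(X.columns)
    remaining = list(range(len(cols)))
    eliminated: list[int] = []
    Xv = X.to_numpy(dtype=np.float64)
    while remaining:
        if len(remaining) == 1:
            eliminated.append(remaining.pop())
            break
        crit = _w2_criteria(Xv[:, remaining], y, cost, gamma)
        n_drop = 1 if step is None else (
            int(step) if step >= 1 else max(1, int(np.floor(step * len(remaining))))
        )
        n_drop = min(n_drop, len(remaining) - 1) if len(remaining) > 1 else 1
        # smallest criterion first; ties -> later original column drops first
        order = np.lexsort((-np.array(remaining), crit))
        drop = list(order[:n_drop])
        # exact criterion ties straddling the cut are eliminated together
        # (symmetric duplicates would otherwise leapfrog each other)
        boundary = crit[drop[-1]]
        extra = [i for i in order[n_drop:] if crit[i] == boundary]
        drop = (drop + extra)[: len(remaining) - 1] or drop[:1]
        drop = sorted(drop, key=lambda i: (crit[i], -remaining[i]))
        for i in drop:
            eliminated.append(remaining[i])
        for i in sorted(drop, reverse=True):
            remaining.pop(i)
    eliminated.reverse()  # last eliminated = most relevant
    return [cols[i] for i in eliminated]


def _cv_auc(Xv, y, cost, gamma, n_folds, fold_seed) -> float:
    # stratified folding cannot exceed the minority class count
    n_folds = min(n_folds, int(y.sum()), int((~y).sum()))
    if n_folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    scores = np.empty(len(y))
    for tr, te in skf.split(Xv, y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("fold with a single class despite stratification")
        clf = SVC(kernel="rbf", C=cost, gamma=gamma)
        clf.fit(Xv[tr], y[tr])
        s = clf.decision_function(Xv[te])
        if clf.classes_[1] != True:  # noqa: E712 - sklearn class order
            s = -s
        scores[te] = s
    return float(roc_auc_score(y, scores))


def tune_and_select(
    X: pd.DataFrame, y, config: ModelConfig | None = None, ranking: list[str] | None = None
) -> FittedModel:
    """Select (k, cost, gamma) by 10-fold CV AUC over top-k ranked features.

    Must be called with development-arm data only.  Ties in CV AUC resolve
    toward fewer features, then smaller cost, then larger gamma.  The
    winning configuration is refit on all provided samples.
    """
    config = config or ModelConfig()
    y = _check_xy(X, y)
    if ranking is None:
        ranking = svm_rfe_rank(X, y, config)
    kmax = min(config.max_features, len(ranking))

    rows = []
    best = None
    for k in range(1, kmax + 1):
        feats = ranking[:k]
        Xv = X[feats].to_numpy(dtype=np.float64)
        for cost in config.cost_grid:
            for gamma in config.gamma_grid:
                auc = _cv_auc(Xv, y, cost, gamma, config.n_folds, config.fold_seed)
                rows.append({"k": k, "cost": cost, "gamma": gamma, "cv_auc": auc})
                key = (round(auc, 12), -k, -cost, gamma)
                if best is None or key > best[0]:
                    best = (key, k, cost, gamma)
    _, k, cost, gamma = best
    feats = ranking[:k]
    clf = SVC(kernel="rbf", C=cost, gamma=gamma)
    clf.fit(X[feats].to_numpy(dtype=np.float64), y)
    orientation = 1.0 if clf.classes_[1] == True else -1.0  # noqa: E712
    return FittedModel(
        feature_names=feats,
        ranking=list(ranking),
        cost=float(cost),
        gamma=float(gamma),
        cv_curve=pd.DataFrame(rows),
        classifier=clf,
        orientation=orientation,
    )


def evaluate_roc(scores, labels) -> EvalResult:
    """ROC metrics with the Youden-index operating point.

    AUC by the trapezoidal rank rule (ties count one half); SE by the
    Hanley-McNeil formula; sensitivity/specificity at the threshold
    maximizing their sum; PPV/NPV from the confusion table at that point.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("both classes required for ROC evaluation")
    auc = float(roc_auc_score(y, scores))
    n1, n0 = int(y.sum()), int((~y).sum())
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    se = float(
        np.sqrt(
            (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
            / (n1 * n0)
        )
    )
    fpr, tpr, thresholds = roc_curve(y, scores)
    j = tpr - fpr
    best = int(np.argmax(j))  # first maximum = highest threshold among ties
    thr = float(thresholds[best])
    pred = scores >= thr
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    return EvalResult(
        auc=auc,
        auc_se=se,
        threshold=thr,
        sensitivity=tp / n1,
        specificity=tn / n0,
        ppv=tp / (tp + fp) if tp + fp else 0.0,
        npv=tn / (tn + fn) if tn + fn else 0.0,
        scores=scores,
        labels=y,
    )


# --- DeLong paired AUC comparison -----------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(np.concatenate([pos, neg]))
    tpos = _midrank(pos)
    tneg = _midrank(neg)
    auc = (tx[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tx[:m] - tpos) / n  # structural components over positives
    v01 = 1.0 - (tx[m:] - tneg) / m  # over negatives
    return auc, v10, v01


def compare_auc(scores_a, scores_b, labels, method: str = "delong",
                n_boot: int = 2000, seed: int = 0) -> dict[str, float]:
    """Two-sided test of AUC_A = AUC_B on the same (paired) test samples."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired comparison requires aligned score/label arrays")
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    if method == "delong":
        if len(v10a) < 2 or len(v01a) < 2:
            raise ValueError("DeLong test needs >= 2 samples per class")
        s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
        var = (
            s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]
        ) / len(v10a) + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / len(v01a)
        if not np.isfinite(var) or var <= 0:
            p = 1.0
            z = 0.0
        else:
            z = (auc_a - auc_b) / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(y)
        idx_neg = np.flatnonzero(~y)
        diffs = np.empty(n_boot)
        for i in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx_pos, len(idx_pos)), rng.choice(idx_neg, len(idx_neg))]
            )
            diffs[i] = roc_auc_score(y[take], a[take]) - roc_auc_score(y[take], b[take])
        obs = auc_a - auc_b
        se = diffs.std(ddof=1)
        if se == 0:
            p, z = 1.0, 0.0
        else:
            z = obs / se
            p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "auc_a": float(auc_a),
        "auc_b": float(auc_b),
        "delta": float(auc_a - auc_b),
        "z": float(z),
        "p_value": float(min(1.0, p)),
        "method": method,
    }
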