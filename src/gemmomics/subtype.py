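"""Cross-species intrinsic-subtype classification.

The translator maps mouse tumor expression onto human breast cancer
intrinsic subtypes in four stages:

1. **Batch adjustment** — per-gene location/scale batch-effect removal
   with parametric empirical-Bayes shrinkage of the batch parameters
   (additive effect gamma with a normal prior, multiplicative effect
   delta^2 with an inverse-gamma prior, hyperparameters by method of
   moments, iterated to convergence), applied jointly to the human and
   mouse cohorts.
2. **Feature elimination** — recursive feature elimination with
   stratified cross-validation using an RBF-kernel SVM; since a kernel
   SVM exposes no coefficients, features are ranked by permutation
   importance averaged over folds.
3. **Soft-voting ensemble** — five base learners (regularized logistic
   regression, RBF-kernel SVM with probability outputs, random forest,
   gradient-boosted trees, multi-layer perceptron) fit on stratified
   70/30 shuffle splits; class probabilities are averaged with equal
   weights, over 15 independent instantiations.
4. **Assignment** — a mouse sample's subtype is the class with the
   highest probability averaged over every learner of every
   instantiation, ties resolved by the canonical class order.

The canonical class order (BASAL, CLAUDIN_LOW, HER2, LUMA, LUMB,
NORMAL) is the single tie-break authority everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

#: Canonical intrinsic-subtype order; index order breaks all ties.
SUBTYPE_ORDER: tuple[str, ...] = (
    "BASAL",
    "CLAUDIN_LOW",
    "HER2",
    "LUMA",
    "LUMB",
    "NORMAL",
)


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters (one row per gene)."""

    genes: list[str]
    grand_mean: np.ndarray
    pooled_sd: np.ndarray
    gamma_star: dict[str, np.ndarray]
    delta2_star: dict[str, np.ndarray]
    gamma_bar: dict[str, float]
    tau2_bar: dict[str, float]


def _invgamma_moments(delta2_hat: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma hyperparameters (lambda, theta)."""
    m = float(delta2_hat.mean())
    v = float(delta2_hat.var(ddof=1)) if delta2_hat.size > 1 else 0.0
    if v <= 0:
        return 3.0, 2.0 * m  # flat-ish prior when genes agree exactly
    lam = (2.0 * v + m**2) / v
    theta = (m * v + m**3) / v
    return lam, theta


def eb_batch_adjust(
    expr: ExpressionMatrix,
    max_iter: int = 100,
    conv: float = 1e-4,
) -> tuple[ExpressionMatrix, BatchModel | None]:
    """Remove per-gene batch location/scale effects with EB shrinkage.

    With a single batch the input is returned unchanged (with a
    warning). Genes with zero pooled variance are dropped with a
    warning. The per-gene grand mean is preserved exactly by a final
    recentering step.
    """
    batches = expr.batches()
    batch_names = list(pd.unique(batches))
    if len(batch_names) < 2:
        warnings.warn("single batch: returning input unchanged", stacklevel=2)
        return expr, None
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples")

    Y = expr.values.to_numpy(dtype=float)
    sample_batch = batches.to_numpy()
    n_total = Y.shape[1]
    idx = {b: np.flatnonzero(sample_batch == b) for b in batch_names}

    batch_means = {b: Y[:, idx[b]].mean(axis=1) for b in batch_names}
    grand_mean = sum(len(idx[b]) * batch_means[b] for b in batch_names) / n_total
    resid = np.empty_like(Y)
    for b in batch_names:
        resid[:, idx[b]] = Y[:, idx[b]] - batch_means[b][:, None]
    var_pooled = (resid**2).sum(axis=1) / n_total

    keep = var_pooled > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance gene(s)", stacklevel=2
        )
    genes = [g for g, k in zip(expr.genes, keep) if k]
    Y = Y[keep]
    grand_mean = grand_mean[keep]
    pooled_sd = np.sqrt(var_pooled[keep])

    Z = (Y - grand_mean[:, None]) / pooled_sd[:, None]

    gamma_star: dict[str, np.ndarray] = {}
    delta2_star: dict[str, np.ndarray] = {}
    gamma_bar_out: dict[str, float] = {}
    tau2_bar_out: dict[str, float] = {}
    Zadj = np.empty_like(Z)
    for b in batch_names:
        zb = Z[:, idx[b]]
        nb = zb.shape[1]
        gamma_hat = zb.mean(axis=1)
        delta2_hat = zb.var(axis=1, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau2_bar = float(gamma_hat.var(ddof=1))
        lam, theta = _invgamma_moments(delta2_hat)

        g_star = gamma_hat.copy()
        d_star = delta2_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * tau2_bar * gamma_hat + d_star * gamma_bar) / (
                nb * tau2_bar + d_star
            )
            ssq = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * ssq) / (nb / 2.0 + lam - 1.0)
            change = max(
                np.abs(g_new - g_star).max(initial=0.0),
                np.abs(d_new - d_star).max(initial=0.0),
            )
            g_star, d_star = g_new, d_new
            if change < conv:
                break
        gamma_star[b] = g_star
        delta2_star[b] = d_star
        gamma_bar_out[b] = gamma_bar
        tau2_bar_out[b] = tau2_bar
        Zadj[:, idx[b]] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    adjusted = Zadj * pooled_sd[:, None] + grand_mean[:, None]
    # EB shrinkage leaves a small residual location shift; recenter so the
    # per-gene grand mean is preserved exactly.
    adjusted += (grand_mean - adjusted.mean(axis=1))[:, None]

    values = pd.DataFrame(adjusted, index=genes, columns=expr.samples)
    model = BatchModel(
        genes=genes,
        grand_mean=grand_mean,
        pooled_sd=pooled_sd,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar_out,
        tau2_bar=tau2_bar_out,
    )
    return ExpressionMatrix(values, expr.meta.copy()), model


# ---------------------------------------------------------------------------
# RFECV with permutation importance
# ---------------------------------------------------------------------------

def rfecv_select(
    expr: ExpressionMatrix,
    labels: Sequence[str],
    folds: int = 10,
    step: int = 1,
    n_repeats: int = 3,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination with stratified CV (RBF-SVM).

    At each round the ``step`` features with the lowest permutation
    importance (averaged over folds) are removed and the mean CV
    accuracy at the current feature count recorded. Returns the feature
    subset with the highest mean CV accuracy (ties: fewer features) and
    the full accuracy curve.
    """
    from sklearn.inspection import permutation_importance
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    labels = np.asarray(labels)
    classes, class_counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if class_counts.min() < folds:
        raise ValueError(
            f"every class needs >= {folds} samples for {folds}-fold CV"
        )
    X_full = expr.values.to_numpy(dtype=float).T  # samples x genes
    genes = list(expr.genes)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X_full, labels))

    current = list(range(len(genes)))
    curve_rows = []
    best: tuple[float, int, list[int]] | None = None
    rng_seed = seed
    while current:
        X = X_full[:, current]
        accs = []
        importances = np.zeros(len(current))
        for train, test in splits:
            clf = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=0)
            clf.fit(X[train], labels[train])
            accs.append(clf.score(X[test], labels[test]))
            imp = permutation_importance(
                clf,
                X[test],
                labels[test],
                n_repeats=n_repeats,
                random_state=rng_seed,
            )
            importances += imp.importances_mean
        importances /= len(splits)
        mean_acc = float(np.mean(accs))
        curve_rows.append((len(current), mean_acc, float(np.std(accs))))
        cand = (mean_acc, -len(current), list(current))
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
        if len(current) == 1:
            break
        drop = np.argsort(importances, kind="stable")[: min(step, len(current) - 1)]
        current = [f for k, f in enumerate(current) if k not in set(drop.tolist())]
    assert best is not None
    curve = pd.DataFrame(curve_rows, columns=["n_features", "mean_cv_accuracy", "sd"])
    selected = [genes[i] for i in best[2]]
    return selected, curve


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassifierMetrics:
    """Accuracy / weighted F1 / multiclass MCC plus a confusion matrix.

    ``confusion`` rows are true classes, columns predicted, in the
    order of ``class_order``. The scalar metrics are means over
    instantiations; ``pooled_*`` versions are recomputed from the
    summed confusion matrix.
    """

    accuracy: float
    f1_weighted: float
    mcc: float
    confusion: np.ndarray
    class_order: tuple[str, ...]
    learner_accuracy: dict[str, float] = field(default_factory=dict)

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def pooled_f1_weighted(self) -> float:
        return weighted_f1(self.confusion)

    @property
    def pooled_mcc(self) -> float:
        return mcc_multiclass(self.confusion)


def mcc_multiclass(confusion: np.ndarray) -> float:
    """Generalized multiclass Matthews correlation coefficient.

    (c*s - sum p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2));
    0 when either factor under the root vanishes (degenerate marginals).
    """
    cm = np.asarray(confusion, dtype=float)
    s = cm.sum()
    if s <= 0:
        raise ValueError("confusion matrix is empty")
    c = np.trace(cm)
    t = cm.sum(axis=1)  # true marginals
    p = cm.sum(axis=0)  # predicted marginals
    num = c * s - float(p @ t)
    f1 = s**2 - float(p @ p)
    f2 = s**2 - float(t @ t)
    if f1 <= 0 or f2 <= 0:
        return 0.0
    return float(num / np.sqrt(f1 * f2))


def weighted_f1(confusion: np.ndarray) -> float:
    """Support-weighted mean of per-class F1 (0 where undefined)."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    support = cm.sum(axis=1)
    f1s = np.zeros(cm.shape[0])
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        denom = cm[:, k].sum() + support[k]  # (tp+fp) + (tp+fn)
        f1s[k] = 2.0 * tp / denom if denom > 0 else 0.0
    return float((f1s * support).sum() / support.sum())


def _confusion(
    y_true: np.ndarray, y_pred: np.ndarray, class_order: Sequence[str]
) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    cm = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


# ---------------------------------------------------------------------------
# Soft-voting ensemble
# ---------------------------------------------------------------------------

def _base_learners(seed: int) -> dict[str, object]:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from xgboost import XGBClassifier

    return {
        "logistic": LogisticRegression(max_iter=2000, random_state=seed),
        "svm_rbf": SVC(
            kernel="rbf", probability=True, C=1.0, gamma="scale", random_state=seed
        ),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "xgboost": XGBClassifier(
            n_estimators=100,
            max_depth=4,
            learning_rate=0.3,
            random_state=seed,
            verbosity=0,
            n_jobs=1,
        ),
        "mlp": MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=500, random_state=seed
        ),
    }


@dataclass
class EnsembleModel:
    """Fitted soft-voting ensemble over several stratified instantiations."""

    features: list[str]
    class_order: tuple[str, ...]
    instantiations: list[dict[str, object]] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities averaged over all learners x instantiations."""
        probs = np.zeros((X.shape[0], len(self.class_order)))
        n = 0
        for learners in self.instantiations:
            for clf in learners.values():
                probs += self._aligned_proba(clf, X)
                n += 1
        return probs / n

    def _aligned_proba(self, clf, X: np.ndarray) -> np.ndarray:
        """predict_proba with columns aligned to the canonical order."""
        raw = clf.predict_proba(X)
        out = np.zeros((X.shape[0], len(self.class_order)))
        for j, cls in enumerate(clf.classes_):
            name = (
                self.class_order[int(cls)] if isinstance(cls, (int, np.integer))
                else str(cls)
            )
            out[:, self.class_order.index(name)] = raw[:, j]
        return out


def fit_voting_ensemble(
    expr: ExpressionMatrix,
    labels: Sequence[str],
    n_instantiations: int = 15,
    train_frac: float = 0.70,
    seed: int = 42,
    class_order: Sequence[str] | None = None,
) -> tuple[EnsembleModel, ClassifierMetrics]:
    """Fit the five-learner soft-voting ensemble.

    Each instantiation draws a stratified 70/30 shuffle split
    (preserving class proportions), fits all five learners on the
    training part, and averages their class probabilities on the test
    part. Scalar metrics are averaged over instantiations; the
    confusion matrix is summed.
    """
    from sklearn.model_selection import StratifiedShuffleSplit

    labels = np.asarray([str(l) for l in labels])
    present = set(labels)
    if class_order is None:
        class_order = tuple(
            [c for c in SUBTYPE_ORDER if c in present]
            + sorted(present - set(SUBTYPE_ORDER))
        )
    class_order = tuple(class_order)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 samples to stratify")

    X = expr.values.to_numpy(dtype=float).T
    class_index = {c: i for i, c in enumerate(class_order)}
    y_num = np.array([class_index[l] for l in labels])

    model = EnsembleModel(features=list(expr.genes), class_order=class_order)
    accs, f1s, mccs = [], [], []
    learner_accs: dict[str, list[float]] = {}
    confusion = np.zeros((len(class_order), len(class_order)), dtype=int)
    for i in range(n_instantiations):
        sss = StratifiedShuffleSplit(
            n_splits=1, train_size=train_frac, random_state=seed + i
        )
        train, test = next(sss.split(X, labels))
        learners = _base_learners(seed + i)
        probs = np.zeros((len(test), len(class_order)))
        for name, clf in learners.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                if name == "xgboost":
                    clf.fit(X[train], y_num[train])
                else:
                    clf.fit(X[train], labels[train])
            aligned = model._aligned_proba(clf, X[test])
            solo = np.array([class_order[k] for k in aligned.argmax(axis=1)])
            learner_accs.setdefault(name, []).append(
                float(np.mean(solo == labels[test]))
            )
            probs += aligned
        probs /= len(learners)
        pred_idx = probs.argmax(axis=1)  # argmax takes first max: canonical tie-break
        y_pred = np.array([class_order[k] for k in pred_idx])
        cm = _confusion(labels[test], y_pred, class_order)
        confusion += cm
        accs.append(np.trace(cm) / cm.sum())
        f1s.append(weighted_f1(cm))
        mccs.append(mcc_multiclass(cm))
        model.instantiations.append(learners)

    metrics = ClassifierMetrics(
        accuracy=float(np.mean(accs)),
        f1_weighted=float(np.mean(f1s)),
        mcc=float(np.mean(mccs)),
        confusion=confusion,
        class_order=class_order,
        learner_accuracy={k: float(np.mean(v)) for k, v in learner_accs.items()},
    )
    return model, metrics


def assign_mouse_subtypes(
    model: EnsembleModel, mouse_expr: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each mouse sample the subtype with highest mean probability.

    Returns ``(assignments, proportions)``: per-sample mean class
    probabilities plus the assigned label, and per-cohort (metadata
    ``group``) fractions of assigned subtypes.
    """
    missing = [g for g in model.features if g not in mouse_expr.values.index]
    if missing:
        raise KeyError(f"mouse data lacks model features: {missing}")
    sub = mouse_expr.subset_genes(model.features)
    X = sub.values.to_numpy(dtype=float).T
    probs = model.predict_proba(X)
    pred_idx = probs.argmax(axis=1)
    assignments = pd.DataFrame(
        probs, index=sub.samples, columns=list(model.class_order)
    )
    assignments["assigned"] = [model.class_order[k] for k in pred_idx]
    assignments.index.name = "sample"

    cohorts = sub.groups()
    rows = {}
    for cohort in pd.unique(cohorts):
        members = assignments.loc[cohorts[cohorts == cohort].index, "assigned"]
        frac = members.value_counts(normalize=True)
        rows[cohort] = [float(frac.get(c, 0.0)) for c in model.class_order]
    proportions = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(model.class_order)
    )
    proportions.index.name = "cohort"
    return assignments, proportions
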