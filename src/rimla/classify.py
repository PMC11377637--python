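"""Multivariate association between microstructure and lesion phenotype.

A balanced random forest predicts the longitudinal lesion class
(enlarging, shrinking, stable, new) from the 18 z-score metrics, the
lesion volume and the disease course: each tree is grown on a draw of
equal size per class (25 % prevalence each) taken with replacement from
the training set, so the model is not dominated by the majority class.
Performance on held-out lesions is summarized by per-class balanced
accuracy (one-vs-rest), the Hand-Till multiclass AUC (mean of all
pairwise two-class AUCs), and Krippendorff's alpha with a permutation p
value. Variable importance is the mean drop in held-out accuracy over
repeated column permutations, and predictor collinearity is quantified
with variance inflation factors from the linear model predicting the
lesion volumetric rate of change.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from rimla.core import CLASS_ORDER, child_rng


@dataclasses.dataclass
class BalancedForest:
    """Ensemble of CART trees, each fit on a class-balanced bootstrap draw."""

    trees: list
    classes_: np.ndarray
    feature_names: list[str]

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], self.classes_.size))
        col = {c: i for i, c in enumerate(self.classes_)}
        for t in self.trees:
            p = t.predict_proba(X)
            for j, c in enumerate(t.classes_):
                out[:, col[c]] += p[:, j]
        return out / len(self.trees)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def split_data(
    table: pd.DataFrame,
    n_train: int = 3000,
    seed: int = 0,
    class_col: str = "rimla_label",
    max_tries: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random train/test split without replacement.

    Resamples the split (up to ``max_tries``) until both partitions
    contain every class present in the table.
    """
    n = len(table)
    if n_train >= n:
        raise ValueError(f"n_train={n_train} must be smaller than the table size {n}")
    classes = set(table[class_col])
    rng = child_rng(seed, "split")
    for _ in range(max_tries):
        perm = rng.permutation(n)
        train = table.iloc[perm[:n_train]]
        test = table.iloc[perm[n_train:]]
        if set(train[class_col]) == classes and set(test[class_col]) == classes:
            return train.reset_index(drop=True), test.reset_index(drop=True)
    raise ValueError("could not produce a split containing every class in both parts")


def balanced_draw(idx_by_class, classes, n_per_class: int, rng) -> np.ndarray:
    """Indices of one tree's training draw: n_per_class per class, with replacement."""
    return np.concatenate(
        [rng.choice(idx_by_class[c], size=n_per_class, replace=True) for c in classes]
    )


def train_balanced_forest(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    n_trees: int = 500,
    per_tree: int = 1000,
    seed: int = 0,
) -> BalancedForest:
    """Grow the balanced forest.

    Per tree, ``per_tree`` training lesions are drawn with replacement
    with equal counts per class (``per_tree / n_classes`` each,
    regardless of the training prevalence) and a CART tree with sqrt
    feature subsampling is fit on the draw.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.array([c for c in CLASS_ORDER if c in set(y)] +
                       sorted(set(map(str, y)) - set(CLASS_ORDER)))
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    for c, idx in idx_by_class.items():
        if idx.size == 0:
            raise ValueError(f"class {c!r} absent from the training set")
    n_per_class = per_tree // classes.size
    trees = []
    for t in range(n_trees):
        rng = child_rng(seed, "tree", t)
        draw = balanced_draw(idx_by_class, classes, n_per_class, rng)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[draw], y[draw])
        trees.append(tree)
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return BalancedForest(trees, classes, names)


def permutation_importance(
    model: BalancedForest,
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation variable importance on held-out data.

    Importance of a feature is the drop in multiclass accuracy when its
    column is permuted; mean and SD over ``n_perm`` permutations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    base = float((model.predict(X) == y).mean())
    n, d = X.shape
    rows = []
    for j, name in enumerate(model.feature_names):
        rng = child_rng(seed, "perm", j)
        # batch the n_perm permuted copies into one prediction call
        Xbig = np.tile(X, (n_perm, 1))
        for k in range(n_perm):
            Xbig[k * n : (k + 1) * n, j] = X[rng.permutation(n), j]
        pred = model.predict(Xbig).reshape(n_perm, n)
        acc = (pred == y[None, :]).mean(axis=1)
        drops = base - acc
        rows.append(
            {
                "feature": name,
                "importance_mean": float(drops.mean()),
                "importance_sd": float(drops.std(ddof=0)) if n_perm > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def balanced_accuracy_per_class(y, yhat, classes=None) -> dict[str, float]:
    """One-vs-rest balanced accuracy (recall+specificity)/2 per class."""
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if classes is None:
        classes = [c for c in CLASS_ORDER if c in set(y)] or sorted(set(map(str, y)))
    out = {}
    for c in classes:
        pos, neg = y == c, y != c
        recall = float((yhat[pos] == c).mean()) if pos.any() else np.nan
        spec = float((yhat[neg] != c).mean()) if neg.any() else np.nan
        out[str(c)] = (recall + spec) / 2
    return out


def _binary_auc(scores: np.ndarray, pos: np.ndarray) -> float:
    """Rank-based AUC with 0.5 credit for ties (Mann-Whitney form)."""
    from scipy.stats import rankdata

    r = rankdata(scores)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def multiclass_auc(probs: np.ndarray, y, classes) -> float:
    """Hand-Till multiclass AUC.

    Mean over all ordered class pairs (i, j), i != j, of the rank-based
    AUC of class i's probability column on the lesions truly of class i
    (positives) or class j (negatives).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    classes = list(classes)
    aucs = []
    for i, ci in enumerate(classes):
        for cj in classes:
            if cj == ci:
                continue
            sel = (y == ci) | (y == cj)
            if not (np.any(y == ci) and np.any(y == cj)):
                continue
            aucs.append(_binary_auc(probs[sel, i], (y[sel] == ci)))
    return float(np.mean(aucs))


def krippendorff_alpha(
    y, yhat, n_permutations: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Nominal Krippendorff's alpha between two label assignments.

    alpha = 1 - D_o / D_e from the coincidence matrix of the paired
    labels; the p value is a one-sided permutation test (shuffling
    ``yhat``) for alpha > 0.
    """
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.size != yhat.size or y.size == 0:
        raise ValueError("label vectors must be non-empty and equally long")

    levels = sorted(set(map(str, y)) | set(map(str, yhat)))
    code = {c: i for i, c in enumerate(levels)}
    a = np.array([code[str(v)] for v in y])
    b = np.array([code[str(v)] for v in yhat])
    k = len(levels)

    def alpha_of(bb):
        o = np.zeros((k, k))
        np.add.at(o, (a, bb), 1.0)
        o = o + o.T  # each unit contributes both ordered pairs
        n_c = o.sum(axis=1)
        n_tot = n_c.sum()
        if n_tot <= 1:
            return np.nan
        d_o = (o.sum() - np.trace(o)) / n_tot
        d_e = (n_tot**2 - (n_c**2).sum()) / (n_tot * (n_tot - 1))
        if d_e == 0:
            return 1.0  # no variability: perfect agreement by convention
        return 1.0 - d_o / d_e

    alpha = float(alpha_of(b))
    rng = child_rng(seed, "kripp")
    count = 0
    for _ in range(n_permutations):
        if alpha_of(rng.permutation(b)) >= alpha:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return alpha, float(p)


def vif(X: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """Variance inflation factor of each predictor.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing (with intercept)
    predictor j on all the others. A perfectly collinear predictor is
    reported as +inf rather than raising.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    names = names or [f"x{i}" for i in range(d)]
    out = []
    for j in range(d):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            out.append(np.nan)  # constant predictor: VIF undefined
            continue
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.DataFrame({"predictor": names, "vif": out})


@dataclasses.dataclass
class ClassifierReport:
    balanced_accuracy: dict[str, float]
    multiclass_auc: float
    accuracy: float
    krippendorff_alpha: float
    krippendorff_p: float
    confusion: pd.DataFrame
    importance: pd.DataFrame
    vif: pd.DataFrame
    classes: tuple[str, ...]
    auc_method: str = "hand-till"


def evaluate(
    table: pd.DataFrame,
    feature_cols: list[str],
    class_col: str = "rimla_label",
    rate_col: str | None = None,
    n_train: int = 3000,
    n_trees: int = 500,
    per_tree: int = 1000,
    n_perm: int = 50,
    seed: int = 0,
) -> ClassifierReport:
    """Full multivariate analysis: split, train, test metrics, importance, VIF."""
    train, test = split_data(table, n_train=n_train, seed=seed, class_col=class_col)
    Xtr = train[feature_cols].to_numpy(float)
    Xte = test[feature_cols].to_numpy(float)
    ytr = train[class_col].to_numpy(str)
    yte = test[class_col].to_numpy(str)
    model = train_balanced_forest(
        Xtr, ytr, feature_cols, n_trees=n_trees, per_tree=per_tree, seed=seed
    )
    probs = model.predict_proba(Xte)
    yhat = model.predict(Xte)
    classes = tuple(model.classes_)
    conf = pd.DataFrame(
        0, index=list(classes), columns=list(classes), dtype=int
    )
    for t, p in zip(yte, yhat):
        conf.loc[t, p] += 1
    alpha, p_alpha = krippendorff_alpha(yte, yhat, seed=seed)
    imp = permutation_importance(model, Xte, yte, n_perm=n_perm, seed=seed)
    vif_table = vif(train[feature_cols].to_numpy(float), feature_cols)
    return ClassifierReport(
        balanced_accuracy=balanced_accuracy_per_class(yte, yhat, classes),
        multiclass_auc=multiclass_auc(probs, yte, classes),
        accuracy=float((yhat == yte).mean()),
        krippendorff_alpha=alpha,
        krippendorff_p=p_alpha,
        confusion=conf,
        importance=imp,
        vif=vif_table,
        classes=classes,
    )
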