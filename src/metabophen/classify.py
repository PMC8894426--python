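"""LOOCV LogitBoost classification of phenotype groups.

The classifier is additive logistic boosting with depth-1 decision
stumps.  Each iteration computes working responses
``z_i = (y*_i - p_i) / (p_i (1 - p_i))`` and weights
``w_i = p_i (1 - p_i)`` (probabilities clipped to [1e-4, 1 - 1e-4]),
fits the weighted least-squares stump over all (feature, midpoint
threshold) candidates, adds half its fitted value to the committee F,
and updates p through the logistic link.  Multiclass problems train one
one-vs-rest committee per class and predict the argmax committee score.

Three feature-extraction variants feed the classifier: all significant
features; significant features with linear dependencies removed (exact
rank reduction, then greedy |r| >= threshold pruning); and PCA scores
retaining a cumulative explained-variance fraction.  Evaluation is
leave-one-out cross-validation with confusion-matrix metrics, an exact
Clopper-Pearson CI on accuracy, and a one-sided exact binomial
comparison against the no-information rate (NIR).

By default feature extraction is fitted once on all samples before the
LOOCV loop (fixed-selection mode, the protocol small-cohort studies
commonly use), which lets the held-out sample influence feature
selection; ``nested=True`` re-fits the extraction inside every fold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import ClassificationReport, SampleMetadata, ValidationError

VARIANTS = ("ALL_SIG", "REMOVE_LINEAR_CORRELATED", "PCA")


@dataclass
class Stump:
    feature: int
    threshold: float  # goes left when x <= threshold
    left_value: float
    right_value: float


@dataclass
class StumpEnsemble:
    """One boosting committee per class (a single committee when binary)."""

    classes: list[str]
    committees: dict[str, list[Stump]]
    n_iterations: int

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Committee scores F, shape (n_samples, n_classes)."""
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], len(self.classes)))
        for k, cls in enumerate(self.classes):
            f = np.zeros(X.shape[0])
            for st in self.committees[cls]:
                go_left = X[:, st.feature] <= st.threshold
                f += 0.5 * np.where(go_left, st.left_value, st.right_value)
            out[:, k] = f
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        if len(self.classes) == 2:
            # single committee trained for classes[1]; ties -> classes[0]
            return np.where(s[:, 1] > 0, self.classes[1], self.classes[0])
        return np.asarray(self.classes)[np.argmax(s, axis=1)]


def _fit_stump(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> Stump:
    """Weighted least-squares stump over all midpoint split candidates.

    Ties in stump loss break by (feature index, threshold) order.
    """
    n, p = X.shape
    total_w = w.sum()
    total_wz = (w * z).sum()
    best = None  # (score, feature, threshold, left, right)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        cw = np.cumsum(w[order])
        cwz = np.cumsum((w * z)[order])
        valid = np.nonzero(xs[:-1] < xs[1:])[0]
        if valid.size == 0:
            continue
        wl, wr = cw[valid], total_w - cw[valid]
        sl, sr = cwz[valid], total_wz - cwz[valid]
        # maximizing explained weighted sum of squares
        score = sl**2 / wl + sr**2 / wr
        i = int(np.argmax(score))
        if best is None or score[i] > best[0]:
            k = valid[i]
            best = (
                float(score[i]),
                j,
                float((xs[k] + xs[k + 1]) / 2.0),
                float(sl[i] / wl[i]),
                float(sr[i] / wr[i]),
            )
    if best is None:  # every feature constant: intercept-only stump
        mean = float(total_wz / total_w)
        return Stump(0, np.inf, mean, mean)
    return Stump(best[1], best[2], best[3], best[4])


def _fit_binary_committee(X: np.ndarray, y01: np.ndarray, n_iter: int) -> list[Stump]:
    n = X.shape[0]
    f = np.zeros(n)
    prob = np.full(n, 0.5)
    stumps: list[Stump] = []
    for _ in range(n_iter):
        pc = np.clip(prob, 1e-4, 1 - 1e-4)
        w = pc * (1 - pc)
        z = (y01 - pc) / w
        st = _fit_stump(X, z, w)
        stumps.append(st)
        go_left = X[:, st.feature] <= st.threshold
        f += 0.5 * np.where(go_left, st.left_value, st.right_value)
        prob = 1.0 / (1.0 + np.exp(-2.0 * f))
    return stumps


def fit_logitboost(X, y, n_iter: int = 21) -> StumpEnsemble:
    """Fit a LogitBoost stump ensemble; multiclass is one-vs-rest."""
    X = np.asarray(getattr(X, "to_numpy", lambda: X)(), dtype=float)
    y = np.asarray(y)
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    classes = sorted(set(map(str, y)))
    if len(classes) < 2:
        raise ValidationError("need at least two classes to fit a classifier")
    committees: dict[str, list[Stump]] = {}
    if len(classes) == 2:
        committees[classes[1]] = _fit_binary_committee(
            X, (y == classes[1]).astype(float), n_iter
        )
        committees[classes[0]] = [
            Stump(s.feature, s.threshold, -s.left_value, -s.right_value)
            for s in committees[classes[1]]
        ]
    else:
        for cls in classes:
            committees[cls] = _fit_binary_committee(
                X, (y == cls).astype(float), n_iter
            )
    return StumpEnsemble(classes, committees, n_iter)


def remove_linear_correlated(
    X: pd.DataFrame, corr_threshold: float = 0.90, rank_tol: float = 1e-8
) -> pd.DataFrame:
    """Drop exact linear combinations, then greedily prune |r| pairs.

    Exact dependencies are found by rank-revealing QR (pivoted; columns
    whose R diagonal falls below ``rank_tol`` relative to the largest are
    linear combinations of earlier pivots).  Then, while any pair has
    |r| >= ``corr_threshold``, the pair with the largest |r| (ties by
    column order) loses its member with the larger mean absolute
    correlation (ties drop the later column).
    """
    if X.shape[1] < 1:
        return X
    from scipy.linalg import qr

    mat = X.to_numpy(dtype=float)
    _, r_mat, piv = qr(mat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r_mat))
    rank = int(np.sum(diag > rank_tol * max(diag[0], 1e-300))) if diag.size else 0
    keep = sorted(piv[:rank])
    cols = list(X.columns[keep])
    out = X[cols]
    while out.shape[1] > 1:
        corr = out.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) < corr_threshold:
            break
        mean_abs = np.abs(corr).mean(axis=0)
        drop = (i if mean_abs[i] > mean_abs[j] else j) if mean_abs[i] != mean_abs[j] else max(i, j)
        out = out.drop(columns=out.columns[drop])
    return out


@dataclass
class PCAReduction:
    scores: pd.DataFrame
    n_components: int
    model: PCA


def pca_reduce(X: pd.DataFrame, variance_threshold: float = 0.95) -> PCAReduction:
    """Project onto the smallest PC set reaching the variance threshold."""
    if not 0 < variance_threshold <= 1:
        raise ValidationError("variance_threshold must be in (0, 1]")
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    model = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = model.fit_transform(X.to_numpy(dtype=float))
    cum = np.cumsum(model.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, scores.shape[1])
    return PCAReduction(
        pd.DataFrame(
            scores[:, :k], index=X.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        k,
        model,
    )


@dataclass
class LoocvResult:
    predictions: pd.Series
    n_iter: int
    accuracy: float
    n_features: int
    variant: str


def _loocv_predictions(X: np.ndarray, y: np.ndarray, n_iter: int) -> np.ndarray:
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    for i in range(n):
        train = np.arange(n) != i
        model = fit_logitboost(X[train], y[train], n_iter)
        preds[i] = model.predict(X[i: i + 1])[0]
    return preds


def loocv(
    X: pd.DataFrame,
    y: pd.Series,
    variant: str = "ALL_SIG",
    iter_grid: tuple[int, ...] = (11, 21, 31),
    nested: bool = False,
    corr_threshold: float = 0.90,
    variance_threshold: float = 0.95,
) -> LoocvResult:
    """Leave-one-out cross-validation under one feature variant.

    The boosting iteration count is chosen from ``iter_grid`` by highest
    LOOCV accuracy (ties take the smallest count).  In fixed-selection
    mode (default) the feature extraction is fitted once on all samples;
    in nested mode it is re-fitted on each fold's training samples.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"variant must be one of {VARIANTS}")
    if X.shape[0] < 3:
        raise ValidationError("LOOCV needs at least 3 samples")
    y_arr = np.asarray(y.loc[X.index], dtype=object).astype(str)

    def transform_all(frame: pd.DataFrame) -> pd.DataFrame:
        if variant == "REMOVE_LINEAR_CORRELATED":
            return remove_linear_correlated(frame, corr_threshold)
        if variant == "PCA":
            return pca_reduce(frame, variance_threshold).scores
        return frame

    results: dict[int, tuple[np.ndarray, float, int]] = {}
    if not nested:
        xt = transform_all(X)
        n_features = xt.shape[1]
        mat = xt.to_numpy(dtype=float)
        for n_iter in iter_grid:
            preds = _loocv_predictions(mat, y_arr, n_iter)
            results[n_iter] = (preds, float(np.mean(preds == y_arr)), n_features)
    else:
        n = X.shape[0]
        for n_iter in iter_grid:
            preds = np.empty(n, dtype=object)
            n_feat_folds = []
            for i in range(n):
                train_idx = X.index[np.arange(n) != i]
                if variant == "PCA":
                    red = pca_reduce(X.loc[train_idx], variance_threshold)
                    centered = X.iloc[[i]].to_numpy(dtype=float) - red.model.mean_
                    test = centered @ red.model.components_[: red.n_components].T
                    train = red.scores.to_numpy(dtype=float)
                else:
                    sub = transform_all(X.loc[train_idx])
                    train = sub.to_numpy(dtype=float)
                    test = X.loc[[X.index[i]], sub.columns].to_numpy(dtype=float)
                n_feat_folds.append(train.shape[1])
                model = fit_logitboost(train, y_arr[np.arange(n) != i], n_iter)
                preds[i] = model.predict(test)[0]
            results[n_iter] = (
                preds,
                float(np.mean(preds == y_arr)),
                int(round(np.mean(n_feat_folds))),
            )
    best_iter = max(sorted(results), key=lambda it: (results[it][1], -it))
    preds, acc, n_features = results[best_iter]
    return LoocvResult(
        pd.Series(preds, index=X.index, name="prediction"),
        best_iter,
        acc,
        n_features,
        variant,
    )


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def confusion_report(
    pred: pd.Series, truth: pd.Series, positive_class: str = "CANCER"
) -> ClassificationReport:
    """Confusion matrix (rows truth, columns predicted) with metrics.

    NIR is the largest class's relative frequency in the truth labels;
    ``p_vs_nir`` is the one-sided exact binomial P(X >= correct | n, NIR).
    """
    truth = truth.astype(str)
    pred = pred.astype(str)
    if not truth.index.equals(pred.index):
        pred = pred.reindex(truth.index)
        if pred.isna().any():
            raise ValidationError("prediction and truth labels do not align")
    labels = sorted(set(truth) | set(pred))
    confusion = pd.crosstab(truth, pred).reindex(
        index=labels, columns=labels, fill_value=0
    )
    confusion.index.name = "truth"
    confusion.columns.name = "predicted"
    n = len(truth)
    k = int(np.trace(confusion.to_numpy()))
    accuracy = k / n
    nir = float(truth.value_counts().max() / n)
    p_vs_nir = float(stats.binom.sf(k - 1, n, nir))
    truth_labels = sorted(set(truth))

    def one_vs_rest(cls: str) -> tuple[float, float]:
        tp = int(((truth == cls) & (pred == cls)).sum())
        fn = int(((truth == cls) & (pred != cls)).sum())
        tn = int(((truth != cls) & (pred != cls)).sum())
        fp = int(((truth != cls) & (pred == cls)).sum())
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return sens, spec

    if len(truth_labels) == 2:
        if positive_class not in truth_labels:
            raise ValidationError(
                f"positive class {positive_class!r} absent from truth labels"
            )
        sensitivity, specificity = one_vs_rest(positive_class)
    else:
        per = {cls: one_vs_rest(cls) for cls in truth_labels}
        sensitivity = {cls: v[0] for cls, v in per.items()}
        specificity = {cls: v[1] for cls, v in per.items()}
    return ClassificationReport(
        confusion=confusion,
        accuracy=accuracy,
        ci95=clopper_pearson(k, n),
        nir=nir,
        p_vs_nir=p_vs_nir,
        sensitivity=sensitivity,
        specificity=specificity,
        positive_class=positive_class,
        n=n,
    )


def performance_grid(
    feature_sets: dict[str, dict[str, pd.DataFrame]],
    meta: SampleMetadata,
    positive_class: str = "CANCER",
    iter_grid: tuple[int, ...] = (11, 21, 31),
    corr_threshold: float = 0.90,
    variance_threshold: float = 0.95,
    nested: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], ClassificationReport]]:
    """One LOOCV report per (source matrix x variant x grouping).

    ``feature_sets[source][grouping]`` holds the samples x significant-
    features table for that arm and grouping ("two_group" restricts to
    ASD_DD vs CANCER).  Empty feature sets yield a row with n = 0 and NA
    metrics.  Returns the Table-1-shaped grid and the full reports.
    """
    rows = []
    reports: dict[tuple[str, str, str], ClassificationReport] = {}
    for source, by_grouping in feature_sets.items():
        for grouping, X in by_grouping.items():
            y = meta.frame.loc[X.index, "group"] if len(X) else pd.Series(dtype=object)
            for variant in VARIANTS:
                row = {
                    "source_matrix": source,
                    "grouping": grouping,
                    "variant": variant,
                    "n_input_features": X.shape[1],
                }
                if X.shape[1] == 0 or X.shape[0] < 3:
                    row.update(
                        n_features=0, n_iter=np.nan, accuracy=np.nan,
                        ci_low=np.nan, ci_high=np.nan, nir=np.nan,
                        p_vs_nir=np.nan, sensitivity=np.nan, specificity=np.nan,
                    )
                    rows.append(row)
                    continue
                res = loocv(
                    X, y, variant=variant, iter_grid=iter_grid, nested=nested,
                    corr_threshold=corr_threshold,
                    variance_threshold=variance_threshold,
                )
                rep = confusion_report(res.predictions, y, positive_class)
                reports[(source, variant, grouping)] = rep
                sens, spec = rep.sensitivity, rep.specificity
                if isinstance(sens, dict):  # macro average for the grid row
                    sens = float(np.nanmean(list(sens.values())))
                    spec = float(np.nanmean(list(spec.values())))
                row.update(
                    n_features=res.n_features,
                    n_iter=res.n_iter,
                    accuracy=rep.accuracy,
                    ci_low=rep.ci95[0],
                    ci_high=rep.ci95[1],
                    nir=rep.nir,
                    p_vs_nir=rep.p_vs_nir,
                    sensitivity=sens,
                    specificity=spec,
                )
                rows.append(row)
    return pd.DataFrame(rows), reports
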