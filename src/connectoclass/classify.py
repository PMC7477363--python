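"""Cross-validated two-group classification with permutation significance
and weight-based region importance.

Three linear-readout classifiers of increasing complexity are supported:
L2-penalized logistic regression (``"LR"``), a linear-kernel support vector
machine (``"SVM"``), and a small feed-forward neural network (``"DL"``,
two ReLU hidden layers of 64 and 32 units with early stopping).  Each
exposes a length-p input-space weight vector — raw coefficients for LR,
primal hyperplane weights for the SVM, and for the network the product of
its layer weight matrices collapsed back to input space.

Performance is measured by stratified k-fold cross-validation with the
patient group as the positive class: sensitivity, specificity and balanced
accuracy = (sensitivity + specificity) / 2 on the pooled out-of-fold
predictions.  Significance comes from a label-permutation test (the full
CV is re-run per permutation).  For connectivity features, fold-averaged
absolute weights are folded back onto regions: each region's importance is
the mean |weight| over its n-1 incident connections, and regions are ranked
by that score (ties broken by ascending region index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .confounds import fit_confound_model
from .features import FeatureTable

__all__ = [
    "MODEL_KINDS",
    "CvResult",
    "PermutationResult",
    "WeightMap",
    "stratified_folds",
    "fit_predict",
    "evaluate_cv",
    "permutation_test",
    "region_importance",
    "leave_one_site_out",
]

MODEL_KINDS = ("LR", "SVM", "DL")


@dataclass
class CvResult:
    """Pooled cross-validation outcome for one (table, model) pair."""

    model_kind: str
    representation: str
    fold_assignment: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    fold_weights: list[np.ndarray] = field(default_factory=list)


@dataclass
class PermutationResult:
    observed: float
    null_accuracies: np.ndarray
    p_value: float
    tie_rule: str


@dataclass
class WeightMap:
    """Edge-level |weights| aggregated to per-region scores and a ranking."""

    edge_weights: np.ndarray  # (n_pairs,)
    region_scores: np.ndarray  # (n_regions,)
    ranking: np.ndarray  # region indices, descending score


def stratified_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) preserving class proportions within 1 subject."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} subjects < k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels), labels)):
        assignment[test_idx] = fold
    return assignment


def _build_model(model_kind: str, seed: int):
    if model_kind == "LR":
        return LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
    if model_kind == "SVM":
        return SVC(kernel="linear", C=1.0)
    if model_kind == "DL":
        return MLPClassifier(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            alpha=1e-3,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=10,
            max_iter=200,
            random_state=seed,
        )
    raise ValueError(f"model_kind must be one of {MODEL_KINDS}, got {model_kind!r}")


def _input_space_weights(model, model_kind: str) -> np.ndarray:
    if model_kind in ("LR", "SVM"):
        return model.coef_.ravel().copy()
    # collapse the network to input space: product of layer weight matrices
    w = model.coefs_[0]
    for layer in model.coefs_[1:]:
        w = w @ layer
    return w.ravel().copy()


def fit_predict(
    model_kind: str,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one classifier and return hard test labels plus its weight vector.

    Features are standardized to the training sample before fitting, so the
    weights refer to standardized inputs.
    """
    train_labels = np.asarray(train_labels)
    if np.unique(train_labels).size < 2:
        raise ValueError("training set contains a single class")
    if train_features.shape[1] != test_features.shape[1]:
        raise ValueError(
            f"feature-count mismatch: train {train_features.shape[1]} "
            f"vs test {test_features.shape[1]}"
        )
    scaler = StandardScaler().fit(train_features)
    xtr = scaler.transform(train_features)
    xte = scaler.transform(test_features)
    model = _build_model(model_kind, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(xtr, train_labels)
    return model.predict(xte), _input_space_weights(model, model_kind)


def _confusion_rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(balanced accuracy, sensitivity, specificity), patient = 1 positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = ~pos
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else 0.0
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else 0.0
    return (sens + spec) / 2.0, sens, spec


def evaluate_cv(
    table: FeatureTable,
    model_kind: str,
    k: int = 5,
    seed: int = 0,
    confound_scope: str | None = "train_controls",
) -> CvResult:
    """Stratified k-fold CV with optional within-fold confound removal.

    ``confound_scope="train_controls"`` refits the age/sex GP on each
    fold's training controls before fitting the classifier (no test
    leakage); ``"all_controls"`` residualizes once on every control before
    splitting; ``None`` skips residualization.
    """
    labels = table.labels
    folds = stratified_folds(labels, k=k, seed=seed)
    if confound_scope == "all_controls":
        model = fit_confound_model(table, seed=seed)
        table = model.residualize(table)
    y_pred = np.empty_like(labels)
    fold_weights = []
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        work = table
        if confound_scope == "train_controls":
            cm = fit_confound_model(table, fit_index=train_idx, seed=seed)
            work = cm.residualize(table)
        pred, weights = fit_predict(
            model_kind,
            work.features[train_idx],
            labels[train_idx],
            work.features[test_idx],
            seed=seed + fold,
        )
        y_pred[test_idx] = pred
        fold_weights.append(weights)
    bacc, sens, spec = _confusion_rates(labels, y_pred)
    return CvResult(
        model_kind=model_kind,
        representation=table.representation,
        fold_assignment=folds,
        y_true=labels,
        y_pred=y_pred,
        balanced_accuracy=bacc,
        sensitivity=sens,
        specificity=spec,
        fold_weights=fold_weights,
    )


def permutation_test(
    table: FeatureTable,
    model_kind: str,
    k: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    confound_scope: str | None = None,
    tie_rule: str = "greater",
) -> PermutationResult:
    """Label-permutation significance of the cross-validated accuracy.

    The whole CV procedure is repeated with shuffled group labels; the
    default p-value is the literal strictly-greater count
    ``#{null > observed} / n_perm`` (which can return 0); ``"smoothed"``
    uses the add-one rule ``(#{null >= observed} + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tie_rule not in ("greater", "smoothed"):
        raise ValueError("tie_rule must be 'greater' or 'smoothed'")
    observed = evaluate_cv(
        table, model_kind, k=k, seed=seed, confound_scope=confound_scope
    ).balanced_accuracy
    rng = np.random.default_rng(seed)
    groups = table.subjects["group"].to_numpy()
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(groups.shape[0])
        shuffled = table.subjects.copy()
        shuffled["group"] = groups[perm]
        perm_table = FeatureTable(
            subjects=shuffled,
            features=table.features,
            representation=table.representation,
            feature_names=list(table.feature_names),
        )
        nulls[b] = evaluate_cv(
            perm_table, model_kind, k=k, seed=seed + 1 + b,
            confound_scope=confound_scope,
        ).balanced_accuracy
    if tie_rule == "greater":
        p = float((nulls > observed).sum() / n_perm)
    else:
        p = float(((nulls >= observed).sum() + 1) / (n_perm + 1))
    return PermutationResult(
        observed=observed, null_accuracies=nulls, p_value=p, tie_rule=tie_rule
    )


def _n_regions_from_pairs(n_pairs: int) -> int:
    n = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    if n * (n - 1) // 2 != n_pairs:
        raise ValueError(f"{n_pairs} features is not n(n-1)/2 for any integer n")
    return n


def region_importance(
    cv: CvResult | list[CvResult],
    index_map: list[tuple[int, int]] | None = None,
) -> WeightMap:
    """Fold-averaged |weights| per connection, aggregated per region.

    Accepts one CvResult or several (e.g. one per site, in which case
    per-region scores are averaged across them before ranking).  Requires
    connectivity-representation results; ``index_map`` defaults to the
    row-major lower-triangle order used by ``vectorize_fc``.
    """
    results = cv if isinstance(cv, list) else [cv]
    if not results:
        raise ValueError("no CV results given")
    for r in results:
        if r.representation != "fc":
            raise ValueError(
                "region importance is defined for connectivity (fc) features, "
                f"got representation {r.representation!r}"
            )
    n_pairs = results[0].fold_weights[0].shape[0]
    n = _n_regions_from_pairs(n_pairs)
    if index_map is None:
        rows, cols = np.tril_indices(n, k=-1)
        index_map = list(zip(rows.tolist(), cols.tolist()))
    incidence = np.zeros((n, n_pairs))
    for pos, (i, j) in enumerate(index_map):
        incidence[i, pos] = 1.0
        incidence[j, pos] = 1.0
    per_site_scores = []
    edge_mean = np.zeros(n_pairs)
    for r in results:
        edges = np.mean(np.abs(np.vstack(r.fold_weights)), axis=0)
        edge_mean += edges / len(results)
        per_site_scores.append(incidence @ edges / (n - 1))
    scores = np.mean(per_site_scores, axis=0)
    # descending score, ties broken by ascending region index
    ranking = np.lexsort((np.arange(n), -scores))
    return WeightMap(edge_weights=edge_mean, region_scores=scores, ranking=ranking)


def leave_one_site_out(
    table: FeatureTable,
    model_kind: str,
    seed: int = 0,
    confound_scope: str | None = "train_controls",
) -> dict[str, CvResult]:
    """Train on all sites but one, test on the held-out site, per site."""
    sites = table.subjects["site"].unique().tolist()
    if len(sites) < 2:
        raise ValueError("leave-one-site-out needs at least 2 sites")
    labels = table.labels
    site_col = table.subjects["site"].to_numpy()
    out: dict[str, CvResult] = {}
    for site in sites:
        test_idx = np.flatnonzero(site_col == site)
        train_idx = np.flatnonzero(site_col != site)
        for name, idx in (("training", train_idx), ("held-out", test_idx)):
            if np.unique(labels[idx]).size < 2:
                raise ValueError(f"{name} set for site {site} has a single class")
        work = table
        if confound_scope == "train_controls":
            cm = fit_confound_model(table, fit_index=train_idx, seed=seed)
            work = cm.residualize(table)
        elif confound_scope == "all_controls":
            cm = fit_confound_model(table, seed=seed)
            work = cm.residualize(table)
        pred, weights = fit_predict(
            model_kind,
            work.features[train_idx],
            labels[train_idx],
            work.features[test_idx],
            seed=seed,
        )
        bacc, sens, spec = _confusion_rates(labels[test_idx], pred)
        assignment = np.full(labels.shape[0], -1)
        assignment[test_idx] = 0
        out[site] = CvResult(
            model_kind=model_kind,
            representation=table.representation,
            fold_assignment=assignment,
            y_true=labels[test_idx],
            y_pred=pred,
            balanced_accuracy=bacc,
            sensitivity=sens,
            specificity=spec,
            fold_weights=[weights],
        )
    return out
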