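"""Outcome and cost models under the stratified-CV + holdout-year protocol.

Binary acute-care outcomes are scored by AUC under stratified 10-fold
cross-validation on the training years; the final year is a holdout that
is never touched during model selection. Continuous cost outcomes are
scored by R^2 plus the mean absolute prediction error (Cumming's
prediction measure). Also implements minority oversampling (SMOTE-style
interpolation, applied inside CV folds to the training portion only),
backward elimination at a 0.02 accuracy tolerance, the feature-merging
reduction for cost models, and the paired comparison that decides whether
physician-profile features add at least 0.10 of AUC / R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.metrics import mean_absolute_error, r2_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import (
    KNeighborsClassifier,
    KNeighborsRegressor,
    NearestNeighbors,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .cohort_features import FeatureMatrix

CLASSIFIERS = {
    "logistic": lambda hp, seed: make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=2000, **hp)
    ),
    "tree": lambda hp, seed: DecisionTreeClassifier(random_state=seed, **hp),
    "random_forest": lambda hp, seed: RandomForestClassifier(
        n_estimators=hp.pop("n_estimators", 200), random_state=seed, **hp
    ),
    "gradient_boosting": lambda hp, seed: GradientBoostingClassifier(
        random_state=seed, **hp
    ),
    "knn": lambda hp, seed: make_pipeline(StandardScaler(), KNeighborsClassifier(**hp)),
}

REGRESSORS = {
    "linear": lambda hp, seed: LinearRegression(**hp),
    "ridge": lambda hp, seed: make_pipeline(StandardScaler(), Ridge(**hp)),
    "tree": lambda hp, seed: DecisionTreeRegressor(random_state=seed, **hp),
    "random_forest": lambda hp, seed: RandomForestRegressor(
        n_estimators=hp.pop("n_estimators", 200), random_state=seed, **hp
    ),
    "gradient_boosting": lambda hp, seed: GradientBoostingRegressor(
        random_state=seed, **hp
    ),
    "knn": lambda hp, seed: make_pipeline(StandardScaler(), KNeighborsRegressor(**hp)),
}


@dataclass
class ModelSpec:
    learner: str = "random_forest"
    hyperparams: dict = field(default_factory=dict)
    #: feature families to include (None = all three)
    families: set[str] | None = None
    rebalance: bool = False
    rebalance_ratio: float = 1.0
    #: keep only the k features most associated with the target (None = all)
    select_k: int | None = None
    seed: int = 0

    def build(self, binary: bool):
        registry = CLASSIFIERS if binary else REGRESSORS
        if self.learner not in registry:
            raise KeyError(
                f"unknown learner {self.learner!r}; choose from {sorted(registry)}"
            )
        return registry[self.learner](dict(self.hyperparams), self.seed)


@dataclass
class EvalReport:
    metric: str  # "auc" | "r2"
    value: float  # pooled over CV test folds (or the holdout value)
    fold_values: list[float] = field(default_factory=list)
    mae: float | None = None  # Cumming's prediction measure, continuous targets
    holdout_value: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "value": self.value,
            "fold_values": self.fold_values,
            "mae": self.mae,
            "holdout_value": self.holdout_value,
            "seed": self.seed,
        }


@dataclass
class FittedModel:
    estimator: object
    columns: list[str]
    target: str
    binary: bool
    spec: ModelSpec
    train_years: tuple[int, ...]

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        X = X.reindex(columns=self.columns, fill_value=0.0)
        if self.binary and hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X.to_numpy())[:, 1]
        return np.asarray(self.estimator.predict(X.to_numpy()), dtype=float)


def _prepare(
    matrix: FeatureMatrix, spec: ModelSpec, target: str
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    sub = matrix.select(families=spec.families) if spec.families else matrix
    X = sub.encoded()
    y = matrix.data[target]
    years = matrix.data.index.get_level_values("index_year").to_numpy()
    return X, y, years

def _is_binary(y: pd.Series) -> bool:
    return set(pd.unique(y)) <= {0, 1}


def _metric(binary: bool, y_true, y_score) -> float:
    return float(roc_auc_score(y_true, y_score)) if binary else float(r2_score(y_true, y_score))


def rebalance(
    X: np.ndarray,
    y: np.ndarray,
    target_ratio: float = 1.0,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling by convex interpolation.

    New minority points are drawn on segments between a random minority
    point and one of its k nearest minority neighbours, until the
    minority count reaches ``target_ratio`` times the majority count.
    Already-balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("rebalance expects exactly two classes")
    mi = int(np.argmin(counts))
    minority, majority = classes[mi], classes[1 - mi]
    n_min, n_maj = counts[mi], counts[1 - mi]
    if n_min < 2:
        raise ValueError("minority class must have at least 2 rows")
    n_new = int(round(target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return X, y
    Xm = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    nb = idx[base, rng.integers(1, k + 1, size=n_new)]
    u = rng.uniform(size=(n_new, 1))
    X_new = Xm[base] + u * (Xm[nb] - Xm[base])
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)]),
    )


def train_and_cv(
    matrix: FeatureMatrix,
    spec: ModelSpec,
    target: str = "label",
    n_folds: int = 10,
    train_years: list[int] | None = None,
) -> tuple[FittedModel, EvalReport]:
    """Fit under stratified k-fold CV on the training years.

    Rebalancing (if requested) touches only each fold's training portion;
    the pooled metric is computed from out-of-fold predictions. The final
    model is refit on all training rows. Holdout-year rows are never seen
    here.
    """
    X, y, years = _prepare(matrix, spec, target)
    if train_years is None:
        train_years = sorted(set(years))[:-1] if len(set(years)) > 1 else sorted(set(years))
    in_train = np.isin(years, list(train_years))
    Xt, yt = X[in_train], y[in_train]
    binary = _is_binary(yt)
    if binary:
        counts = yt.value_counts()
        if len(counts) < 2:
            raise ValueError("training data contain a single class")
        if counts.min() < n_folds:
            raise ValueError(
                f"need at least {n_folds} rows per class for {n_folds}-fold stratified CV"
            )
        splitter = StratifiedKFold(n_folds, shuffle=True, random_state=spec.seed)
        splits = splitter.split(Xt, yt)
    else:
        splitter = KFold(n_folds, shuffle=True, random_state=spec.seed)
        splits = splitter.split(Xt)

    if spec.select_k is not None:
        keep = _top_associated(Xt, yt, spec.select_k)
        Xt = Xt[keep]
        X = X[keep]

    oof = np.full(len(Xt), np.nan)
    fold_values = []
    Xa, ya = Xt.to_numpy(), yt.to_numpy()
    for tr, te in splits:
        Xtr, ytr = Xa[tr], ya[tr]
        if spec.rebalance and binary:
            Xtr, ytr = rebalance(Xtr, ytr, spec.rebalance_ratio, seed=spec.seed)
        est = spec.build(binary)
        est.fit(Xtr, ytr)
        score = (
            est.predict_proba(Xa[te])[:, 1]
            if binary and hasattr(est, "predict_proba")
            else est.predict(Xa[te])
        )
        oof[te] = score
        fold_values.append(_metric(binary, ya[te], score))

    report = EvalReport(
        metric="auc" if binary else "r2",
        value=_metric(binary, ya, oof),
        fold_values=fold_values,
        mae=None if binary else float(mean_absolute_error(ya, oof)),
        seed=spec.seed,
    )
    Xfit, yfit = Xa, ya
    if spec.rebalance and binary:
        Xfit, yfit = rebalance(Xfit, yfit, spec.rebalance_ratio, seed=spec.seed)
    final = spec.build(binary)
    final.fit(Xfit, yfit)
    fitted = FittedModel(final, list(Xt.columns), target, binary, spec, tuple(train_years))
    return fitted, report


def evaluate_holdout(
    fitted: FittedModel, matrix: FeatureMatrix, year: int
) -> EvalReport:
    """Score the fitted model once on the holdout year's rows."""
    if year in fitted.train_years:
        raise ValueError(f"year {year} was used for training")
    sub = matrix.select(families=fitted.spec.families) if fitted.spec.families else matrix
    X = sub.encoded()
    years = matrix.data.index.get_level_values("index_year").to_numpy()
    mask = years == year
    if not mask.any():
        raise ValueError(f"no rows in holdout year {year}")
    Xh = X[mask]
    yh = matrix.data[fitted.target][mask]
    score = fitted.predict_risk(Xh)
    return EvalReport(
        metric="auc" if fitted.binary else "r2",
        value=_metric(fitted.binary, yh, score),
        mae=None if fitted.binary else float(mean_absolute_error(yh, score)),
        holdout_value=_metric(fitted.binary, yh, score),
    )


def _top_associated(X: pd.DataFrame, y: pd.Series, k: int) -> list[str]:
    assoc = _associations(X, y)
    return list(assoc.sort_values(ascending=False).index[:k])


def _associations(X: pd.DataFrame, y: pd.Series) -> pd.Series:
    """Absolute association of each column with the target.

    Pearson |r| for numeric columns; correlation ratio (eta) for object
    columns. Constant columns are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    out = {}
    dropped = []
    for col in X.columns:
        s = X[col]
        if s.dtype == object:
            groups = [y[np.asarray(s == v)] for v in pd.unique(s)]
            ss_between = sum(len(g) * (g.mean() - y.mean()) ** 2 for g in groups if len(g))
            ss_total = ((y - y.mean()) ** 2).sum()
            out[col] = np.sqrt(ss_between / ss_total) if ss_total > 0 else 0.0
            continue
        x = np.asarray(s, dtype=float)
        if np.std(x) == 0:
            dropped.append(col)
            continue
        if np.std(y) == 0:
            out[col] = 0.0
            continue
        out[col] = abs(float(np.corrcoef(x, y)[0, 1]))
    if dropped:
        warnings.warn(
            f"constant features excluded from association ranking: {dropped}",
            stacklevel=2,
        )
    return pd.Series(out)


def backward_eliminate(
    matrix: FeatureMatrix,
    spec: ModelSpec,
    target: str = "label",
    tolerance: float = 0.02,
    n_folds: int = 10,
    train_years: list[int] | None = None,
) -> list[str]:
    """Greedy backward elimination at an accuracy tolerance.

    Repeatedly drops the raw attribute whose removal degrades the CV
    metric least, as long as the metric stays within ``tolerance`` of the
    full model's; ties break by attribute name. Fold seeds are shared
    across evaluations for comparability.
    """

    def cv_metric(names: list[str]) -> float:
        sub = FeatureMatrix(
            matrix.data[names + [c for c in ("label", "secondary", "cost_outcome") if c in matrix.data.columns]],
            {k: v for k, v in matrix.feature_meta.items() if k in names},
        )
        _, rep = train_and_cv(sub, spec, target, n_folds, train_years)
        return rep.value

    remaining = sorted(matrix.feature_names)
    if len(remaining) < 2:
        raise ValueError("backward elimination needs at least 2 attributes")
    full_metric = cv_metric(remaining)
    while len(remaining) > 1:
        trials = [
            (cv_metric([f for f in remaining if f != cand]), cand)
            for cand in remaining
        ]
        best_metric, best_cand = max(trials, key=lambda t: (t[0], t[1]))
        # keep name-order tie-break deterministic: among equal metrics, first name
        ties = sorted(c for m, c in trials if m == best_metric)
        best_cand = ties[0]
        if best_metric >= full_metric - tolerance:
            remaining.remove(best_cand)
        else:
            break
    return remaining


def reduce_features(
    X: pd.DataFrame,
    target: pd.Series,
    n_keep: int,
    n_groups: int,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Keep the top-associated features; merge the rest into group features.

    The ``n_keep`` features with the largest absolute association with the
    target stay as-is. Remaining features are clustered into ``n_groups``
    by average-linkage agglomeration on the distance 1 - |corr|, and each
    cluster is replaced by the mean of its standardized members. Returns
    the reduced frame and a map feature -> "kept" | "merged_<i>".
    """
    from sklearn.cluster import AgglomerativeClustering

    if n_keep + n_groups > X.shape[1]:
        raise ValueError("n_keep + n_groups exceeds the feature count")
    work = X.copy()
    for col in work.columns:
        if work[col].dtype == object:
            work[col] = pd.factorize(work[col])[0].astype(float)
    assoc = _associations(work, target)
    ranked = assoc.sort_values(ascending=False)
    kept = list(ranked.index[:n_keep])
    rest = [c for c in ranked.index if c not in kept]
    mapping = {c: "kept" for c in kept}
    out = work[kept].copy()
    if n_groups == 0 or not rest:
        return out, mapping
    if len(rest) < n_groups:
        raise ValueError("fewer remaining features than requested groups")
    R = work[rest]
    corr = np.abs(np.corrcoef(R.to_numpy(), rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    labels = AgglomerativeClustering(
        n_clusters=n_groups, metric="precomputed", linkage="average"
    ).fit_predict(1.0 - corr)
    Z = (R - R.mean()) / R.std(ddof=0).replace(0, 1.0)
    for g in range(n_groups):
        members = [rest[i] for i in range(len(rest)) if labels[i] == g]
        out[f"merged_{g}"] = Z[members].mean(axis=1)
        for m in members:
            mapping[m] = f"merged_{g}"
    return out, mapping


def compare_feature_families(
    matrix: FeatureMatrix,
    spec_full: ModelSpec,
    spec_reduced: ModelSpec,
    target: str = "label",
    holdout_year: int | None = None,
    n_folds: int = 10,
    threshold: float = 0.10,
    relative: bool = False,
) -> dict:
    """Train two specs identically and test the added-value hypothesis.

    The decision accepts when the full model's holdout metric exceeds the
    reduced model's by at least ``threshold`` — an absolute difference of
    0.10 in AUC / R^2 by default; set ``relative=True`` for a relative
    reading.
    """
    years = sorted(set(matrix.data.index.get_level_values("index_year")))
    if holdout_year is None:
        holdout_year = years[-1]
    train_years = [y for y in years if y != holdout_year]
    fit_a, rep_a = train_and_cv(matrix, spec_full, target, n_folds, train_years)
    fit_b, rep_b = train_and_cv(matrix, spec_reduced, target, n_folds, train_years)
    hold_a = evaluate_holdout(fit_a, matrix, holdout_year)
    hold_b = evaluate_holdout(fit_b, matrix, holdout_year)
    diff = hold_a.value - hold_b.value
    crit = diff / abs(hold_b.value) if relative and hold_b.value != 0 else diff
    return {
        "full": {"cv": rep_a, "holdout": hold_a, "model": fit_a},
        "reduced": {"cv": rep_b, "holdout": hold_b, "model": fit_b},
        "difference": diff,
        "accept": bool(crit >= threshold),
        "threshold": threshold,
        "relative": relative,
    }
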