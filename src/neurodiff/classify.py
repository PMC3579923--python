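"""Fisher-discriminant ensemble with nested, stratified cross-validation.

Training follows a fixed protocol on a feature table of two conditions (an
undifferentiated and a differentiated reference):

1. the rows are split into ``n_folds`` stratified folds (balanced over
   condition and day);
2. a stepwise forward/backward search selects the feature set, scoring
   candidate sets by an inner cross-validated correctness rate and judging
   each leave-one-fold-out repetition's result by the Gini index on the
   held-out fold over all days;
3. the training day is the day whose day-restricted training generalizes
   best (largest mean held-out Gini, again pooled over all days);
4. five independent discriminants are trained on the five disjoint
   consecutive fold pairs, restricted to the training day; each member gets
   its own decision threshold (where sensitivity equals specificity) and
   dispersion from the folds it was not trained on.

Scores are standardized per member, z = (s - theta) / dispersion, so that 0
is the decision boundary for every member and the ensemble verdict is the
median standardized score: z > 0 means differentiated.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import SchemaError, ValidationError
from .screening import _feature_columns


@dataclasses.dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    inner_folds: int = 5
    stop_epsilon: float = 0.01
    stratify_keys: tuple[str, ...] = ("condition", "day")
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 4 or self.n_folds % 2:
            raise ValidationError("n_folds must be even and >= 4 (disjoint fold pairs)")
        if not 0 < self.stop_epsilon < 1:
            raise ValidationError("stop_epsilon must lie in (0, 1)")
        if self.inner_folds < 2:
            raise ValidationError("inner_folds must be >= 2")


@dataclasses.dataclass
class FDAModel:
    """One linear discriminant: score(x) = weights . x + offset.

    The offset centres the midpoint of the class means at zero; ``theta`` is
    the calibrated decision threshold on the raw score scale and
    ``dispersion`` the score scale used for standardization.
    """

    feature_names: list
    weights: np.ndarray
    offset: float
    theta: float = float("nan")
    dispersion: float = float("nan")
    training_fold_ids: tuple | None = None
    training_day: int | None = None

    def score(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in table.columns]
            if missing:
                raise SchemaError(f"missing feature columns: {missing}")
            X = table[self.feature_names].to_numpy(dtype=np.float64)
        else:
            X = np.asarray(table, dtype=np.float64)
        return X @ self.weights + self.offset

    def z(self, table) -> np.ndarray:
        return (self.score(table) - self.theta) / self.dispersion

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "weights": np.asarray(self.weights).tolist(),
            "offset": float(self.offset),
            "theta": float(self.theta),
            "dispersion": float(self.dispersion),
            "training_fold_ids": list(self.training_fold_ids or []),
            "training_day": self.training_day,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FDAModel":
        return cls(feature_names=list(d["feature_names"]),
                   weights=np.asarray(d["weights"], dtype=np.float64),
                   offset=float(d["offset"]), theta=float(d["theta"]),
                   dispersion=float(d["dispersion"]),
                   training_fold_ids=tuple(d.get("training_fold_ids") or ()),
                   training_day=d.get("training_day"))


def fit_fda(X, y, feature_names=None) -> FDAModel:
    """Fisher's linear discriminant: pooled within-class scatter versus the
    between-class mean difference; singular scatter handled by pseudo-inverse.

    The score is positive towards class 1 and zero at the midpoint of the
    projected class means.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError("FDA needs exactly two classes in y")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValidationError("each class needs at least two rows")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Sw = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    w = np.linalg.pinv(Sw) @ (mu1 - mu0)
    offset = -float(w @ ((mu0 + mu1) / 2.0))
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(X.shape[1])]
    return FDAModel(feature_names=names, weights=w, offset=offset)


class FisherDiscriminant(BaseEstimator, ClassifierMixin):
    """Minimal scikit-learn estimator around :func:`fit_fda`."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.model_ = fit_fda(X, y)
        self.coef_ = self.model_.weights[None, :]
        self.intercept_ = np.array([self.model_.offset])
        return self

    def decision_function(self, X):
        return self.model_.score(np.asarray(X, dtype=np.float64))

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def gini_index(scores, labels) -> float:
    """Gini coefficient of separation, 2*AUC - 1, ties counted one half."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    pos = y == np.max(y) if y.dtype != bool else y
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("Gini index needs both classes present")
    ranks = rankdata(s)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(2.0 * auc - 1.0)


def calibrate_threshold(scores, labels) -> float:
    """Decision threshold where sensitivity equals specificity on the ROC.

    Candidate cuts are the observed scores and the midpoints between
    consecutive distinct scores (plus sentinels outside the range); the
    candidate with the smallest |sensitivity - specificity| wins, plateaus
    resolved by taking the middle candidate, which lands between separated
    classes at the centre of the separating gap.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    pos = y == np.max(y) if y.dtype != bool else y
    s1, s0 = s[pos], s[~pos]
    if s1.size == 0 or s0.size == 0:
        raise ValidationError("threshold calibration needs both classes")
    uniq = np.unique(s)
    cand = np.concatenate([[uniq[0] - 1.0], uniq,
                           (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    cand = np.unique(cand)
    sens = (s1[None, :] > cand[:, None]).mean(axis=1)
    spec = (s0[None, :] <= cand[:, None]).mean(axis=1)
    gap = np.abs(sens - spec)
    best = np.flatnonzero(gap == gap.min())
    return float(cand[best[len(best) // 2]])


def make_stratified_folds(table: pd.DataFrame, n_folds: int,
                          keys=("condition", "day"), seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment, round-robin within strata."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(table), dtype=int)
    pos = np.arange(len(table))
    for _, idx in table.groupby(list(keys), sort=True).indices.items():
        perm = rng.permutation(len(idx))
        folds[pos[idx][perm]] = np.arange(len(idx)) % n_folds
    return folds


def _correctness_rate(X, y, inner_folds: np.ndarray) -> float:
    """Unweighted accuracy of FDA at the class-midpoint cut, inner CV mean."""
    accs = []
    for f in np.unique(inner_folds):
        tr, te = inner_folds != f, inner_folds == f
        if len(np.unique(y[tr])) < 2 or te.sum() == 0:
            continue
        model = fit_fda(X[tr], y[tr])
        pred = model.score(X[te]) > 0
        accs.append(float((pred == (y[te] == 1)).mean()))
    if not accs:
        raise ValidationError("inner folds degenerate: a class is missing")
    return float(np.mean(accs))


def _greedy_search(df: pd.DataFrame, y: np.ndarray, candidates: list,
                   inner_folds: np.ndarray, stop_epsilon: float) -> list:
    current: list = []
    Xall = df[candidates].to_numpy(dtype=np.float64)
    col = {f: i for i, f in enumerate(candidates)}
    base = float(max(y.mean(), 1 - y.mean()))
    current_rate = base
    for _ in range(2 * len(candidates)):
        moves = []
        for f in candidates:
            if f not in current:
                moves.append(sorted(current + [f]))
        if len(current) > 1:
            for f in current:
                moves.append(sorted(set(current) - {f}))
        scored = []
        for mv in moves:
            rate = _correctness_rate(Xall[:, [col[f] for f in mv]], y, inner_folds)
            scored.append((rate, len(mv), tuple(mv)))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        best_rate, _, best_set = scored[0]
        if best_rate - current_rate < stop_epsilon:
            break
        current, current_rate = list(best_set), best_rate
    return current


def stepwise_feature_search(table: pd.DataFrame, candidate_features: list,
                            cfg: CVConfig, neg_condition: str, pos_condition: str,
                            folds: np.ndarray | None = None) -> list:
    """Greedy forward/backward feature selection under nested CV.

    For each leave-one-fold-out repetition the greedy loop runs on the
    training folds (candidate sets scored by the inner-CV correctness rate,
    stopping once the best move improves it by less than ``stop_epsilon``);
    the repetition's set is then judged by the Gini index on the held-out
    fold over all days, and the best set across repetitions is returned
    (ties: fewer features, then lexicographic order).
    """
    if not candidate_features:
        raise ValidationError("candidate feature list is empty")
    df = _training_view(table, neg_condition, pos_condition)
    y = (df["condition"] == pos_condition).to_numpy().astype(int)
    if folds is None:
        folds = make_stratified_folds(df, cfg.n_folds, cfg.stratify_keys, cfg.seed)
    results = []
    for o in range(cfg.n_folds):
        tr = folds != o
        df_tr, y_tr = df[tr], y[tr]
        inner = make_stratified_folds(df_tr, cfg.inner_folds, cfg.stratify_keys,
                                      cfg.seed + 1000 + o)
        chosen = _greedy_search(df_tr, y_tr, list(candidate_features), inner,
                                cfg.stop_epsilon)
        if not chosen:
            continue
        model = fit_fda(df_tr[chosen].to_numpy(dtype=np.float64), y_tr, chosen)
        g = gini_index(model.score(df[~tr]), y[~tr])
        results.append((g, len(chosen), tuple(chosen)))
    if not results:
        raise ValidationError("stepwise search selected no features in any repetition")
    results.sort(key=lambda t: (-t[0], t[1], t[2]))
    return list(results[0][2])


def select_training_day(table: pd.DataFrame, feature_set: list, cfg: CVConfig,
                        neg_condition: str, pos_condition: str,
                        folds: np.ndarray | None = None) -> int:
    """Pick the day whose day-restricted training generalizes best.

    Per candidate day, leave-one-fold-out training on that day's rows and
    Gini evaluation on the held-out fold pooled over all days; the day with
    the largest mean Gini wins, ties going to the earliest day.
    """
    df = _training_view(table, neg_condition, pos_condition)
    y = (df["condition"] == pos_condition).to_numpy().astype(int)
    if folds is None:
        folds = make_stratified_folds(df, cfg.n_folds, cfg.stratify_keys, cfg.seed)
    days = sorted(df["day"].unique())
    if len(days) == 1:
        return int(days[0])
    mean_gini = {}
    for day in days:
        on_day = (df["day"] == day).to_numpy()
        if len(np.unique(y[on_day])) < 2:
            warnings.warn(f"day {day} lacks a class and is skipped", stacklevel=2)
            continue
        ginis = []
        for o in range(cfg.n_folds):
            tr = (folds != o) & on_day
            te = folds == o
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            model = fit_fda(df.loc[tr, feature_set].to_numpy(dtype=np.float64),
                            y[tr], feature_set)
            ginis.append(gini_index(model.score(df[te]), y[te]))
        if ginis:
            mean_gini[int(day)] = float(np.mean(ginis))
    if not mean_gini:
        raise ValidationError("no day with both classes present")
    best = max(mean_gini.values())
    return min(d for d, g in mean_gini.items() if g == best)


@dataclasses.dataclass
class FDAEnsemble:
    members: list            # five FDAModel
    selected_features: list
    training_day: int
    cv_layout: dict          # image_path -> fold id (training provenance)
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "selected_features": list(self.selected_features),
            "training_day": int(self.training_day),
            "members": [m.to_dict() for m in self.members],
            "cv_layout": self.cv_layout,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FDAEnsemble":
        return cls(members=[FDAModel.from_dict(m) for m in d["members"]],
                   selected_features=list(d["selected_features"]),
                   training_day=int(d["training_day"]),
                   cv_layout=dict(d.get("cv_layout", {})),
                   provenance=dict(d.get("provenance", {})))


def _training_view(table: pd.DataFrame, neg: str, pos: str) -> pd.DataFrame:
    for col in ("condition", "day", "is_outlier"):
        if col not in table.columns:
            raise SchemaError(f"feature table is missing column {col!r}")
    df = table[table["condition"].isin([neg, pos]) & ~table["is_outlier"]]
    if df.empty or df["condition"].nunique() < 2:
        raise ValidationError("training table must contain both conditions")
    return df.reset_index(drop=True)


def train_ensemble(table: pd.DataFrame, undiff_condition: str, diff_condition: str,
                   screening=None, cfg: CVConfig | None = None) -> FDAEnsemble:
    """Full training protocol: feature search, day selection, five members.

    ``screening`` may be a list of candidate feature names or an
    :class:`~neurodiff.screening.AutocorrelationReport`; by default all
    feature columns are candidates. Outlier-flagged rows are excluded.
    """
    cfg = cfg or CVConfig()
    if screening is None:
        candidates = _feature_columns(table)
    elif hasattr(screening, "selected_features"):
        candidates = list(screening.selected_features)
    else:
        candidates = list(screening)
    df = _training_view(table, undiff_condition, diff_condition)
    y = (df["condition"] == diff_condition).to_numpy().astype(int)
    folds = make_stratified_folds(df, cfg.n_folds, cfg.stratify_keys, cfg.seed)
    for f in range(cfg.n_folds):
        if len(np.unique(y[folds == f])) < 2:
            raise ValidationError(
                f"fold {f} lacks a class: check outlier contamination/stratification")

    selected = stepwise_feature_search(df, candidates, cfg, undiff_condition,
                                       diff_condition, folds=folds)
    day = select_training_day(df, selected, cfg, undiff_condition,
                              diff_condition, folds=folds)

    members = []
    n_members = cfg.n_folds // 2
    for i in range(n_members):
        pair = (2 * i, 2 * i + 1)
        tr = np.isin(folds, pair) & (df["day"] == day).to_numpy()
        rest = ~np.isin(folds, pair)
        assert not np.any(tr & rest), "training rows leaked into the holdout"
        model = fit_fda(df.loc[tr, selected].to_numpy(dtype=np.float64),
                        y[tr], selected)
        s_rest = model.score(df[rest])
        theta = calibrate_threshold(s_rest, y[rest])
        dispersion = float(np.std(s_rest, ddof=1))
        if dispersion <= 0:
            raise ValidationError("degenerate dispersion on holdout folds")
        members.append(dataclasses.replace(model, theta=theta,
                                           dispersion=dispersion,
                                           training_fold_ids=pair,
                                           training_day=int(day)))
    layout = {str(p): int(f) for p, f in zip(df["image_path"], folds)}
    return FDAEnsemble(
        members=members, selected_features=selected, training_day=int(day),
        cv_layout=layout,
        provenance={"n_folds": cfg.n_folds, "inner_folds": cfg.inner_folds,
                    "stop_epsilon": cfg.stop_epsilon, "seed": cfg.seed,
                    "neg_condition": undiff_condition,
                    "pos_condition": diff_condition,
                    "n_training_rows": int(len(df))},
    )


def standardize_and_classify(ensemble: FDAEnsemble, table: pd.DataFrame) -> pd.DataFrame:
    """Member-wise standardized scores, their median, and the verdict.

    Outlier-flagged rows keep their scores but get no verdict.
    """
    missing = [f for f in ensemble.selected_features if f not in table.columns]
    if missing:
        raise SchemaError(f"missing feature columns: {missing}")
    out = table[[c for c in ("image_path", "well", "day", "condition",
                             "replicate", "is_outlier") if c in table.columns]].copy()
    zs = np.column_stack([m.z(table) for m in ensemble.members])
    for i in range(zs.shape[1]):
        out[f"z_{i}"] = zs[:, i]
    out["z_median"] = np.median(zs, axis=1)
    verdict = pd.array(out["z_median"] > 0, dtype="boolean")
    if "is_outlier" in out.columns:
        verdict[out["is_outlier"].to_numpy(dtype=bool)] = pd.NA
    out["differentiated"] = verdict
    return out


def holdout_gini_per_day(ensemble: FDAEnsemble, table: pd.DataFrame,
                         neg_condition: str, pos_condition: str) -> pd.Series:
    """Median member Gini per day, each member judged on rows outside its
    training folds (rows unknown to the cv layout count as held out)."""
    df = _training_view(table, neg_condition, pos_condition)
    y = (df["condition"] == pos_condition).to_numpy().astype(int)
    folds = df["image_path"].map(lambda p: ensemble.cv_layout.get(str(p), -1)).to_numpy()
    result = {}
    for day in sorted(df["day"].unique()):
        on_day = (df["day"] == day).to_numpy()
        ginis = []
        for m in ensemble.members:
            held = on_day & ~np.isin(folds, m.training_fold_ids)
            if len(np.unique(y[held])) < 2:
                continue
            ginis.append(gini_index(m.score(df[held]), y[held]))
        if ginis:
            result[int(day)] = float(np.median(ginis))
    return pd.Series(result, name="gini").sort_index()


class FDAEnsembleClassifier(BaseEstimator):
    """Estimator front end for the full training protocol.

    ``fit`` consumes a feature table (metadata + feature columns) and trains
    the five-member ensemble; ``decision_function`` returns the median
    standardized score and ``predict`` the boolean differentiation verdict.
    """

    def __init__(self, neg_condition: str = "CTL", pos_condition: str = "NGF",
                 candidate_features=None, n_folds: int = 10, inner_folds: int = 5,
                 stop_epsilon: float = 0.01, seed: int = 0):
        self.neg_condition = neg_condition
        self.pos_condition = pos_condition
        self.candidate_features = candidate_features
        self.n_folds = n_folds
        self.inner_folds = inner_folds
        self.stop_epsilon = stop_epsilon
        self.seed = seed

    def _config(self) -> CVConfig:
        return CVConfig(n_folds=self.n_folds, inner_folds=self.inner_folds,
                        stop_epsilon=self.stop_epsilon, seed=self.seed)

    def fit(self, table: pd.DataFrame, y=None):
        self.ensemble_ = train_ensemble(table, self.neg_condition,
                                        self.pos_condition,
                                        screening=self.candidate_features,
                                        cfg=self._config())
        self.selected_features_ = list(self.ensemble_.selected_features)
        self.training_day_ = self.ensemble_.training_day
        return self

    def decision_function(self, table: pd.DataFrame) -> np.ndarray:
        return standardize_and_classify(self.ensemble_, table)["z_median"].to_numpy()

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.decision_function(table) > 0

    def score_table(self, table: pd.DataFrame) -> pd.DataFrame:
        return standardize_and_classify(self.ensemble_, table)
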