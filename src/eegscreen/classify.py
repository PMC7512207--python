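"""Trial classifiers: Gaussian discriminants (LDA/QDA) and an MLP.

LDA/QDA are fitted directly as Gaussian class-conditional models (pooled or
per-class covariance) so their parameters serialize to JSON.  The MLP is a
single logistic-sigmoid hidden layer with a 3-unit softmax output and an L2
weight penalty, trained with scikit-learn's L-BFGS backend; predictions are
made by an explicit forward pass through the stored weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import softmax, expit
from sklearn.neural_network import MLPClassifier

from .core import ConfigurationError, GROUPS
from .evaluate import cohens_kappa, confusion_matrix3


def class_order(labels) -> list[str]:
    """Canonical class order: (HC, MCI, AD) first, any extras sorted after."""
    present = set(labels)
    ordered = [g for g in GROUPS if g in present]
    return ordered + sorted(present - set(GROUPS))


@dataclass
class StandardizationStats:
    """Per-feature mean and SD computed on the training split."""

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame, features: list[str]) -> "StandardizationStats":
        x = table[features].to_numpy(dtype=float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            bad = [f for f, s in zip(features, sd) if s <= 0]
            raise ConfigurationError(f"zero-variance feature(s): {bad}")
        return cls(features=list(features), mean=mean, sd=sd)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[self.features] = (table[self.features].to_numpy(dtype=float)
                              - self.mean) / self.sd
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[self.features] = (table[self.features].to_numpy(dtype=float)
                              * self.sd + self.mean)
        return out

    def to_dict(self) -> dict:
        return {"features": self.features, "mean": self.mean.tolist(),
                "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationStats":
        return cls(d["features"], np.asarray(d["mean"]), np.asarray(d["sd"]))


def standardize(table: pd.DataFrame,
                stats: StandardizationStats) -> pd.DataFrame:
    """Apply training-split standardization to any table."""
    return stats.apply(table)


@dataclass(frozen=True)
class MLPConfig:
    """MLP hyperparameters: hidden width n_h and weight decay u."""

    n_hidden: int = 11
    weight_decay: float = 45.0
    n_restarts: int = 30
    max_iterations: int = 400
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1 or self.n_restarts < 1:
            raise ConfigurationError("n_hidden and n_restarts must be >= 1")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be non-negative")


@dataclass
class TrainedModel:
    """A fitted LDA, QDA or MLP with its standardization statistics."""

    kind: str
    classes: list[str]
    features: list[str]
    stats: StandardizationStats | None = None
    # Gaussian discriminant parameters
    means: np.ndarray | None = None          # (K, p)
    covariances: np.ndarray | None = None    # (p, p) pooled or (K, p, p)
    priors: np.ndarray | None = None
    # MLP parameters
    coefs: list[np.ndarray] | None = None
    intercepts: list[np.ndarray] | None = None
    mlp_config: MLPConfig | None = None

    # -- prediction ---------------------------------------------------------

    def _design(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.features if f not in features.columns]
            if missing:
                raise ConfigurationError(f"missing feature column(s): {missing}")
            x = features[self.features].to_numpy(dtype=float)
        else:
            x = np.asarray(features, dtype=float)
            if x.shape[1] != len(self.features):
                raise ConfigurationError("feature-count mismatch")
        return x

    def _log_posteriors_gda(self, x: np.ndarray) -> np.ndarray:
        k = len(self.classes)
        out = np.empty((x.shape[0], k))
        for i in range(k):
            cov = (self.covariances if self.covariances.ndim == 2
                   else self.covariances[i])
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise ConfigurationError("non positive-definite covariance")
            diff = x - self.means[i]
            maha = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
            out[:, i] = np.log(self.priors[i]) - 0.5 * (logdet + maha)
        return out

    def _mlp_forward(self, x: np.ndarray) -> np.ndarray:
        h = expit(x @ self.coefs[0] + self.intercepts[0])
        return softmax(h @ self.coefs[1] + self.intercepts[1], axis=1)

    def predict_proba(self, features) -> np.ndarray:
        x = self._design(features)
        if self.kind in ("LDA", "QDA"):
            return softmax(self._log_posteriors_gda(x), axis=1)
        return self._mlp_forward(x)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "classes": self.classes,
                   "features": self.features,
                   "stats": self.stats.to_dict() if self.stats else None}
        if self.kind in ("LDA", "QDA"):
            d["means"] = self.means.tolist()
            d["covariances"] = self.covariances.tolist()
            d["priors"] = self.priors.tolist()
        else:
            d["coefs"] = [c.tolist() for c in self.coefs]
            d["intercepts"] = [c.tolist() for c in self.intercepts]
            d["mlp_config"] = asdict(self.mlp_config)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        stats = (StandardizationStats.from_dict(d["stats"])
                 if d.get("stats") else None)
        model = cls(kind=d["kind"], classes=list(d["classes"]),
                    features=list(d["features"]), stats=stats)
        if d["kind"] in ("LDA", "QDA"):
            model.means = np.asarray(d["means"])
            model.covariances = np.asarray(d["covariances"])
            model.priors = np.asarray(d["priors"])
        else:
            model.coefs = [np.asarray(c) for c in d["coefs"]]
            model.intercepts = [np.asarray(c) for c in d["intercepts"]]
            model.mlp_config = MLPConfig(**d["mlp_config"])
        return model


def _regularize(cov: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    p = cov.shape[0]
    reg = cov + ridge * (np.trace(cov) / p) * np.eye(p)
    if np.linalg.matrix_rank(reg) < p:
        raise ConfigurationError("singular covariance even after ridge")
    return reg


def _fit_gda(features: pd.DataFrame | np.ndarray, labels, pooled: bool,
             feature_names: list[str] | None = None,
             stats: StandardizationStats | None = None) -> TrainedModel:
    labels = np.asarray(labels)
    classes = class_order(labels)
    if isinstance(features, pd.DataFrame):
        feature_names = feature_names or list(features.columns)
        x = features[feature_names].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        feature_names = feature_names or [f"x{i}" for i in range(x.shape[1])]
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    n, p = x.shape
    means, covs, priors = [], [], []
    for c in classes:
        xc = x[labels == c]
        if xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
        means.append(xc.mean(axis=0))
        covs.append(np.cov(xc, rowvar=False, ddof=1) * (xc.shape[0] - 1))
        priors.append(xc.shape[0] / n)
    means = np.asarray(means)
    priors = np.asarray(priors)
    if pooled:
        cov = _regularize(sum(covs) / (n - len(classes)))
    else:
        cov = np.asarray([_regularize(s / (np.sum(labels == c) - 1))
                          for s, c in zip(covs, classes)])
    return TrainedModel(kind="LDA" if pooled else "QDA", classes=classes,
                        features=feature_names, stats=stats, means=means,
                        covariances=cov, priors=priors)


def train_lda(features, labels, feature_names=None, stats=None) -> TrainedModel:
    """Gaussian discriminant with one pooled covariance (linear boundaries)."""
    return _fit_gda(features, labels, pooled=True,
                    feature_names=feature_names, stats=stats)


def train_qda(features, labels, feature_names=None, stats=None) -> TrainedModel:
    """Gaussian discriminant with per-class covariances (quadratic boundaries)."""
    return _fit_gda(features, labels, pooled=False,
                    feature_names=feature_names, stats=stats)


def train_mlp(features, labels, config: MLPConfig,
              feature_names=None, stats=None) -> TrainedModel:
    """Single-hidden-layer sigmoid MLP with softmax output, L2-penalized
    cross-entropy loss, deterministic given config.rng_seed."""
    labels = np.asarray(labels)
    classes = class_order(labels)
    if len(classes) < 3:
        raise ConfigurationError("the MLP is defined for >= 3 classes "
                                 "(one softmax output per group)")
    if isinstance(features, pd.DataFrame):
        feature_names = feature_names or list(features.columns)
        x = features[feature_names].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        feature_names = feature_names or [f"x{i}" for i in range(x.shape[1])]
    est = MLPClassifier(hidden_layer_sizes=(config.n_hidden,),
                        activation="logistic", solver="lbfgs",
                        alpha=config.weight_decay,
                        max_iter=config.max_iterations,
                        random_state=config.rng_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence: model still usable
        est.fit(x, labels)
    # reorder output units from sklearn's sorted classes_ to canonical order
    perm = [list(est.classes_).index(c) for c in classes]
    coefs = [est.coefs_[0].copy(), est.coefs_[1][:, perm].copy()]
    intercepts = [est.intercepts_[0].copy(), est.intercepts_[1][perm].copy()]
    return TrainedModel(kind="MLP", classes=classes, features=feature_names,
                        stats=stats, coefs=coefs, intercepts=intercepts,
                        mlp_config=config)


def predict_trials(model: TrainedModel, features) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-trial labels (argmax posterior, ties to earlier class) + posteriors."""
    proba = model.predict_proba(features)
    labels = np.asarray(model.classes, dtype=object)[np.argmax(proba, axis=1)]
    return labels, pd.DataFrame(proba, columns=model.classes)


def tune_mlp(table: pd.DataFrame, feature_names: list[str],
             grid_u=None, grid_nh=None, n_restarts: int = 30,
             cv: str = "loso", n_folds: int = 3, rng_seed: int = 0,
             max_iterations: int = 300, label_col: str = "group") -> MLPConfig:
    """Grid-search (u, n_h) by cross-validation over training subjects.

    For each grid point, held-out trial predictions are pooled over folds and
    scored with Cohen's kappa, averaged over n_restarts random
    initializations.  cv="loso" leaves one subject out per fold; cv="group"
    uses n_folds subject-stratified folds (cheaper, same leakage guarantee).
    Ties break toward smaller n_h, then smaller u.
    """
    grid_u = list(grid_u) if grid_u is not None else list(range(0, 101, 5))
    grid_nh = list(grid_nh) if grid_nh is not None else list(range(1, 21))
    if not grid_u or not grid_nh:
        raise ConfigurationError("empty tuning grid")

    subjects = table["subject_id"].to_numpy()
    labels = table[label_col].to_numpy()
    subj_ids = pd.unique(subjects)
    subj_group = {s: labels[subjects == s][0] for s in subj_ids}
    for g in set(labels):
        if sum(subj_group[s] == g for s in subj_ids) < (3 if cv == "loso" else 2):
            raise ValueError(f"too few training subjects in group {g!r}")

    if cv == "loso":
        folds = [[s] for s in subj_ids]
    elif cv == "group":
        rng = np.random.default_rng(rng_seed)
        folds = [[] for _ in range(n_folds)]
        for g in class_order(labels):
            members = [s for s in subj_ids if subj_group[s] == g]
            rng.shuffle(members)
            for i, s in enumerate(members):
                folds[i % n_folds].append(s)
    else:
        raise ConfigurationError(f"unknown cv scheme {cv!r}")

    order = class_order(labels)
    results: dict[tuple[float, int], float] = {}
    for u in grid_u:
        for nh in grid_nh:
            kappas = []
            for restart in range(n_restarts):
                seed = rng_seed + 1000 * restart
                pred = np.empty(len(table), dtype=object)
                for fold in folds:
                    held = np.isin(subjects, fold)
                    tr = table[~held]
                    stats = StandardizationStats.fit(tr, feature_names)
                    cfg = MLPConfig(n_hidden=nh, weight_decay=float(u),
                                    n_restarts=1, rng_seed=seed,
                                    max_iterations=max_iterations)
                    model = train_mlp(stats.apply(tr), labels[~held], cfg,
                                      feature_names=feature_names, stats=stats)
                    pred[held], _ = predict_trials(
                        model, stats.apply(table[held]))
                cm = confusion_matrix3(labels, pred, level="trial",
                                       classes=order)
                kappas.append(cohens_kappa(cm).kappa)
            results[(float(u), nh)] = float(np.mean(kappas))

    best = max(results.values())
    u, nh = min((k for k, v in results.items() if v == best),
                key=lambda k: (k[1], k[0]))
    return MLPConfig(n_hidden=nh, weight_decay=u, n_restarts=n_restarts,
                     max_iterations=max_iterations, rng_seed=rng_seed)
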