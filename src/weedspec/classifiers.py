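"""The five classification algorithms under the study's hyperparameters.

Random Forest (100 trees, unrestricted depth, 11 features per split), linear
SVM (C = 1.0, one-vs-rest, softmax over decision values for probabilities),
single-hidden-layer neural network (logistic activation, width auto-selected
as the geometric mean of input and output dimensions), maximum-entropy /
multinomial logistic regression (L2, lambda = 0.001 per sample), and SIMCA —
a per-class principal-component model assigning samples by orthogonal
(residual) distance to each class plane.

The first four stand on scikit-learn estimators; SIMCA is implemented here
from scratch, PC1-PC2 per class, and is cross-checked against a brute-force
projection oracle in the test suite.

Cross-validation is stratified by species and grouped by plant: plants are
dealt to folds round-robin after a seeded shuffle, so no plant straddles
folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .preprocessing import preprocess
from .roi_sampling import ROI

log = logging.getLogger(__name__)

ALGORITHMS = ("rf", "svm", "nn", "maxent", "simca")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "rf": {"n_trees": 100, "max_depth": None, "features_per_split": 11},
    "svm": {"C": 1.0},
    "nn": {"hidden_width": None, "max_iter": 400},  # None -> geometric-mean rule
    "maxent": {"lam": 0.001, "max_iter": 5000},
    "simca": {"n_components": 2},
}


@dataclass
class FeatureMatrix:
    """ROI-level feature rows with species labels and plant grouping."""

    X: np.ndarray
    labels: np.ndarray
    plant_ids: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.plant_ids = np.asarray(self.plant_ids)
        if not (len(self.X) == len(self.labels) == len(self.plant_ids)):
            raise ValueError("X, labels and plant_ids must have equal length")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[idx], self.labels[idx], self.plant_ids[idx],
                             self.feature_names)


def build_feature_matrix(
    rois: list[ROI], window: int = 5, apply_snv: bool = True
) -> FeatureMatrix:
    """Default feature vectors: preprocessed (smoothed + SNV) ROI mean spectra."""
    X = np.vstack([preprocess(r.mean_spectrum, window=window, apply_snv=apply_snv)
                   for r in rois])
    return FeatureMatrix(
        X,
        np.array([r.species for r in rois]),
        np.array([r.plant_id for r in rois]),
    )


# ---------------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------------

@dataclass
class ClassSubmodel:
    mean: np.ndarray
    loadings: np.ndarray  # (p, k) orthonormal
    eigenvalues: np.ndarray
    od_threshold: float  # critical orthogonal distance (mean + 3 sd on training)


@dataclass
class SimcaModel:
    classes: list[str]
    submodels: dict[str, ClassSubmodel]
    n_components: int


def fit_simca(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> SimcaModel:
    """One truncated PCA model per class (PC1-PC2 by default)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    submodels: dict[str, ClassSubmodel] = {}
    for cls in classes:
        Xc = X[y == cls]
        k = min(n_components, Xc.shape[0] - 1, Xc.shape[1])
        k = max(k, 0)
        mean = Xc.mean(axis=0)
        centred = Xc - mean
        if k > 0:
            _, s, vt = np.linalg.svd(centred, full_matrices=False)
            loadings = vt[:k].T
            eigenvalues = (s[:k] ** 2) / max(Xc.shape[0] - 1, 1)
        else:
            loadings = np.zeros((X.shape[1], 0))
            eigenvalues = np.zeros(0)
        resid = centred - (centred @ loadings) @ loadings.T
        od = np.linalg.norm(resid, axis=1)
        threshold = float(od.mean() + 3.0 * od.std()) or 1e-12
        submodels[cls] = ClassSubmodel(mean, loadings, eigenvalues, threshold)
    return SimcaModel(classes, submodels, n_components)


def orthogonal_distances(model: SimcaModel, X: np.ndarray) -> np.ndarray:
    """(n, n_classes) residual norms after projection on each class plane."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != next(iter(model.submodels.values())).mean.shape[0]:
        raise ValueError("feature dimension does not match the trained model")
    out = np.empty((X.shape[0], len(model.classes)))
    for j, cls in enumerate(model.classes):
        sm = model.submodels[cls]
        centred = X - sm.mean
        resid = centred - (centred @ sm.loadings) @ sm.loadings.T
        out[:, j] = np.linalg.norm(resid, axis=1)
    return out


def simca_classify(model: SimcaModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Assign one sample to the class with the smallest orthogonal distance.

    Ties break toward the smaller class index (argmin order).
    Returns (assigned class, per-class distances).
    """
    d = orthogonal_distances(model, np.atleast_2d(x))[0]
    return model.classes[int(np.argmin(d))], d


def _simca_proba(model: SimcaModel, X: np.ndarray) -> np.ndarray:
    """Distance-derived scores normalised to sum 1 (inverse-distance weights)."""
    d = orthogonal_distances(model, X)
    inv = 1.0 / (d + 1e-9)
    return inv / inv.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Unified training front end
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A fitted model with its class list, priors and probability interface."""

    algorithm: str
    model: object
    classes: np.ndarray
    seed: int
    class_priors: dict[str, float] = field(default_factory=dict)
    hyperparams: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.algorithm == "simca":
            d = orthogonal_distances(self.model, X)
            return np.array([self.model.classes[i] for i in np.argmin(d, axis=1)])
        return self.model.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Row-normalised class scores, columns ordered as ``self.classes``."""
        X = np.asarray(X, dtype=float)
        if self.algorithm == "simca":
            return _simca_proba(self.model, X)
        if self.algorithm == "svm":
            scores = self.model.decision_function(X)
            if scores.ndim == 1:  # binary: ovr decision value for class 1
                scores = np.column_stack([-scores, scores])
            scores = scores - scores.max(axis=1, keepdims=True)
            e = np.exp(scores)
            return e / e.sum(axis=1, keepdims=True)
        return self.model.predict_proba(X)


def _auto_hidden_width(n_features: int, n_classes: int) -> int:
    """Geometric-mean width rule for the auto-selected hidden layer."""
    return int(np.ceil(np.sqrt(n_features * n_classes)))


def train(
    algorithm: str,
    fm: FeatureMatrix,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Train one of the five algorithms at the study defaults.

    Deterministic given the seed.  Single-class input is rejected for all
    algorithms except SIMCA, whose per-class models are defined regardless.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    hp = {**DEFAULT_HYPERPARAMS[algorithm], **(hyperparams or {})}
    classes = np.array(sorted(np.unique(fm.labels)))
    if len(classes) < 2 and algorithm != "simca":
        raise ValueError(f"{algorithm} needs at least 2 classes")
    n, p = fm.X.shape

    if algorithm == "rf":
        max_features = min(hp["features_per_split"], p)
        if max_features < hp["features_per_split"]:
            log.info("rf: only %d features available, using all per split", p)
        model = RandomForestClassifier(
            n_estimators=hp["n_trees"], max_depth=hp["max_depth"],
            max_features=max_features, random_state=seed,
        )
        model.fit(fm.X, fm.labels)
    elif algorithm == "svm":
        model = LinearSVC(C=hp["C"], random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence noise on tiny folds
            model.fit(fm.X, fm.labels)
    elif algorithm == "nn":
        width = hp["hidden_width"] or _auto_hidden_width(p, len(classes))
        model = MLPClassifier(
            hidden_layer_sizes=(width,), activation="logistic",
            max_iter=hp["max_iter"], random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(fm.X, fm.labels)
    elif algorithm == "maxent":
        # per-sample L2 strength lambda maps to sklearn's C = 1 / (n * lambda)
        model = LogisticRegression(
            C=1.0 / (n * hp["lam"]), max_iter=hp["max_iter"], tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(fm.X, fm.labels)
    else:  # simca
        model = fit_simca(fm.X, fm.labels, n_components=hp["n_components"])

    priors = {c: float(np.mean(fm.labels == c)) for c in classes}
    return TrainedClassifier(algorithm, model, classes, seed, priors, hp)


def _grouped_stratified_folds(
    fm: FeatureMatrix, folds: int, seed: int
) -> list[np.ndarray]:
    """Fold index arrays: stratified by species, plants dealt round-robin."""
    plants_by_species: dict[str, list[str]] = {}
    for sp, plant in zip(fm.labels, fm.plant_ids):
        plants_by_species.setdefault(sp, [])
        if plant not in plants_by_species[sp]:
            plants_by_species[sp].append(plant)
    min_plants = min(len(v) for v in plants_by_species.values())
    if min_plants < folds:
        warnings.warn(
            f"a species has only {min_plants} plants; reducing folds "
            f"{folds} -> {min_plants}",
            stacklevel=2,
        )
        folds = min_plants
    rng = np.random.default_rng(seed)
    fold_of_plant: dict[tuple[str, str], int] = {}
    for sp in sorted(plants_by_species):
        plants = sorted(plants_by_species[sp])
        order = rng.permutation(len(plants))
        for pos, i in enumerate(order):
            fold_of_plant[(sp, plants[i])] = pos % folds
    assignments = np.array(
        [fold_of_plant[(sp, plant)] for sp, plant in zip(fm.labels, fm.plant_ids)]
    )
    return [np.nonzero(assignments == f)[0] for f in range(folds)]


def cross_validate(
    algorithm: str,
    fm: FeatureMatrix,
    grid: list[dict] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, np.ndarray]:
    """Plant-grouped, species-stratified k-fold grid search.

    Returns (best hyperparameters, fold accuracies of the best point); ties
    resolve to the earlier grid entry.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = grid or [DEFAULT_HYPERPARAMS[algorithm]]
    fold_idx = _grouped_stratified_folds(fm, folds, seed)
    best: tuple[float, int, dict, np.ndarray] | None = None
    for g_i, hp in enumerate(grid):
        scores = []
        for f, test_idx in enumerate(fold_idx):
            train_idx = np.concatenate([fold_idx[j] for j in range(len(fold_idx)) if j != f])
            clf = train(algorithm, fm.subset(train_idx), hp, seed=seed)
            pred = clf.predict(fm.X[test_idx])
            scores.append(float(np.mean(pred == fm.labels[test_idx])))
        mean_score = float(np.mean(scores))
        if best is None or mean_score > best[0]:
            best = (mean_score, g_i, hp, np.array(scores))
    assert best is not None
    return best[2], best[3]
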