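"""Evaluation protocol: base-session LDA, projection of later sessions,
threefold cross-validation, centroid distances, PCA, and trend fits.

The classifier is classic multiclass linear discriminant analysis with a
shared within-class covariance: canonical axes solve the generalized
eigenproblem of between-class versus pooled within-class scatter, and
classification uses linear Gaussian discriminant scores with priors
proportional to training counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .data import MeasurementSet
from .errors import DataError, FitError

_RIDGE_REL = 1e-6  # ridge strength relative to mean within-class variance
_SINGULAR_REL = 1e-9  # eigenvalue ratio below which the scatter counts as singular


# ------------------------------------------------------------------- LDA
@dataclass(frozen=True)
class LDAModel:
    """Fitted linear discriminant model.

    ``scaling`` maps sensor space to the canonical discriminant space
    (columns are scatter-orthonormal: ``W.T @ S_W @ W = I``), ordered by
    decreasing between/within eigenvalue.
    """

    classes: tuple[str, ...]
    centroids: np.ndarray  # (k, p)
    priors: np.ndarray  # (k,)
    scaling: np.ndarray  # (p, d)
    eigenvalues: np.ndarray  # (d,)
    pooled_scatter: np.ndarray  # (p, p), possibly ridged
    covariance: np.ndarray  # (p, p) pooled within-class covariance estimate
    grand_mean: np.ndarray  # (p,)
    sensors: tuple[str, ...]
    ridge_used: bool = False
    _coef: np.ndarray = field(default=None, repr=False)
    _const: np.ndarray = field(default=None, repr=False)

    @property
    def n_axes(self) -> int:
        return self.scaling.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project rows of X into canonical discriminant coordinates."""
        return (np.asarray(X, float) - self.grand_mean) @ self.scaling

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores (rows x classes); argmax classifies."""
        return np.asarray(X, float) @ self._coef.T + self._const

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.classes)[np.argmax(self.scores(X), axis=1)]


def _fit_lda_arrays(
    X: np.ndarray, y: np.ndarray, sensors: tuple[str, ...], ridge: bool = True
) -> LDAModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise DataError("LDA needs at least two classes")
    n, p = X.shape
    counts = np.array([(y == c).sum() for c in classes])
    if (counts < 2).any():
        lab = classes[int(np.argmin(counts))]
        raise DataError(f"class {lab!r} has fewer than 2 observations")
    centroids = np.vstack([X[y == c].mean(axis=0) for c in classes])
    priors = counts / n
    grand_mean = X.mean(axis=0)

    s_w = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = X[y == c] - centroids[i]
        s_w += d.T @ d
    s_b = np.zeros((p, p))
    for i in range(len(classes)):
        d = centroids[i] - grand_mean
        s_b += counts[i] * np.outer(d, d)

    s_w_used = s_w
    ridge_used = False
    w_evals = np.linalg.eigvalsh(s_w)
    if w_evals[0] <= _SINGULAR_REL * w_evals[-1]:
        if not ridge:
            raise FitError("pooled within-class scatter is singular (ridge disabled)")
        eps = _RIDGE_REL * (np.trace(s_w) / p if np.trace(s_w) > 0 else 1.0)
        s_w_used = s_w + eps * np.eye(p)
        warnings.warn(
            f"singular pooled scatter; regularized with ridge {eps:.3g}", stacklevel=2
        )
        ridge_used = True
    evals, evecs = scipy.linalg.eigh(s_b, s_w_used)

    order = np.argsort(evals)[::-1]
    d = min(len(classes) - 1, p)
    w = evecs[:, order[:d]]
    evals = evals[order[:d]]
    # deterministic sign: largest-magnitude component of each axis positive
    for j in range(w.shape[1]):
        k = int(np.argmax(np.abs(w[:, j])))
        if w[k, j] < 0:
            w[:, j] = -w[:, j]

    cov = s_w_used / max(n - len(classes), 1)
    cov_inv_mu = np.linalg.solve(cov, centroids.T).T  # (k, p)
    const = -0.5 * np.einsum("ij,ij->i", cov_inv_mu, centroids) + np.log(priors)
    return LDAModel(
        classes=classes,
        centroids=centroids,
        priors=priors,
        scaling=w,
        eigenvalues=evals,
        pooled_scatter=s_w_used,
        covariance=cov,
        grand_mean=grand_mean,
        sensors=tuple(sensors),
        ridge_used=ridge_used,
        _coef=cov_inv_mu,
        _const=const,
    )


def fit_lda(ms: MeasurementSet, session: int | None = None, ridge: bool = True) -> LDAModel:
    """Fit LDA, optionally restricted to one session (the model-building one)."""
    X, y, _ = ms.matrix(session)
    return _fit_lda_arrays(X, y, ms.sensors, ridge=ridge)


@dataclass(frozen=True)
class Prediction:
    index: pd.MultiIndex
    labels: np.ndarray
    coordinates: np.ndarray


def predict(model: LDAModel, ms: MeasurementSet, session: int | None = None) -> Prediction:
    """Classify observations and project them into discriminant space."""
    if tuple(ms.sensors) != tuple(model.sensors):
        raise DataError(f"sensor mismatch: data {ms.sensors} vs model {model.sensors}")
    X, _, index = ms.matrix(session)
    return Prediction(index, model.predict_labels(X), model.transform(X))


# -------------------------------------------------------- cross-validation
@dataclass
class EvaluationReport:
    """Per-(session, class) accuracies, confusion matrices, and centroid
    distances with their spread over cross-validation folds."""

    base_session: int
    n_folds: int
    seed: int
    classes: tuple[str, ...]
    sessions: tuple[int, ...]
    accuracy: dict  # session -> class -> {"mean","spread","per_fold"}
    confusion: dict  # session -> {"labels", "matrix"}
    distances: dict | None = None  # session -> {"mean","spread","per_fold"}
    target_class: str | None = None
    norm_pair: tuple[str, str] | None = None
    fold_assignment: list | None = None  # fold -> list of (session, round, sample_id)

    def accuracy_frame(self) -> pd.DataFrame:
        rows = [
            {
                "session": s,
                "class": c,
                "accuracy_mean": self.accuracy[s][c]["mean"],
                "accuracy_spread": self.accuracy[s][c]["spread"],
            }
            for s in self.sessions
            for c in self.classes
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "base_session": self.base_session,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "classes": list(self.classes),
            "sessions": list(map(int, self.sessions)),
            "target_class": self.target_class,
            "norm_pair": list(self.norm_pair) if self.norm_pair else None,
            "accuracy": {
                str(s): {c: v for c, v in self.accuracy[s].items()} for s in self.sessions
            },
            "confusion": {
                str(s): {
                    "labels": list(self.confusion[s]["labels"]),
                    "matrix": [list(map(float, row)) for row in self.confusion[s]["matrix"]],
                }
                for s in self.sessions
            },
            "distances": None
            if self.distances is None
            else {str(s): v for s, v in self.distances.items()},
            "fold_assignment": self.fold_assignment,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def make_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified folds: seeded shuffle within each class,
    then round-robin assignment. Returns per-fold position arrays."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for label in sorted(set(map(str, y))):
        pos = np.nonzero(np.asarray(y) == label)[0]
        if len(pos) < n_folds:
            raise DataError(
                f"class {label!r} has {len(pos)} observations; "
                f"{n_folds}-fold CV needs at least {n_folds}"
            )
        pos = rng.permutation(pos)
        for j, idx in enumerate(pos):
            folds[j % n_folds].append(int(idx))
    return [np.array(sorted(f)) for f in folds]


def threefold_cv(
    ms: MeasurementSet,
    base_session: int = 0,
    n_folds: int = 3,
    seed: int = 0,
    target_class: str | None = None,
    norm_pair: tuple[str, str] | None = None,
    ridge: bool = True,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a base-session LDA.

    Per fold the model is trained on the remaining (k-1)/k of the base
    session, validated on the held-out part, and used to project every later
    session in full.  Accuracies are reported per (session, class) as the
    mean over folds with the fold spread (population standard deviation).
    When *target_class* and *norm_pair* are given, relative centroid
    distances are computed per fold in each fold model's discriminant space.
    """
    if base_session not in ms.sessions:
        raise DataError(f"base session {base_session} not present")
    X0, y0, index0 = ms.matrix(base_session)
    classes = tuple(sorted(set(map(str, y0))))
    sessions = ms.sessions
    later = [s for s in sessions if s != base_session]
    folds = make_folds(y0, n_folds, seed)

    acc_folds: dict[int, dict[str, list[float]]] = {
        s: {c: [] for c in classes} for s in sessions
    }
    conf_folds: dict[int, list[np.ndarray]] = {s: [] for s in sessions}
    dist_folds: dict[int, list[float]] = {s: [] for s in sessions}

    for f, held in enumerate(folds):
        train_mask = np.ones(len(y0), dtype=bool)
        train_mask[held] = False
        model = _fit_lda_arrays(X0[train_mask], y0[train_mask], ms.sensors, ridge=ridge)

        def _score(X: np.ndarray, y: np.ndarray, session: int) -> None:
            pred = model.predict_labels(X)
            conf = np.zeros((len(classes), len(classes)))
            for i, ci in enumerate(classes):
                sel = y == ci
                if sel.any():
                    acc_folds[session][ci].append(100.0 * float(np.mean(pred[sel] == ci)))
                for j, cj in enumerate(classes):
                    conf[i, j] = float(np.sum(pred[sel] == cj))
            conf_folds[session].append(conf)

        _score(X0[held], y0[held], base_session)
        for s in later:
            Xs, ys, _ = ms.matrix(s)
            _score(Xs, ys, s)

        if target_class is not None and norm_pair is not None:
            d = _relative_distance_arrays(model, ms, target_class, norm_pair, base_session)
            for s, v in d.items():
                dist_folds[s].append(v)

    accuracy = {
        s: {
            c: {
                "mean": float(np.mean(acc_folds[s][c])),
                "spread": float(np.std(acc_folds[s][c])),
                "per_fold": [float(v) for v in acc_folds[s][c]],
            }
            for c in classes
        }
        for s in sessions
    }
    confusion = {}
    for s in sessions:
        stack = np.stack(conf_folds[s])
        # base session folds partition the data: sum; later sessions are
        # evaluated in full by each fold: average
        mat = stack.sum(axis=0) if s == base_session else stack.mean(axis=0)
        confusion[s] = {"labels": classes, "matrix": mat}
    distances = None
    if target_class is not None and norm_pair is not None:
        distances = {
            s: {
                "mean": float(np.mean(dist_folds[s])),
                "spread": float(np.std(dist_folds[s])),
                "per_fold": [float(v) for v in dist_folds[s]],
            }
            for s in sessions
        }
    fold_assignment = [[list(map(_py, index0[i])) for i in f] for f in folds]
    return EvaluationReport(
        base_session=base_session,
        n_folds=n_folds,
        seed=seed,
        classes=classes,
        sessions=sessions,
        accuracy=accuracy,
        confusion=confusion,
        distances=distances,
        target_class=target_class,
        norm_pair=tuple(norm_pair) if norm_pair else None,
        fold_assignment=fold_assignment,
    )


def _py(v):
    return v.item() if hasattr(v, "item") else v


# ------------------------------------------------------------- distances
def _relative_distance_arrays(model, ms, target_class, norm_pair, base_session):
    coords = {}
    labels = {}
    for s in ms.sessions:
        X, y, _ = ms.matrix(s)
        coords[s] = model.transform(X)
        labels[s] = y

    def centroid(session, label):
        sel = labels[session] == label
        if not sel.any():
            raise DataError(f"class {label!r} absent from session {session}")
        return coords[session][sel].mean(axis=0)

    a, b = norm_pair
    norm = float(np.linalg.norm(centroid(base_session, a) - centroid(base_session, b)))
    if norm == 0.0:
        raise DataError(f"zero distance between norm-pair centroids {norm_pair}")
    base_c = centroid(base_session, target_class)
    return {
        s: float(np.linalg.norm(centroid(s, target_class) - base_c)) / norm
        for s in ms.sessions
    }


def relative_centroid_distance(
    model: LDAModel,
    ms: MeasurementSet,
    target_class: str,
    norm_pair: tuple[str, str],
    base_session: int = 0,
) -> dict[int, float]:
    """Distance of the target class centroid from its base-session position,
    in discriminant space, normalized by the base-session distance between
    the two norm-pair class centroids.  Returns ``{session: distance}``."""
    if tuple(ms.sensors) != tuple(model.sensors):
        raise DataError("sensor mismatch between model and data")
    return _relative_distance_arrays(model, ms, target_class, norm_pair, base_session)


def centroid_distances_sensor_space(
    ms: MeasurementSet, groups, reference
) -> dict:
    """Euclidean distance of each group centroid from the reference group
    centroid, in full sensor space.

    *groups* is either the name of a grouping factor (``"class"`` or a
    covariate column such as ``"temperature"``) or a sequence of group labels
    aligned with the observation rows.
    """
    X = ms.values.to_numpy(dtype=float)
    if isinstance(groups, str):
        if groups == "class":
            g = ms.row_classes()
        else:
            if ms.covariates is None or groups not in ms.covariates.columns:
                raise DataError(f"no covariate column {groups!r}")
            g = ms.covariates[groups].to_numpy()
    else:
        g = np.asarray(list(groups))
        if len(g) != len(X):
            raise DataError("group labels must align with observations")
    if not (g == reference).any():
        raise DataError(f"reference group {reference!r} is empty")
    ref_c = X[g == reference].mean(axis=0)
    out = {}
    for label in pd.unique(g):
        out[_py(label)] = float(np.linalg.norm(X[g == label].mean(axis=0) - ref_c))
    return out


# ----------------------------------------------------------------- trends
@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float


def fit_trend(x, y) -> TrendFit:
    """Univariate ordinary least squares with R^2.

    A constant response yields slope 0 and (by convention, with a warning)
    R^2 = 0; a constant predictor is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise DataError("need at least 3 points for a trend fit")
    vx = x - x.mean()
    sxx = float(vx @ vx)
    if sxx == 0.0:
        raise DataError("constant predictor: trend slope is undefined")
    slope = float(vx @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant response; R^2 reported as 0", stacklevel=2)
        return TrendFit(slope, intercept, 0.0)
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    return TrendFit(slope, intercept, 1.0 - ss_res / ss_tot)


# -------------------------------------------------------------------- PCA
@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (n_components, p), rows unit-norm
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_scores(data, n_components: int | None = None) -> PCAResult:
    """Column-centered PCA via SVD.

    *data* is a MeasurementSet or a 2-D array.  Loadings are unit-norm with
    a deterministic sign (largest-magnitude element positive); explained
    variances are non-increasing.
    """
    X = data.values.to_numpy(dtype=float) if isinstance(data, MeasurementSet) else np.asarray(
        data, dtype=float
    )
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("PCA needs a 2-D array with at least 2 observations")
    mean = X.mean(axis=0)
    u, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    d = min(n_components or len(s), len(s))
    for j in range(d):
        k = int(np.argmax(np.abs(vt[j])))
        if vt[j, k] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    return PCAResult(
        scores=(u[:, :d] * s[:d]),
        loadings=vt[:d],
        explained_variance=var[:d],
        explained_variance_ratio=ratio[:d],
        mean=mean,
    )
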