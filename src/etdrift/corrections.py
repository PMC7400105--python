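"""Drift-correction methods for multi-session sensor-array data.

Four families are implemented, each as a fit/apply pair:

* additive correction relative to **all** samples of a round,
* additive correction relative to designated **reference** classes,
* multi-sensor **linear** (affine) correction between sessions, fitted on
  reference-class centroids, and
* **component correction**: removal of the dominant drift direction found by
  PCA on a pooled reference class, including the modified variant that
  subtracts the drift component twice from later sessions only, mapping them
  onto the base session.

All fitters consume a :class:`~etdrift.data.MeasurementSet` and return a
small serializable model object; ``apply_*`` produces a new corrected set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .data import MeasurementSet
from .errors import DataError, FitError

METHODS = ("none", "additive_all", "additive_ref", "linear_ref", "cc", "cc_modified")


# ---------------------------------------------------------------- additive
@dataclass(frozen=True)
class AdditiveOffsets:
    """Per-(session, round, sensor) offsets subtracted from the raw signal."""

    offsets: dict[tuple[int, int], np.ndarray]
    basis: str  # "all_samples" | "reference_classes"
    reference_classes: tuple[str, ...]
    sensors: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "kind": "AdditiveOffsets",
            "basis": self.basis,
            "reference_classes": list(self.reference_classes),
            "sensors": list(self.sensors),
            "offsets": {f"{s}:{r}": list(map(float, v)) for (s, r), v in self.offsets.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "AdditiveOffsets":
        offsets = {}
        for key, v in d["offsets"].items():
            s, r = key.split(":")
            offsets[(int(s), int(r))] = np.asarray(v, dtype=float)
        return AdditiveOffsets(
            offsets, d["basis"], tuple(d["reference_classes"]), tuple(d["sensors"])
        )


def fit_additive_all(ms: MeasurementSet) -> AdditiveOffsets:
    """Offset of each round = mean signal over *all* samples of that round.

    Requires complete blocks: the same sample set must be present in every
    round, otherwise the block mean is not comparable across rounds.
    """
    all_classes = set(ms.class_labels())
    offsets: dict[tuple[int, int], np.ndarray] = {}
    for (session, rnd), block in ms.iter_blocks():
        present = set(ms.classes[block.index.get_level_values("sample_id")])
        if present != all_classes:
            raise DataError(
                f"block (session={session}, round={rnd}) is incomplete: "
                f"missing classes {sorted(all_classes - present)}"
            )
        offsets[(session, rnd)] = block.to_numpy(dtype=float).mean(axis=0)
    return AdditiveOffsets(offsets, "all_samples", (), ms.sensors)


def fit_additive_reference(ms: MeasurementSet, reference_classes) -> AdditiveOffsets:
    """Offset of each round = mean signal over the reference classes only."""
    refs = tuple(reference_classes)
    if not refs:
        raise DataError("at least one reference class is required")
    unknown = set(refs) - set(ms.class_labels())
    if unknown:
        raise DataError(f"unknown reference class(es): {sorted(unknown)}")
    offsets: dict[tuple[int, int], np.ndarray] = {}
    for (session, rnd), block in ms.iter_blocks():
        cls = ms.classes[block.index.get_level_values("sample_id")].to_numpy()
        missing = set(refs) - set(cls)
        if missing:
            raise DataError(
                f"block (session={session}, round={rnd}) lacks reference class(es) "
                f"{sorted(missing)}"
            )
        sel = np.isin(cls, refs)
        offsets[(session, rnd)] = block.to_numpy(dtype=float)[sel].mean(axis=0)
    return AdditiveOffsets(offsets, "reference_classes", refs, ms.sensors)


def apply_additive(ms: MeasurementSet, model: AdditiveOffsets) -> MeasurementSet:
    """Subtract the fitted per-round offsets, zero-centering each block."""
    _check_sensors(ms, model.sensors)
    out = ms.values.copy()
    for (session, rnd), block in ms.iter_blocks():
        key = (int(session), int(rnd))
        if key not in model.offsets:
            raise DataError(f"no offsets fitted for block (session={session}, round={rnd})")
        out.loc[block.index] = block.to_numpy(dtype=float) - model.offsets[key]
    return ms.with_values(out)


# ------------------------------------------------------------------ linear
@dataclass(frozen=True)
class AffineSensorMap:
    """Per-(session, sensor) affine map ``x -> m*x + b`` onto the base session."""

    slope: dict[int, np.ndarray]
    intercept: dict[int, np.ndarray]
    reference_classes: tuple[str, ...]
    base_session: int
    sensors: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "kind": "AffineSensorMap",
            "base_session": self.base_session,
            "reference_classes": list(self.reference_classes),
            "sensors": list(self.sensors),
            "slope": {str(s): list(map(float, v)) for s, v in self.slope.items()},
            "intercept": {str(s): list(map(float, v)) for s, v in self.intercept.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "AffineSensorMap":
        return AffineSensorMap(
            {int(k): np.asarray(v, float) for k, v in d["slope"].items()},
            {int(k): np.asarray(v, float) for k, v in d["intercept"].items()},
            tuple(d["reference_classes"]),
            int(d["base_session"]),
            tuple(d["sensors"]),
        )


def _class_centroids(ms: MeasurementSet, session: int, classes) -> np.ndarray:
    """Stack per-class centroids (len(classes) x n_sensors) for one session."""
    X, y, _ = ms.matrix(session)
    rows = []
    for label in classes:
        sel = y == label
        if not sel.any():
            raise DataError(f"class {label!r} absent from session {session}")
        rows.append(X[sel].mean(axis=0))
    return np.vstack(rows)


def fit_linear_map(ms: MeasurementSet, reference_classes, base_session: int = 0) -> AffineSensorMap:
    """Per-sensor least squares mapping each session's reference centroids
    onto the base session's.

    For sensor *s* and session *w*, the points are one (x, y) pair per
    reference class with ``x`` the session-*w* centroid and ``y`` the
    base-session centroid; OLS yields slope ``m`` and intercept ``b`` such
    that ``y ~ m*x + b``.  At least two reference classes are required.
    """
    refs = tuple(reference_classes)
    if len(refs) < 2:
        raise DataError("at least two reference classes are required for the linear correction")
    if base_session not in ms.sessions:
        raise DataError(f"base session {base_session} not present")
    y_cent = _class_centroids(ms, base_session, refs)  # (k, p)
    slope: dict[int, np.ndarray] = {}
    intercept: dict[int, np.ndarray] = {}
    p = len(ms.sensors)
    for session in ms.sessions:
        if session == base_session:
            slope[session] = np.ones(p)
            intercept[session] = np.zeros(p)
            continue
        x_cent = _class_centroids(ms, session, refs)
        m = np.empty(p)
        b = np.empty(p)
        for j, sensor in enumerate(ms.sensors):
            x = x_cent[:, j]
            y = y_cent[:, j]
            vx = x - x.mean()
            sxx = float(vx @ vx)
            if sxx == 0.0:
                raise FitError(
                    f"sensor {sensor!r}: reference centroids have zero spread in "
                    f"session {session}; slope is undefined"
                )
            m[j] = float(vx @ (y - y.mean())) / sxx
            b[j] = y.mean() - m[j] * x.mean()
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(b))):
            raise FitError(f"non-finite affine parameters in session {session}")
        slope[session] = m
        intercept[session] = b
    return AffineSensorMap(slope, intercept, refs, base_session, ms.sensors)


def apply_linear_map(ms: MeasurementSet, model: AffineSensorMap) -> MeasurementSet:
    """Transform every cell of session *w* by its fitted ``(m, b)``."""
    _check_sensors(ms, model.sensors)
    missing = [s for s in ms.sessions if s not in model.slope]
    if missing:
        raise DataError(f"no affine map fitted for session(s) {missing}")
    out = ms.values.copy()
    sess = out.index.get_level_values("session")
    for session in ms.sessions:
        sel = sess == session
        out.loc[sel] = out.loc[sel].to_numpy(dtype=float) * model.slope[session] + model.intercept[
            session
        ]
    return ms.with_values(out)


# --------------------------------------------------------------- component
@dataclass(frozen=True)
class DriftComponent:
    """One drift direction estimated from a reference class across two sessions."""

    center: np.ndarray
    loading: np.ndarray
    multiplier: int  # 1 = classic removal, 2 = reflect later session onto base
    reference_class: str
    base_session: int
    later_session: int
    pairing: str  # "first_last" | "each_week_to_week0"
    sensors: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        p = np.asarray(self.loading, dtype=float)
        if not np.isclose(np.linalg.norm(p), 1.0):
            raise FitError("drift loading must be a unit vector")
        if self.multiplier not in (1, 2):
            raise FitError("multiplier must be 1 or 2")

    def to_dict(self) -> dict:
        return {
            "kind": "DriftComponent",
            "center": list(map(float, self.center)),
            "loading": list(map(float, self.loading)),
            "multiplier": self.multiplier,
            "reference_class": self.reference_class,
            "base_session": self.base_session,
            "later_session": self.later_session,
            "pairing": self.pairing,
            "sensors": list(self.sensors),
        }

    @staticmethod
    def from_dict(d: dict) -> "DriftComponent":
        return DriftComponent(
            np.asarray(d["center"], float),
            np.asarray(d["loading"], float),
            int(d["multiplier"]),
            d["reference_class"],
            int(d["base_session"]),
            int(d["later_session"]),
            d["pairing"],
            tuple(d["sensors"]),
        )


def fit_drift_component(
    ms: MeasurementSet,
    reference_class: str,
    pairing: str = "first_last",
    base_session: int = 0,
    multiplier: int = 1,
) -> list[DriftComponent]:
    """Estimate drift direction(s) from the reference class by PCA.

    For every session pair ``(base, w)`` dictated by *pairing*, the
    reference-class observations of both sessions are pooled, centered at
    their mean, and the first principal-component loading of the pool is
    taken as the drift direction.  The loading sign is fixed so that the
    base-to-later centroid displacement projects non-negatively onto it
    (cosmetic: corrections are sign-invariant).
    """
    if pairing not in ("first_last", "each_week_to_week0"):
        raise DataError(f"unknown pairing {pairing!r}")
    sessions = ms.sessions
    if base_session not in sessions:
        raise DataError(f"base session {base_session} not present")
    later = [s for s in sessions if s != base_session]
    if not later:
        raise DataError("component correction needs at least two sessions")
    pairs = [(base_session, max(later))] if pairing == "first_last" else [
        (base_session, w) for w in later
    ]
    components: list[DriftComponent] = []
    for base, w in pairs:
        ref_rows = []
        means = {}
        for session in (base, w):
            X, y, _ = ms.matrix(session)
            sel = y == reference_class
            if not sel.any():
                raise DataError(f"reference class {reference_class!r} absent from session {session}")
            ref_rows.append(X[sel])
            means[session] = X[sel].mean(axis=0)
        pool = np.vstack(ref_rows)
        center = pool.mean(axis=0)
        centered = pool - center
        if np.allclose(centered, 0):
            raise FitError(
                f"reference pool for sessions ({base}, {w}) has zero variance; "
                "no drift direction can be estimated"
            )
        # first right-singular vector = first PCA loading
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        loading = vt[0]
        if (means[w] - means[base]) @ loading < 0:
            loading = -loading
        components.append(
            DriftComponent(center, loading, multiplier, reference_class, base, w, pairing, ms.sensors)
        )
    return components


def apply_component_correction(
    ms: MeasurementSet, model: DriftComponent, sessions=None
) -> MeasurementSet:
    """Project out the drift component from the targeted sessions.

    Each targeted observation ``x`` becomes
    ``x - multiplier * ((x - c) . p) * p``.  With ``multiplier=1`` the
    variance along ``p`` is removed (classic component correction); with
    ``multiplier=2`` the data are reflected through the hyperplane, mapping a
    purely translated later cluster back onto the base cluster while the base
    session is left untouched.

    *sessions* overrides the targeted set; by default the classic variant is
    applied to every session of *ms* (the correction is defined for the whole
    data matrix) and the doubled variant only to the component's later
    session.
    """
    _check_sensors(ms, model.sensors)
    if sessions is None:
        sessions = list(ms.sessions) if model.multiplier == 1 else [model.later_session]
    sessions = [s for s in sessions if s in ms.sessions]
    out = ms.values.copy()
    sess = out.index.get_level_values("session")
    p = model.loading
    c = model.center
    for session in sessions:
        sel = sess == session
        X = out.loc[sel].to_numpy(dtype=float)
        t = (X - c) @ p
        out.loc[sel] = X - model.multiplier * np.outer(t, p)
    return ms.with_values(out)


# ---------------------------------------------------------------- dispatch
def correct(ms: MeasurementSet, method: str, **options):
    """Fit and apply one correction method by name.

    Returns ``(corrected MeasurementSet, fitted model)``; the model is
    ``None`` for method ``"none"``, an :class:`AdditiveOffsets`, an
    :class:`AffineSensorMap`, or a list of :class:`DriftComponent`.

    Options: ``reference_classes`` (additive_ref, linear_ref),
    ``reference_class`` (cc, cc_modified), ``base_session`` (default 0),
    ``pairing`` (cc; default ``"first_last"``).
    """
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}; choose from {METHODS}")
    base = int(options.get("base_session", 0))
    if method == "none":
        return ms, None
    if method == "additive_all":
        model = fit_additive_all(ms)
        return apply_additive(ms, model), model
    if method == "additive_ref":
        refs = _require(options, "reference_classes", method)
        model = fit_additive_reference(ms, refs)
        return apply_additive(ms, model), model
    if method == "linear_ref":
        refs = _require(options, "reference_classes", method)
        model = fit_linear_map(ms, refs, base_session=base)
        return apply_linear_map(ms, model), model
    if method == "cc":
        ref = _require(options, "reference_class", method)
        pairing = options.get("pairing", "first_last")
        components = fit_drift_component(ms, ref, pairing=pairing, base_session=base, multiplier=1)
        out = ms
        for comp in components:
            target = None if pairing == "first_last" else [comp.base_session, comp.later_session]
            out = apply_component_correction(out, comp, sessions=target)
        return out, components
    # cc_modified
    ref = _require(options, "reference_class", method)
    pairing = options.get("pairing", "each_week_to_week0")
    components = fit_drift_component(ms, ref, pairing=pairing, base_session=base, multiplier=2)
    out = ms
    for comp in components:
        out = apply_component_correction(out, comp, sessions=[comp.later_session])
    return out, components


def _require(options: dict, key: str, method: str):
    value = options.get(key)
    if not value:
        raise DataError(f"method {method!r} requires option {key!r}")
    return value


def _check_sensors(ms: MeasurementSet, sensors) -> None:
    if tuple(sensors) and tuple(ms.sensors) != tuple(sensors):
        raise DataError(f"sensor mismatch: data {ms.sensors} vs model {tuple(sensors)}")


# ----------------------------------------------------------- serialization
def model_to_dict(model, method: str) -> dict:
    """Serialize any fitted correction model (or None) to a JSON-able dict."""
    if model is None:
        payload = None
    elif isinstance(model, list):
        payload = {"kind": "DriftComponentList", "components": [c.to_dict() for c in model]}
    else:
        payload = model.to_dict()
    return {"method": method, "version": __version__, "model": payload}


def model_from_dict(doc: dict):
    """Inverse of :func:`model_to_dict`; returns ``(model, method)``."""
    payload = doc["model"]
    if payload is None:
        return None, doc["method"]
    kind = payload["kind"]
    if kind == "AdditiveOffsets":
        return AdditiveOffsets.from_dict(payload), doc["method"]
    if kind == "AffineSensorMap":
        return AffineSensorMap.from_dict(payload), doc["method"]
    if kind == "DriftComponentList":
        return [DriftComponent.from_dict(c) for c in payload["components"]], doc["method"]
    raise DataError(f"unknown model kind {kind!r}")


def save_model(model, method: str, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model, method), fh, indent=2)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
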