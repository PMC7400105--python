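"""Measurement data model, CSV I/O, and pretreatment rules.

The canonical on-disk representation is a long-format CSV with the columns
``session,round,sample_id,class,sensor,value`` and optional trailing
``temperature`` and ``seq_pos`` covariate columns.  In memory a
:class:`MeasurementSet` stores the same information as a wide table
(observations x sensors) which is the natural shape for the correction and
evaluation mathematics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Default channel names of the seven-sensor potentiometric array.
DEFAULT_SENSORS: tuple[str, ...] = ("ZZ", "BA", "BB", "CA", "GA", "HA", "JB")

#: Mandatory columns of the long CSV layout, in canonical order.
LONG_COLUMNS: tuple[str, ...] = ("session", "round", "sample_id", "class", "sensor", "value")

#: Optional per-observation covariate columns.
COVARIATE_COLUMNS: tuple[str, ...] = ("temperature", "seq_pos")

_INDEX_NAMES = ("session", "round", "sample_id")

# consistency scale for the median absolute deviation (normal distribution)
_MAD_CONSISTENCY = 0.6745


@dataclass(frozen=True)
class MeasurementSet:
    """A validated tensor of sensor readings indexed by (session, round, sample).

    Parameters
    ----------
    values:
        Wide table with a ``(session, round, sample_id)`` MultiIndex and one
        float column per sensor, in sensor order.
    classes:
        Mapping ``sample_id -> class label`` covering every sample in *values*.
    covariates:
        Optional table aligned with *values* holding ``temperature`` and/or
        ``seq_pos`` columns.
    """

    values: pd.DataFrame
    classes: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        values = self.values
        if not isinstance(values.index, pd.MultiIndex) or values.index.names != list(_INDEX_NAMES):
            raise DataError(
                f"values must be indexed by {_INDEX_NAMES}, got {values.index.names}"
            )
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise DataError(f"duplicate observation {dup!r}")
        if values.isna().any().any():
            bad = values[values.isna().any(axis=1)].index[0]
            raise DataError(f"NaN sensor value at {bad!r}; clean the data or drop the row")
        missing = set(values.index.get_level_values("sample_id")) - set(self.classes.index)
        if missing:
            raise DataError(f"sample ids without a class label: {sorted(missing)}")
        if self.covariates is not None and not self.covariates.index.equals(values.index):
            raise DataError("covariates index must match values index")

    # ------------------------------------------------------------------ views
    @property
    def sensors(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def sessions(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.values.index.get_level_values("session"))))

    @property
    def n_obs(self) -> int:
        return len(self.values)

    def rounds(self, session: int) -> tuple[int, ...]:
        idx = self.values.loc[session].index.get_level_values("round")
        return tuple(sorted(set(idx)))

    def class_labels(self) -> tuple[str, ...]:
        """All class labels present, sorted."""
        return tuple(sorted(set(self.classes[self.values.index.get_level_values("sample_id")])))

    def row_classes(self) -> np.ndarray:
        """Class label of every observation row, aligned with :meth:`matrix`."""
        return self.classes[self.values.index.get_level_values("sample_id")].to_numpy()

    def matrix(self, session: int | None = None) -> tuple[np.ndarray, np.ndarray, pd.MultiIndex]:
        """Return ``(X, y, index)``: readings, class labels, and row index."""
        df = self.values if session is None else self.values.loc[[session]]
        labels = self.classes[df.index.get_level_values("sample_id")].to_numpy()
        return df.to_numpy(dtype=float), labels, df.index

    def iter_blocks(self):
        """Yield ``((session, round), wide sub-frame)`` for every block."""
        for key, block in self.values.groupby(level=["session", "round"], sort=True):
            yield key, block

    # -------------------------------------------------------------- builders
    def with_values(self, new_values: pd.DataFrame) -> "MeasurementSet":
        """Replace the numeric table, keeping labels and covariates."""
        if not new_values.index.equals(self.values.index):
            raise DataError("replacement values must keep the same observation index")
        return MeasurementSet(new_values[list(self.sensors)], self.classes, self.covariates)

    def subset_sessions(self, sessions) -> "MeasurementSet":
        sessions = list(sessions)
        mask = self.values.index.get_level_values("session").isin(sessions)
        cov = self.covariates[mask] if self.covariates is not None else None
        return MeasurementSet(self.values[mask], self.classes, cov)

    def to_long(self) -> pd.DataFrame:
        """Canonical long-format frame (sorted, fixed column order)."""
        long = (
            self.values.stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_3": "sensor"})
        )
        long["class"] = self.classes[long["sample_id"]].to_numpy()
        cols = list(LONG_COLUMNS)
        if self.covariates is not None:
            cov = self.covariates.reset_index()
            long = long.merge(cov, on=list(_INDEX_NAMES), how="left")
            cols += [c for c in COVARIATE_COLUMNS if c in self.covariates.columns]
        # preserve sensor order from the wide table, then sort by index
        order = {s: i for i, s in enumerate(self.sensors)}
        long["_s"] = long["sensor"].map(order)
        long = long.sort_values(["session", "round", "sample_id", "_s"], kind="stable")
        return long[cols].reset_index(drop=True)

    @staticmethod
    def from_long(frame: pd.DataFrame, sensors: tuple[str, ...] | None = None) -> "MeasurementSet":
        """Build from a long-format frame (validated)."""
        frame = frame.copy()
        missing = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"missing required columns: {missing}")
        extra = [c for c in frame.columns if c not in LONG_COLUMNS + COVARIATE_COLUMNS]
        if extra:
            raise DataError(f"unknown columns: {extra}")
        key_cols = ["session", "round", "sample_id", "sensor"]
        dup = frame.duplicated(subset=key_cols)
        if dup.any():
            row = frame.loc[dup.idxmax(), key_cols]
            raise DataError(f"duplicate cell for {tuple(row)}")
        if sensors is None:
            seen = frame["sensor"].astype(str)
            sensors = tuple(dict.fromkeys(seen))
        else:
            unknown = set(frame["sensor"].astype(str)) - set(sensors)
            if unknown:
                raise DataError(f"unknown sensor(s): {sorted(unknown)}")
        # one class per sample_id
        cls = frame.groupby("sample_id")["class"].agg(set)
        conflict = cls[cls.map(len) > 1]
        if not conflict.empty:
            raise DataError(f"conflicting class labels for sample(s): {list(conflict.index)}")
        classes = cls.map(lambda s: next(iter(s))).astype(str)

        wide = frame.pivot_table(
            index=list(_INDEX_NAMES), columns="sensor", values="value", aggfunc="first"
        )
        missing_sensors = [s for s in sensors if s not in wide.columns]
        if missing_sensors:
            raise DataError(f"sensor(s) absent from data: {missing_sensors}")
        wide = wide[list(sensors)].astype(float)
        if wide.isna().any().any():
            bad = wide[wide.isna().any(axis=1)].index[0]
            raise DataError(f"incomplete sensor block at {bad!r}: sensor list must be identical in all blocks")
        wide.columns.name = None

        cov = None
        present = [c for c in COVARIATE_COLUMNS if c in frame.columns]
        if present:
            cov = frame.groupby(list(_INDEX_NAMES), sort=True)[present].first()
            cov = cov.reindex(wide.index)
        return MeasurementSet(wide.sort_index(), classes, cov)


# ----------------------------------------------------------------------- I/O
def read_measurements(
    path,
    layout: str = "long",
    sensors: tuple[str, ...] | None = None,
    on_missing: str = "error",
) -> MeasurementSet:
    """Read a measurement CSV in ``long`` or ``wide`` layout.

    ``on_missing`` controls NaN values: ``"error"`` (default) raises,
    ``"drop"`` removes the affected rows with a warning.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "class": str}, float_precision="round_trip")
    if layout == "long":
        if "sensor" in df.columns:
            df["sensor"] = df["sensor"].astype(str)
        if "value" in df.columns and df["value"].isna().any():
            if on_missing == "drop":
                n = int(df["value"].isna().sum())
                warnings.warn(f"dropping {n} rows with missing values", stacklevel=2)
                df = df[df["value"].notna()]
            else:
                raise DataError("missing values in CSV (use on_missing='drop' to discard)")
        return MeasurementSet.from_long(df, sensors=sensors)
    if layout == "wide":
        meta = [c for c in ("session", "round", "sample_id", "class") if c in df.columns]
        if len(meta) != 4:
            raise DataError("wide layout requires columns session, round, sample_id, class")
        sensor_cols = [c for c in df.columns if c not in meta + list(COVARIATE_COLUMNS)]
        if sensors is not None:
            unknown = [c for c in sensor_cols if c not in sensors]
            if unknown:
                raise DataError(f"unknown sensor column(s): {unknown}")
        keep = [c for c in COVARIATE_COLUMNS if c in df.columns]
        long = df.melt(
            id_vars=meta + keep, value_vars=sensor_cols, var_name="sensor", value_name="value"
        )
        if long["value"].isna().any():
            if on_missing == "drop":
                n = int(long["value"].isna().sum())
                warnings.warn(f"dropping {n} cells with missing values", stacklevel=2)
                long = long[long["value"].notna()]
            else:
                raise DataError("missing values in CSV (use on_missing='drop' to discard)")
        return MeasurementSet.from_long(long, sensors=sensors)
    raise DataError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


def write_measurements(ms: MeasurementSet, path, layout: str = "long") -> None:
    """Write a measurement CSV; round-trips losslessly with :func:`read_measurements`."""
    if layout == "long":
        ms.to_long().to_csv(path, index=False)
    elif layout == "wide":
        wide = ms.values.copy()
        wide.insert(0, "class", ms.row_classes())
        out = wide.reset_index()
        if ms.covariates is not None:
            out = out.merge(ms.covariates.reset_index(), on=list(_INDEX_NAMES), how="left")
        out.to_csv(path, index=False)
    else:
        raise DataError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


# ------------------------------------------------------------- signal traces
@dataclass(frozen=True)
class SignalTrace:
    """Raw potential-vs-time trace of one sensor dipped in one sample."""

    sample_id: str
    sensor: str
    times: np.ndarray = field(repr=False)
    potentials: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.potentials, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise DataError("times and potentials must be 1-D arrays of equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise DataError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "potentials", v)


def collapse_trace(trace: SignalTrace, window_s: float = 10.0) -> float:
    """Average the trace over its final *window_s* seconds.

    The acquisition window is the half-open interval
    ``(t_max - window_s, t_max]``.
    """
    t = trace.times
    if len(t) == 0 or t[-1] - t[0] < window_s:
        raise DataError(
            f"trace covers {0.0 if len(t) == 0 else t[-1] - t[0]:.3g} s, "
            f"shorter than the {window_s:.3g} s averaging window"
        )
    mask = t > t[-1] - window_s
    return float(np.mean(trace.potentials[mask]))


# -------------------------------------------------------------- pretreatment
def drop_initial_rounds(ms: MeasurementSet, k: int = 3) -> MeasurementSet:
    """Remove the first *k* rounds of every session and re-base round indices.

    The initial passes of a session are typically discarded as conditioning
    artefacts before any statistics are computed.
    """
    if k < 0:
        raise DataError("k must be non-negative")
    if k == 0:
        return ms
    keep_masks = []
    index = ms.values.index
    sess_lv = index.get_level_values("session")
    round_lv = index.get_level_values("round")
    remap: dict[tuple[int, int], int] = {}
    for session in ms.sessions:
        rounds = ms.rounds(session)
        if len(rounds) <= k:
            raise DataError(
                f"session {session} has {len(rounds)} rounds, cannot drop the first {k}"
            )
        for new_r, old_r in enumerate(rounds[k:]):
            remap[(session, old_r)] = new_r
    mask = np.array([(s, r) in remap for s, r in zip(sess_lv, round_lv)])
    values = ms.values[mask]
    new_rounds = [remap[(s, r)] for s, r in zip(sess_lv[mask], round_lv[mask])]
    new_index = pd.MultiIndex.from_arrays(
        [sess_lv[mask], new_rounds, index.get_level_values("sample_id")[mask]],
        names=_INDEX_NAMES,
    )
    values = values.set_axis(new_index)
    cov = None
    if ms.covariates is not None:
        cov = ms.covariates[mask].set_axis(new_index)
    return MeasurementSet(values, ms.classes, cov)


def flag_outliers(ms: MeasurementSet, z_thresh: float = 3.5) -> list[tuple[int, int, str]]:
    """Flag observations far from their class centroid (advisory only).

    For each (session, class) group the Euclidean distance of every
    observation to the group centroid is converted to a robust z-score
    (median / MAD with the normal-consistency factor); scores above
    *z_thresh* are flagged.  Groups with zero MAD are skipped with a warning.
    Nothing is removed; call sites decide what to do with the flags.
    """
    flags: list[tuple[int, int, str]] = []
    X = ms.values.to_numpy(dtype=float)
    idx = ms.values.index
    sess = idx.get_level_values("session").to_numpy()
    rnd = idx.get_level_values("round").to_numpy()
    sid = idx.get_level_values("sample_id").to_numpy()
    cls = ms.row_classes()
    for session in ms.sessions:
        for label in sorted(set(cls[sess == session])):
            sel = (sess == session) & (cls == label)
            if sel.sum() < 5:
                raise DataError(
                    f"class {label!r} has {int(sel.sum())} observations in session "
                    f"{session}; need at least 5 for outlier screening"
                )
            pts = X[sel]
            d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
            med = np.median(d)
            mad = np.median(np.abs(d - med))
            if mad == 0:
                warnings.warn(
                    f"degenerate spread for class {label!r} in session {session}; "
                    "no outliers flagged",
                    stacklevel=2,
                )
                continue
            z = _MAD_CONSISTENCY * (d - med) / mad
            for pos in np.nonzero(sel)[0][z > z_thresh]:
                flags.append((int(sess[pos]), int(rnd[pos]), str(sid[pos])))
    return flags


def remove_observations(ms: MeasurementSet, keys) -> MeasurementSet:
    """Explicitly drop observations named by ``(session, round, sample_id)`` keys."""
    keys = set(map(tuple, keys))
    mask = np.array([tuple(k) not in keys for k in ms.values.index])
    cov = ms.covariates[mask] if ms.covariates is not None else None
    return MeasurementSet(ms.values[mask], ms.classes, cov)
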