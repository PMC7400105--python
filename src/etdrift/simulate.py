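"""Synthetic multi-session sensor-array experiments.

The generator produces a clean class fingerprint per sample and layers the
disturbance mechanisms on top, in measurement order:

* per-session additive drift ``d_w`` (deterministic trend + random walk),
* per-session multiplicative gain drift ``g_w``,
* a linear temperature response ``beta * (T - T_ref)``,
* i.i.d. Gaussian sensor noise,
* cross-contamination: per-round dilution of the signal toward the cleaning
  water level, with a linearly advancing pH track,
* first-order memory carryover along the physical measurement sequence.

The returned experiment carries the drift-free ground truth and a parameter
record sufficient to reconstruct the observed values exactly, so recovery of
the generative parameters is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .data import DEFAULT_SENSORS, MeasurementSet
from .errors import ConfigError

_SQ7 = float(np.sqrt(7.0))
_BASE = np.array([150.0, -50.0, 80.0, 200.0, -30.0, 60.0, 100.0])
_U1 = np.ones(7) / _SQ7
_U2 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 0.0]) / np.sqrt(6.0)
_U3 = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0, 0.0]) / 2.0
_U4 = np.array([0.0, 0.0, 1.0, 1.0, -1.0, -1.0, 0.0]) / 2.0

#: Default 4-class fingerprints: pairwise separation >= 10 units at unit
#: noise, with the acid reference deliberately closest to the juice class.
DEFAULT_FINGERPRINTS: dict[str, tuple[float, ...]] = {
    "citric_acid": tuple(_BASE + 12.0 * _U1),
    "nacl": tuple(_BASE + 12.0 * _U2),
    "msg": tuple(_BASE + 12.0 * _U3),
    "apple_juice": tuple(_BASE + 12.0 * (0.6 * _U1 + 0.8 * _U4)),
}

_DRIFT_DIR = np.array([3.0, -1.0, 2.0, 1.0, -2.0, 1.0, 2.0])
_DRIFT_DIR = _DRIFT_DIR / np.linalg.norm(_DRIFT_DIR)
_TEMP_DIR = np.array([2.0, -3.0, 1.0, 2.0, -1.0, 3.0, 1.0])
_TEMP_DIR = _TEMP_DIR / np.linalg.norm(_TEMP_DIR)

SCENARIOS = ("baseline_drift", "temperature_sweep", "memory_orders", "contamination", "week5_shift")


@dataclass(frozen=True)
class SampleSpec:
    """One physical sample measured in every round."""

    sample_id: str
    class_label: str
    temperature: float | None = None  # overrides the session temperature


@dataclass(frozen=True)
class SimulationConfig:
    sensors: tuple[str, ...] = DEFAULT_SENSORS
    fingerprints: dict = field(default_factory=lambda: dict(DEFAULT_FINGERPRINTS))
    samples: tuple[SampleSpec, ...] | None = None  # default: one per class
    n_sessions: int = 6
    rounds_per_session: int = 18
    noise_sd: float = 1.0
    drift_step: float = 0.0  # sd of the per-sensor random-walk increment
    drift_trend: tuple[float, ...] | None = None  # deterministic per-session increment
    gain_step: float = 0.0  # g_w = 1 +/- gain_step * w, alternating per sensor
    base_temperature: float = 25.0
    reference_temperature: float = 25.0
    session_temperatures: dict | None = None  # session -> degrees C
    beta: tuple[float, ...] | None = None  # units per degree C
    carryover: float = 0.0  # lambda in [0, 1)
    dilution: float = 0.0  # per-round fractional shrink toward water
    water_signal: tuple[float, ...] | None = None
    ph_start: float = 3.8
    ph_increment: float = 0.1  # pH advance per dip (round)
    class_order_per_session: tuple | None = None  # per-session measurement order
    seed: int | None = None

    def validate(self) -> None:
        p = len(self.sensors)
        if p < 1:
            raise ConfigError("at least one sensor is required")
        if not self.fingerprints:
            raise ConfigError("fingerprints must not be empty")
        for label, mu in self.fingerprints.items():
            if len(mu) != p:
                raise ConfigError(f"fingerprint of {label!r} has {len(mu)} values, expected {p}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0.0 <= self.carryover < 1.0:
            raise ConfigError("carryover must lie in [0, 1)")
        if not 0.0 <= self.dilution < 1.0:
            raise ConfigError("dilution must lie in [0, 1)")
        if self.n_sessions < 1 or self.rounds_per_session < 1:
            raise ConfigError("n_sessions and rounds_per_session must be positive")
        for vec, name in ((self.drift_trend, "drift_trend"), (self.beta, "beta"),
                          (self.water_signal, "water_signal")):
            if vec is not None and len(vec) != p:
                raise ConfigError(f"{name} must have one entry per sensor")
        for spec in self.resolved_samples():
            if spec.class_label not in self.fingerprints:
                raise ConfigError(f"sample {spec.sample_id!r} has unknown class {spec.class_label!r}")
        if self.class_order_per_session is not None:
            if len(self.class_order_per_session) != self.n_sessions:
                raise ConfigError("class_order_per_session needs one order per session")
            ids = {s.sample_id for s in self.resolved_samples()}
            for order in self.class_order_per_session:
                if set(order) != ids:
                    raise ConfigError(f"order {order!r} must be a permutation of the sample ids")

    def resolved_samples(self) -> tuple[SampleSpec, ...]:
        if self.samples is not None:
            return tuple(self.samples)
        return tuple(SampleSpec(label, label) for label in self.fingerprints)

    # ------------------------------------------------------------- serde
    def to_dict(self) -> dict:
        d = asdict(self)
        d["fingerprints"] = {k: list(map(float, v)) for k, v in self.fingerprints.items()}
        if self.samples is not None:
            d["samples"] = [asdict(s) for s in self.samples]
        if self.session_temperatures is not None:
            d["session_temperatures"] = {str(k): float(v) for k, v in self.session_temperatures.items()}
        d["sensors"] = [str(s) for s in d["sensors"]]
        for key in ("drift_trend", "beta", "water_signal"):
            if d[key] is not None:
                d[key] = [float(v) for v in d[key]]
        if self.class_order_per_session is not None:
            d["class_order_per_session"] = [list(o) for o in self.class_order_per_session]
        return d

    @staticmethod
    def from_dict(d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("samples") is not None:
            d["samples"] = tuple(SampleSpec(**s) for s in d["samples"])
        if d.get("session_temperatures") is not None:
            d["session_temperatures"] = {int(k): float(v) for k, v in d["session_temperatures"].items()}
        for key in ("sensors", "drift_trend", "beta", "water_signal"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("fingerprints") is not None:
            d["fingerprints"] = {k: tuple(v) for k, v in d["fingerprints"].items()}
        if d.get("class_order_per_session") is not None:
            d["class_order_per_session"] = tuple(tuple(o) for o in d["class_order_per_session"])
        cfg = SimulationConfig(**d)
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @staticmethod
    def load(path) -> "SimulationConfig":
        with open(path) as fh:
            return SimulationConfig.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SimulatedExperiment:
    observed: MeasurementSet
    truth: MeasurementSet  # clean fingerprints, no noise, no disturbance
    ph_track: dict  # (session, round) -> pH
    params: dict  # generative record: drift, gain, noise, pre-memory signal, ...
    config: SimulationConfig


def simulate(config: SimulationConfig) -> SimulatedExperiment:
    """Run the generative model; deterministic for a given config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = len(config.sensors)
    samples = config.resolved_samples()
    by_id = {s.sample_id: s for s in samples}
    mu = {label: np.asarray(v, dtype=float) for label, v in config.fingerprints.items()}
    trend = np.asarray(config.drift_trend, float) if config.drift_trend is not None else np.zeros(p)
    beta = np.asarray(config.beta, float) if config.beta is not None else np.zeros(p)
    water = np.asarray(config.water_signal, float) if config.water_signal is not None else np.zeros(p)
    gain_sign = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(p)])

    # per-session additive drift: session 0 is the drift-free baseline
    drift: dict[int, np.ndarray] = {0: np.zeros(p)}
    for w in range(1, config.n_sessions):
        step = rng.normal(0.0, config.drift_step, size=p) if config.drift_step > 0 else np.zeros(p)
        drift[w] = drift[w - 1] + trend + step
    gain = {w: 1.0 + config.gain_step * w * gain_sign for w in range(config.n_sessions)}

    rows = []
    index = []
    truth_rows = []
    premem_rows = []
    noise_rows = []
    cov_rows = []
    ph_track: dict[tuple[int, int], float] = {}
    lam = config.carryover

    for w in range(config.n_sessions):
        t_session = config.base_temperature
        if config.session_temperatures and w in config.session_temperatures:
            t_session = config.session_temperatures[w]
        if config.class_order_per_session is not None:
            order = [by_id[i] for i in config.class_order_per_session[w]]
        else:
            order = list(samples)
        prev = None
        pos = 0
        for r in range(config.rounds_per_session):
            ph_track[(w, r)] = config.ph_start + config.ph_increment * r
            shrink = (1.0 - config.dilution) ** r
            for spec in order:
                temp = spec.temperature if spec.temperature is not None else t_session
                eps = rng.normal(0.0, config.noise_sd, size=p) if config.noise_sd > 0 else np.zeros(p)
                clean = mu[spec.class_label]
                x = gain[w] * clean + drift[w] + beta * (temp - config.reference_temperature) + eps
                x = water + (x - water) * shrink
                obs = x if prev is None else (1.0 - lam) * x + lam * prev
                prev = obs
                rows.append(obs)
                truth_rows.append(clean)
                premem_rows.append(x)
                noise_rows.append(eps)
                index.append((w, r, spec.sample_id))
                cov_rows.append((float(temp), pos))
                pos += 1

    midx = pd.MultiIndex.from_tuples(index, names=("session", "round", "sample_id"))
    # canonical (sorted) index; the physical order is kept in seq_pos
    values = pd.DataFrame(np.vstack(rows), index=midx, columns=list(config.sensors)).sort_index()
    truth_values = (
        pd.DataFrame(np.vstack(truth_rows), index=midx, columns=list(config.sensors))
        .sort_index()
    )
    covariates = pd.DataFrame(
        cov_rows, index=midx, columns=["temperature", "seq_pos"]
    ).sort_index()
    classes = pd.Series({s.sample_id: s.class_label for s in samples}, name="class")
    observed = MeasurementSet(values, classes, covariates)
    truth = MeasurementSet(truth_values, classes, covariates)
    params = {
        "additive_drift": drift,
        "gain": gain,
        "beta": beta,
        "carryover": lam,
        "dilution": config.dilution,
        "noise": pd.DataFrame(
            np.vstack(noise_rows), index=midx, columns=list(config.sensors)
        ).sort_index(),
        "premem": pd.DataFrame(
            np.vstack(premem_rows), index=midx, columns=list(config.sensors)
        ).sort_index(),
        "water_signal": water,
    }
    return SimulatedExperiment(observed, truth, ph_track, params, config)


# ----------------------------------------------------------------- scenarios
def scenario(name: str, **overrides) -> SimulationConfig:
    """Pre-parameterized configurations of the canonical experiments."""
    if name == "baseline_drift":
        cfg = dict(
            drift_trend=tuple(0.9 * _DRIFT_DIR),
            drift_step=0.1,
            seed=1,
        )
    elif name == "temperature_sweep":
        concentrations = (80, 85, 90, 95, 100)
        temperatures = (5.0, 15.0, 25.0, 35.0)
        conc_dir = _U3
        fingerprints = {
            f"aj_{c}": tuple(_BASE + 7.0 * (c - 90) * conc_dir) for c in concentrations
        }
        samples = tuple(
            SampleSpec(f"aj{c}_t{int(t)}", f"aj_{c}", temperature=t)
            for t in temperatures
            for c in concentrations
        )
        cfg = dict(
            fingerprints=fingerprints,
            samples=samples,
            n_sessions=1,
            rounds_per_session=3,
            beta=tuple(50.0 * _TEMP_DIR),
            reference_temperature=25.0,
            seed=1,
        )
    elif name == "memory_orders":
        orders = (
            ("citric_acid", "nacl", "msg", "apple_juice"),
            ("citric_acid", "apple_juice", "msg", "nacl"),
            ("citric_acid", "nacl", "apple_juice", "msg"),
        )
        cfg = dict(
            n_sessions=3,
            rounds_per_session=9,
            carryover=0.3,
            class_order_per_session=orders,
            seed=1,
        )
    elif name == "contamination":
        cfg = dict(
            fingerprints={"apple_juice": DEFAULT_FINGERPRINTS["apple_juice"]},
            n_sessions=1,
            rounds_per_session=9,
            dilution=0.02,
            ph_increment=0.1,
            seed=1,
        )
    elif name == "week5_shift":
        cfg = dict(
            drift_trend=tuple(0.9 * _DRIFT_DIR),
            drift_step=0.1,
            beta=tuple(50.0 * _TEMP_DIR),
            session_temperatures={5: 23.0},
            seed=1,
        )
    else:
        raise ConfigError(f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}")
    cfg.update(overrides)
    out = SimulationConfig(**cfg)
    out.validate()
    return out


def heavy_drift_config(seed: int = 1) -> SimulationConfig:
    """`baseline_drift` variant whose drift is strong enough to break raw
    classification of the juice class by the later sessions.

    The deterministic drift component points mostly along the msg/nacl
    separation (in the discriminant subspace, so centroids move) plus a
    generic direction, at roughly 4.5 units/session against unit noise.
    """
    mu = {k: np.asarray(v) for k, v in DEFAULT_FINGERPRINTS.items()}
    vec = mu["msg"] - mu["nacl"]
    trend = 4.0 * vec / np.linalg.norm(vec) + 2.0 * _DRIFT_DIR
    return scenario("baseline_drift", drift_trend=tuple(trend), drift_step=0.3, seed=seed)


# ------------------------------------------------------------- recovery
@dataclass(frozen=True)
class ParameterEstimates:
    additive_drift: dict  # session -> per-sensor mean disturbance
    beta_norm: float | None  # slope of centroid distance vs delta-T
    carryover: float


def recover_parameters(exp: SimulatedExperiment) -> ParameterEstimates:
    """Estimate the generative parameters back from a simulated experiment.

    * additive drift: per-session mean of (observed - truth) per sensor,
    * temperature sensitivity norm: slope of sensor-space centroid distance
      versus temperature difference from the coolest group (requires >= 3
      temperature levels),
    * carryover: lag-1 regression (through the origin) of the memory residual
      ``obs_i - x_i`` on ``obs_{i-1} - x_i``, pooled over sensors, where
      ``x`` is the recorded pre-memory signal.
    """
    from .evaluation import centroid_distances_sensor_space, fit_trend

    obs = exp.observed
    diff = obs.values.to_numpy(dtype=float) - exp.truth.values.to_numpy(dtype=float)
    sess = obs.values.index.get_level_values("session").to_numpy()
    drift_est = {int(w): diff[sess == w].mean(axis=0) for w in obs.sessions}

    beta_norm = None
    if obs.covariates is not None and "temperature" in obs.covariates.columns:
        temps = obs.covariates["temperature"].to_numpy()
        levels = np.unique(temps)
        if len(levels) >= 3:
            dist = centroid_distances_sensor_space(obs, "temperature", levels.min())
            dts = [float(t - levels.min()) for t in levels]
            ds = [dist[float(t)] for t in levels]
            beta_norm = fit_trend(dts, ds).slope

    premem = exp.params["premem"].to_numpy(dtype=float)
    x_obs = obs.values.to_numpy(dtype=float)
    seq = obs.covariates["seq_pos"].to_numpy()
    num = 0.0
    den = 0.0
    n_pairs = 0
    for w in obs.sessions:
        sel = np.nonzero(sess == w)[0]
        sel = sel[np.argsort(seq[sel])]  # physical measurement order
        if len(sel) < 2:
            continue
        u = x_obs[sel[1:]] - premem[sel[1:]]
        v = x_obs[sel[:-1]] - premem[sel[1:]]
        num += float(np.sum(u * v))
        den += float(np.sum(v * v))
        n_pairs += len(sel) - 1
    if n_pairs == 0:
        raise ConfigError("insufficient observations for the lag-1 carryover regression")
    carry = num / den if den > 0 else 0.0
    return ParameterEstimates(drift_est, beta_norm, float(carry))
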