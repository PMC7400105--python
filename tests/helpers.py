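"""Shared builders for hand-made measurement sets."""

from __future__ import annotations

import numpy as np
import pandas as pd

from etdrift.data import MeasurementSet


def build_ms(blocks, sensors, classes, covariates=None) -> MeasurementSet:
    """Construct a MeasurementSet from ``{(session, round): {sample_id: vector}}``.

    *classes* maps sample_id -> class label.  *covariates*, if given, maps
    ``(session, round, sample_id) -> {"temperature": ..., "seq_pos": ...}``.
    """
    index = []
    rows = []
    for (session, rnd), samples in blocks.items():
        for sample_id, vec in samples.items():
            index.append((session, rnd, sample_id))
            rows.append(np.asarray(vec, dtype=float))
    midx = pd.MultiIndex.from_tuples(index, names=("session", "round", "sample_id"))
    values = pd.DataFrame(np.vstack(rows), index=midx, columns=list(sensors))
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(
            [covariates.get(k, {}) for k in index], index=midx
        )
    return MeasurementSet(values.sort_index(), pd.Series(classes), cov)


def gaussian_classes_ms(
    means: dict, n_per_class: int, sensors, noise_sd: float = 1.0, seed: int = 0,
    session: int = 0,
) -> MeasurementSet:
    """One session, *n_per_class* rounds; one sample per class per round."""
    rng = np.random.default_rng(seed)
    blocks: dict = {}
    for r in range(n_per_class):
        blocks[(session, r)] = {
            label: np.asarray(mu, float) + rng.normal(0, noise_sd, len(sensors))
            for label, mu in means.items()
        }
    return build_ms(blocks, sensors, {label: label for label in means})
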