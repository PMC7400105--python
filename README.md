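# etdrift

Drift correction and evaluation toolkit for multi-sensor electronic-tongue
(potentiometric sensor array) measurements.

Long-running sensor-array experiments suffer from signal drift: additive and
multiplicative session-to-session shifts, temperature sensitivity, carryover
("memory") between consecutive samples, and cross-contamination through the
cleaning fluid. `etdrift` implements four drift-correction methods, the
matching evaluation protocol, and a synthetic generator of drifting
experiments, so the entire pipeline can be exercised without instrument data.

## Components

- **`etdrift.data`** — long/wide CSV I/O for `(session, round, sample, sensor)`
  measurement tables, trace collapsing (average of the final acquisition
  window), pretreatment (dropping initial conditioning rounds, robust
  outlier flagging).
- **`etdrift.corrections`** — the four methods, each a fit/apply pair:
  - `additive_all`: subtract each round's mean over *all* samples,
  - `additive_ref`: subtract each round's mean over designated reference classes,
  - `linear_ref`: per-sensor affine map of each session onto the base session,
    fitted on reference-class centroids (needs ≥ 2 reference classes),
  - `cc` / `cc_modified`: component correction — remove the dominant
    PCA drift direction of a reference class; the modified variant subtracts
    the drift component twice from later sessions only, mapping them onto the
    base session while leaving base-session data untouched.
- **`etdrift.evaluation`** — base-session LDA with canonical discriminant
  axes, projection of later sessions, stratified threefold cross-validation,
  per-(session, class) accuracy and confusion, relative centroid distances in
  discriminant space, sensor-space centroid distances, PCA, OLS trend fits.
- **`etdrift.simulate`** — configurable generator (class fingerprints,
  additive/gain drift, temperature response, carryover, dilution/pH track)
  with named scenarios (`baseline_drift`, `temperature_sweep`,
  `memory_orders`, `contamination`, `week5_shift`), ground truth, and
  parameter-recovery helpers.
- **`etdrift.cli`** — `etdrift simulate|correct|evaluate|compare`.

## CLI quick start

```bash
etdrift simulate --scenario baseline_drift --seed 1 --out run/sim
etdrift correct -i run/sim/measurements.csv --method additive_all --out run/corr
etdrift evaluate -i run/corr/corrected.csv \
    --target-class apple_juice --norm-pair msg,citric_acid --seed 1 --out run/eval
etdrift compare -i run/sim/measurements.csv \
    --reference-classes citric_acid,nacl,msg --reference-class citric_acid \
    --target-class apple_juice --norm-pair msg,citric_acid --out run/cmp
```

Exit codes: `0` success, `2` usage error, `3` data/config error.
All commands are deterministic given explicit seeds.

## Library quick start

```python
from etdrift.simulate import scenario, simulate
from etdrift.corrections import correct
from etdrift.evaluation import threefold_cv

exp = simulate(scenario("baseline_drift", seed=1))
corrected, model = correct(exp.observed, "additive_all")
report = threefold_cv(corrected, base_session=0, seed=1,
                      target_class="apple_juice", norm_pair=("msg", "citric_acid"))
print(report.accuracy_frame())
```

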