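import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etdrift.corrections import (
    apply_additive,
    apply_component_correction,
    apply_linear_map,
    correct,
    fit_additive_all,
    fit_additive_reference,
    fit_drift_component,
    fit_linear_map,
    load_model,
    model_from_dict,
    model_to_dict,
    save_model,
)
from etdrift.data import MeasurementSet
from etdrift.errors import DataError, FitError
from helpers import build_ms

SENSORS2 = ("ZZ", "BA")


def _random_ms(seed=0, n_sessions=2, n_rounds=3, sensors=7):
    rng = np.random.default_rng(seed)
    names = tuple(f"S{i}" for i in range(sensors))
    classes = ("acid", "salt", "umami", "juice")
    blocks = {
        (w, r): {c: rng.normal(size=sensors) * 10 for c in classes}
        for w in range(n_sessions)
        for r in range(n_rounds)
    }
    return build_ms(blocks, names, {c: c for c in classes})


class TestAdditiveAll:
    def test_two_value_block(self):
        ms = build_ms(
            {(0, 0): {"a": [3.0, 0.0], "b": [5.0, 0.0]}},
            SENSORS2,
            {"a": "acid", "b": "salt"},
        )
        model = fit_additive_all(ms)
        assert model.offsets[(0, 0)][0] == 4.0

    def test_zero_mean_block_gives_zero_offsets(self):
        ms = build_ms(
            {(0, 0): {"a": [-1.0, 2.0], "b": [1.0, -2.0]}},
            SENSORS2,
            {"a": "acid", "b": "salt"},
        )
        assert np.allclose(fit_additive_all(ms).offsets[(0, 0)], 0.0)

    def test_matches_hand_loop_means(self):
        ms = _random_ms(seed=5)
        model = fit_additive_all(ms)
        for (w, r), block in ms.iter_blocks():
            arr = block.to_numpy()
            for j in range(arr.shape[1]):
                total = 0.0
                for i in range(arr.shape[0]):
                    total += arr[i, j]
                assert model.offsets[(w, r)][j] == pytest.approx(total / arr.shape[0], abs=1e-12)

    def test_incomplete_block_rejected(self):
        blocks = {
            (0, 0): {"a": [1.0, 1.0], "b": [2.0, 2.0]},
            (0, 1): {"a": [1.0, 1.0]},
        }
        ms = build_ms(blocks, SENSORS2, {"a": "acid", "b": "salt"})
        with pytest.raises(DataError, match="incomplete"):
            fit_additive_all(ms)


class TestAdditiveReference:
    def test_non_reference_ignored(self):
        ms = build_ms(
            {(0, 0): {"a": [1.0, 0.0], "b": [3.0, 0.0], "c": [10.0, 0.0]}},
            SENSORS2,
            {"a": "acid", "b": "salt", "c": "juice"},
        )
        model = fit_additive_reference(ms, ["acid", "salt"])
        assert model.offsets[(0, 0)][0] == 2.0

    def test_all_classes_reduces_to_additive_all(self):
        ms = _random_ms(seed=2)
        full = fit_additive_all(ms)
        ref = fit_additive_reference(ms, list(ms.class_labels()))
        for key in full.offsets:
            assert np.allclose(full.offsets[key], ref.offsets[key])

    def test_matches_brute_force_reference_means(self):
        ms = _random_ms(seed=9)
        refs = ("acid", "salt", "umami")
        model = fit_additive_reference(ms, refs)
        for (w, r), block in ms.iter_blocks():
            labels = ms.classes[block.index.get_level_values("sample_id")].to_numpy()
            rows = [block.to_numpy()[i] for i in range(len(labels)) if labels[i] in refs]
            expected = [sum(v[j] for v in rows) / len(rows) for j in range(len(ms.sensors))]
            assert np.allclose(model.offsets[(w, r)], expected, atol=1e-12)

    def test_missing_reference_names_block(self):
        blocks = {
            (0, 0): {"a": [1.0, 1.0], "b": [2.0, 2.0]},
            (1, 0): {"b": [2.0, 2.0], "a": [1.0, 1.0]},
        }
        del blocks[(1, 0)]["a"]
        ms = build_ms(blocks, SENSORS2, {"a": "acid", "b": "salt"})
        with pytest.raises(DataError, match=r"session=1, round=0"):
            fit_additive_reference(ms, ["acid"])


class TestApplyAdditive:
    def test_blocks_zero_centered(self):
        ms = _random_ms(seed=1)
        out = apply_additive(ms, fit_additive_all(ms))
        for _, block in out.iter_blocks():
            assert np.all(np.abs(block.to_numpy().mean(axis=0)) < 1e-10)

    def test_idempotent_after_refit(self):
        ms = _random_ms(seed=4)
        once = apply_additive(ms, fit_additive_all(ms))
        twice = apply_additive(once, fit_additive_all(once))
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_block_shift_absorbed(self):
        ms = _random_ms(seed=6)
        shifted_values = ms.values.copy()
        sel = shifted_values.index.get_level_values("session") == 1
        shifted_values.loc[sel] += 17.0
        shifted = ms.with_values(shifted_values)
        a = apply_additive(ms, fit_additive_all(ms))
        b = apply_additive(shifted, fit_additive_all(shifted))
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-10)

    def test_uncovered_block_rejected(self):
        ms = _random_ms(seed=3, n_sessions=1)
        other = _random_ms(seed=3, n_sessions=2)
        model = fit_additive_all(ms)
        with pytest.raises(DataError, match="no offsets"):
            apply_additive(other, model)


class TestLinearMap:
    def test_identical_references_identity(self):
        blocks = {
            (0, 0): {"a": [1.0, 5.0], "b": [3.0, 9.0]},
            (1, 0): {"a": [1.0, 5.0], "b": [3.0, 9.0]},
        }
        ms = build_ms(blocks, SENSORS2, {"a": "acid", "b": "salt"})
        model = fit_linear_map(ms, ["acid", "salt"])
        assert np.allclose(model.slope[1], 1.0)
        assert np.allclose(model.intercept[1], 0.0, atol=1e-12)

    def test_pure_offset_drift(self):
        blocks = {
            (0, 0): {"a": [1.0, 5.0], "b": [3.0, 9.0]},
            (1, 0): {"a": [-9.0, -5.0], "b": [-7.0, -1.0]},
        }
        ms = build_ms(blocks, SENSORS2, {"a": "acid", "b": "salt"})
        model = fit_linear_map(ms, ["acid", "salt"])
        assert np.allclose(model.slope[1], 1.0)
        assert np.allclose(model.intercept[1], 10.0)

    def test_exact_affine_relation_and_normal_equation_oracle(self):
        # three reference centroids obeying y = 2x + 1 exactly on sensor 0
        blocks = {
            (0, 0): {"a": [3.0, 0.0], "b": [5.0, 1.0], "c": [9.0, 2.0]},
            (1, 0): {"a": [1.0, 0.5], "b": [2.0, 1.5], "c": [4.0, 2.5]},
        }
        ms = build_ms(blocks, SENSORS2, {"a": "acid", "b": "salt", "c": "umami"})
        model = fit_linear_map(ms, ["acid", "salt", "umami"])
        assert model.slope[1][0] == pytest.approx(2.0, abs=1e-12)
        assert model.intercept[1][0] == pytest.approx(1.0, abs=1e-12)
        # independent normal-equation oracle for sensor 1
        x = np.array([0.5, 1.5, 2.5])
        y = np.array([0.0, 1.0, 2.0])
        A = np.array([[3.0, x.sum()], [x.sum(), (x * x).sum()]])
        rhs = np.array([y.sum(), (x * y).sum()])
        b_hat, m_hat = np.linalg.solve(A, rhs)
        assert model.slope[1][1] == pytest.approx(m_hat, abs=1e-10)
        assert model.intercept[1][1] == pytest.approx(b_hat, abs=1e-10)

    def test_fewer_than_two_references_rejected(self):
        ms = _random_ms()
        with pytest.raises(DataError, match="two reference"):
            fit_linear_map(ms, ["acid"])

    def test_zero_spread_sensor_named(self):
        blocks = {
            (0, 0): {"a": [1.0, 5.0], "b": [3.0, 9.0]},
            (1, 0): {"a": [2.0, 4.0], "b": [2.0, 8.0]},
        }
        ms = build_ms(blocks, SENSORS2, {"a": "acid", "b": "salt"})
        with pytest.raises(FitError, match="ZZ"):
            fit_linear_map(ms, ["acid", "salt"])

    def test_apply_identity(self):
        ms = _random_ms(seed=8)
        model = fit_linear_map(ms, ["acid", "salt", "umami"])
        identity = type(model)(
            {w: np.ones(len(ms.sensors)) for w in ms.sessions},
            {w: np.zeros(len(ms.sensors)) for w in ms.sessions},
            model.reference_classes,
            0,
            ms.sensors,
        )
        out = apply_linear_map(ms, identity)
        pd.testing.assert_frame_equal(out.values, ms.values)

    def test_exact_inversion_of_affine_drift(self):
        # session 1 = (session 0 - b0) / m0 per sensor; correction must invert it
        rng = np.random.default_rng(11)
        classes = {"a": "acid", "b": "salt", "c": "umami", "d": "juice"}
        base = {c: rng.normal(size=2) * 10 for c in classes}
        m0 = np.array([2.0, 0.5])
        b0 = np.array([-3.0, 7.0])
        blocks = {
            (0, 0): dict(base),
            (1, 0): {c: (base[c] - b0) / m0 for c in classes},
        }
        ms = build_ms(blocks, SENSORS2, classes)
        model = fit_linear_map(ms, ["acid", "salt", "umami"])
        out = apply_linear_map(ms, model)
        X1 = out.values.loc[1].to_numpy()
        X0 = out.values.loc[0].to_numpy()
        assert np.max(np.abs(X1 - X0)) < 1e-9  # all classes, not just references

    def test_cellwise_oracle(self):
        ms = _random_ms(seed=13)
        model = fit_linear_map(ms, ["acid", "salt", "umami"])
        out = apply_linear_map(ms, model)
        for key in ms.values.index:
            w = key[0]
            for j, sensor in enumerate(ms.sensors):
                expected = model.slope[w][j] * ms.values.loc[key, sensor] + model.intercept[w][j]
                assert out.values.loc[key, sensor] == pytest.approx(expected, abs=1e-12)

    def test_session_missing_from_model(self):
        ms = _random_ms(seed=1, n_sessions=3)
        model = fit_linear_map(ms.subset_sessions([0, 1]), ["acid", "salt", "umami"])
        with pytest.raises(DataError, match="session"):
            apply_linear_map(ms, model)


class TestDriftComponent:
    def _two_cluster_ms(self, delta, noise=0.0, seed=0, n=6):
        rng = np.random.default_rng(seed)
        blocks = {}
        for r in range(n):
            blocks[(0, r)] = {"ref": rng.normal(0, noise, 2) if noise else np.zeros(2)}
            blocks[(1, r)] = {
                "ref": np.asarray(delta, float) + (rng.normal(0, noise, 2) if noise else 0.0)
            }
        return build_ms(blocks, SENSORS2, {"ref": "acid"})

    def test_axis_aligned_displacement(self):
        ms = self._two_cluster_ms([4.0, 0.0])
        (comp,) = fit_drift_component(ms, "acid", pairing="first_last")
        assert np.allclose(np.abs(comp.loading), [1.0, 0.0])
        assert np.allclose(comp.center, [2.0, 0.0])

    def test_no_drift_degeneracy_projection_small(self):
        ms = self._two_cluster_ms([0.0, 0.0], noise=0.01, seed=3)
        (comp,) = fit_drift_component(ms, "acid", pairing="first_last")
        t = (ms.values.to_numpy() - comp.center) @ comp.loading
        assert np.max(np.abs(t)) < 0.1  # noise scale only

    def test_diagonal_toy_matches_eigen_oracle(self):
        ms = self._two_cluster_ms([4.0, 4.0], noise=0.3, seed=5, n=40)
        (comp,) = fit_drift_component(ms, "acid", pairing="first_last")
        # independent oracle: explicit 2x2 covariance eigen-decomposition
        X = ms.values.to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        assert abs(abs(lead @ comp.loading) - 1.0) < 1e-10
        assert np.allclose(np.abs(comp.loading), np.abs([1, 1] / np.sqrt(2)), atol=0.1)

    def test_sign_convention_follows_displacement(self):
        ms = self._two_cluster_ms([-5.0, 0.0], noise=0.1, seed=2)
        (comp,) = fit_drift_component(ms, "acid", pairing="first_last")
        assert comp.loading[0] < 0

    def test_rank_zero_pool_rejected(self):
        blocks = {(w, r): {"ref": [1.0, 1.0]} for w in (0, 1) for r in range(3)}
        ms = build_ms(blocks, SENSORS2, {"ref": "acid"})
        with pytest.raises(FitError, match="zero variance"):
            fit_drift_component(ms, "acid", pairing="first_last")

    def test_each_week_pairing_yields_one_component_per_later_session(self):
        ms = _random_ms(seed=7, n_sessions=4)
        comps = fit_drift_component(ms, "acid", pairing="each_week_to_week0")
        assert [c.later_session for c in comps] == [1, 2, 3]


class TestApplyComponentCorrection:
    def test_classic_removes_reference_variance_along_p(self, baseline_ms):
        (comp,) = fit_drift_component(baseline_ms, "citric_acid", pairing="first_last")
        out = apply_component_correction(baseline_ms, comp)
        X, y, _ = out.matrix()
        ref = X[y == "citric_acid"]
        along = (ref - ref.mean(axis=0)) @ comp.loading
        total = np.sum((ref - ref.mean(axis=0)) ** 2)
        assert np.sum(along**2) <= 1e-10 * total

    def test_modified_translation_maps_centroid_onto_base(self):
        # noiseless pure translation: the displacement is exactly the leading
        # drift loading, so the reflection maps the later cluster onto base
        delta = 3.7 * np.array([1.0, 2.0]) / np.sqrt(5.0)
        base = np.array([0.4, -1.2])
        blocks = {
            (0, 0): {f"r{i}": base for i in range(8)},
            (1, 0): {f"r{i}": base + delta for i in range(8)},
        }
        ms = build_ms(blocks, SENSORS2, {f"r{i}": "acid" for i in range(8)})
        (comp,) = fit_drift_component(ms, "acid", pairing="first_last", multiplier=2)
        out = apply_component_correction(ms, comp)
        c0 = out.values.loc[0].to_numpy().mean(axis=0)
        c1 = out.values.loc[1].to_numpy().mean(axis=0)
        assert np.max(np.abs(c1 - c0)) < 1e-10
        # base session is bit-identical
        assert out.values.loc[0].equals(ms.values.loc[0])

    def test_modified_translation_with_noise_is_approximate(self):
        rng = np.random.default_rng(0)
        delta = 8.0 * np.array([1.0, 2.0]) / np.sqrt(5.0)
        base_pts = {f"r{i}": 0.1 * rng.normal(size=2) for i in range(12)}
        blocks = {(0, 0): dict(base_pts), (1, 0): {k: v + delta for k, v in base_pts.items()}}
        ms = build_ms(blocks, SENSORS2, {k: "acid" for k in base_pts})
        (comp,) = fit_drift_component(ms, "acid", pairing="first_last", multiplier=2)
        out = apply_component_correction(ms, comp)
        c0 = out.values.loc[0].to_numpy().mean(axis=0)
        c1 = out.values.loc[1].to_numpy().mean(axis=0)
        assert np.max(np.abs(c1 - c0)) < 0.1  # noise-limited

    def test_sign_flip_invariance(self, baseline_ms):
        (comp,) = fit_drift_component(baseline_ms, "citric_acid", pairing="first_last")
        flipped = type(comp)(
            comp.center, -comp.loading, comp.multiplier, comp.reference_class,
            comp.base_session, comp.later_session, comp.pairing, comp.sensors,
        )
        a = apply_component_correction(baseline_ms, comp)
        b = apply_component_correction(baseline_ms, flipped)
        assert a.values.equals(b.values)


class TestCorrectDispatch:
    def test_none_is_identity(self, baseline_ms):
        out, model = correct(baseline_ms, "none")
        assert out is baseline_ms
        assert model is None

    def test_additive_all_zero_centers(self):
        ms = _random_ms(seed=21, n_sessions=1)
        out, _ = correct(ms, "additive_all")
        for _, block in out.iter_blocks():
            assert np.all(np.abs(block.to_numpy().mean(axis=0)) < 1e-10)

    @pytest.mark.parametrize("method", ["additive_all", "additive_ref", "linear_ref", "cc", "cc_modified"])
    def test_dispatch_equals_direct_calls(self, baseline_ms, method):
        refs = ("citric_acid", "nacl", "msg")
        out, _ = correct(
            baseline_ms, method, reference_classes=refs, reference_class="citric_acid"
        )
        if method == "additive_all":
            direct = apply_additive(baseline_ms, fit_additive_all(baseline_ms))
        elif method == "additive_ref":
            direct = apply_additive(baseline_ms, fit_additive_reference(baseline_ms, refs))
        elif method == "linear_ref":
            direct = apply_linear_map(baseline_ms, fit_linear_map(baseline_ms, refs))
        elif method == "cc":
            (comp,) = fit_drift_component(baseline_ms, "citric_acid", pairing="first_last")
            direct = apply_component_correction(baseline_ms, comp)
        else:
            comps = fit_drift_component(
                baseline_ms, "citric_acid", pairing="each_week_to_week0", multiplier=2
            )
            direct = baseline_ms
            for comp in comps:
                direct = apply_component_correction(direct, comp, sessions=[comp.later_session])
        pd.testing.assert_frame_equal(out.values, direct.values)

    def test_missing_option_rejected(self, baseline_ms):
        with pytest.raises(DataError, match="reference_classes"):
            correct(baseline_ms, "linear_ref")

    def test_unknown_method_rejected(self, baseline_ms):
        with pytest.raises(DataError, match="unknown method"):
            correct(baseline_ms, "splines")


class TestSerialization:
    @pytest.mark.parametrize("method", ["none", "additive_all", "linear_ref", "cc_modified"])
    def test_round_trip(self, baseline_ms, tmp_path, method):
        _, model = correct(
            baseline_ms, method,
            reference_classes=("citric_acid", "nacl", "msg"),
            reference_class="citric_acid",
        )
        path = tmp_path / "model.json"
        save_model(model, method, path)
        loaded, name = load_model(path)
        assert name == method
        doc = model_to_dict(loaded, name)
        assert doc == model_to_dict(*model_from_dict(doc))


class TestCorrectionProperties:
    @pytest.mark.parametrize("method", ["additive_all", "additive_ref", "linear_ref", "cc", "cc_modified"])
    def test_sensor_permutation_equivariance(self, baseline_ms, method):
        perm = [3, 0, 6, 1, 5, 2, 4]
        sensors = baseline_ms.sensors
        permuted = MeasurementSet(
            baseline_ms.values[[sensors[i] for i in perm]],
            baseline_ms.classes,
            baseline_ms.covariates,
        )
        kwargs = dict(reference_classes=("citric_acid", "nacl", "msg"), reference_class="citric_acid")
        out, _ = correct(baseline_ms, method, **kwargs)
        out_p, _ = correct(permuted, method, **kwargs)
        expected = out.values[[sensors[i] for i in perm]]
        assert np.allclose(out_p.values.to_numpy(), expected.to_numpy(), atol=1e-9)

    @pytest.mark.parametrize("method", ["linear_ref", "cc", "cc_modified"])
    def test_global_constant_shift_invariance(self, baseline_ms, method):
        shifted = baseline_ms.with_values(baseline_ms.values + 42.0)
        kwargs = dict(reference_classes=("citric_acid", "nacl", "msg"), reference_class="citric_acid")
        out, _ = correct(baseline_ms, method, **kwargs)
        out_s, _ = correct(shifted, method, **kwargs)
        assert np.allclose(out_s.values.to_numpy(), out.values.to_numpy() + 42.0, atol=1e-8)

    @pytest.mark.parametrize("method", ["additive_all", "additive_ref"])
    def test_additive_removes_global_constant(self, baseline_ms, method):
        shifted = baseline_ms.with_values(baseline_ms.values + 42.0)
        kwargs = dict(reference_classes=("citric_acid", "nacl", "msg"))
        out, _ = correct(baseline_ms, method, **kwargs)
        out_s, _ = correct(shifted, method, **kwargs)
        assert np.allclose(out_s.values.to_numpy(), out.values.to_numpy(), atol=1e-9)

    @given(shift=st.floats(-100.0, 100.0))
    @settings(max_examples=10, deadline=None)
    def test_additive_shift_property(self, shift):
        ms = _random_ms(seed=17)
        shifted = ms.with_values(ms.values + shift)
        a, _ = correct(ms, "additive_all")
        b, _ = correct(shifted, "additive_all")
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-9)
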