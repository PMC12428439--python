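import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import pepscreen as ps
from pepscreen.errors import ConfigurationError, FeatureLayoutError, IntegrityError
from pepscreen.models import _round_half_away, prediction_table


@pytest.fixture(scope="module")
def trained(small_stratified_dataset_module):
    ds = small_stratified_dataset_module
    train, test = ps.split_dataset(ds, ps.SplitSpec(0.2, 42))
    spec = ps.ModelSpec(task="classifier", rule="ro5", n_trees=10, seed=0)
    return ps.train_model(train, spec), train, test


@pytest.fixture(scope="module")
def small_stratified_dataset_module():
    cfg = ps.SamplerConfig(n=1000, seed=11, stratify_rule="ro5")
    table = ps.sample_descriptor_vectors(cfg)
    return ps.build_dataset_from_descriptor_table(
        table, [ps.builtin_ruleset("ro5"), ps.builtin_ruleset("bro5")]
    )


class TestTraining:
    def test_near_perfect_in_sample_fit(self, trained):
        model, train, _ = trained
        y_pred = ps.predict_counts(model, train.features)
        accuracy = np.mean(y_pred == train.targets["ro5"])
        assert accuracy >= 0.99

    def test_seeded_determinism(self, small_stratified_dataset_module):
        ds = small_stratified_dataset_module
        train, test = ps.split_dataset(ds)
        spec = ps.ModelSpec(task="classifier", rule="ro5", n_trees=10, seed=5)
        m1 = ps.train_model(train, spec)
        m2 = ps.train_model(train, spec)
        assert np.array_equal(ps.predict_counts(m1, test.features), ps.predict_counts(m2, test.features))

    def test_missing_rule_errors(self, small_stratified_dataset_module):
        train, _ = ps.split_dataset(small_stratified_dataset_module)
        with pytest.raises(ConfigurationError, match="muegge"):
            ps.train_model(train, ps.ModelSpec(task="classifier", rule="muegge", n_trees=10))

    def test_single_class_target_warns_but_trains(self):
        X = pd.DataFrame({"mw": [100.0, 200.0, 300.0], "logp": [1.0, 2.0, 3.0]})
        y = np.zeros(3, dtype=int)
        clf = ps.ViolationCountClassifier(rule="ro5", n_trees=5)
        with pytest.warns(UserWarning, match="single-class"):
            clf.fit(X, y)
        assert (clf.predict(X) == 0).all()

    def test_metadata_populated(self, trained):
        model, train, _ = trained
        assert model.spec.parity
        assert model.feature_names == train.feature_names
        assert model.thresholds_fingerprint == ps.builtin_ruleset("ro5").thresholds_fingerprint()
        assert model.provenance["n_train_rows"] == train.n


class TestSklearnCompat:
    def test_get_set_params_and_clone(self):
        clf = ps.ViolationCountClassifier(rule="bro5", n_trees=20, seed=3)
        params = clf.get_params()
        assert params["rule"] == "bro5" and params["n_trees"] == 20
        cloned = clone(clf)
        assert cloned.get_params() == params
        cloned.set_params(n_trees=30)
        assert cloned.n_trees == 30

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            ps.ViolationCountClassifier().predict(np.zeros((2, 9)))


class TestPrediction:
    def test_rounding_half_away_from_zero(self):
        assert _round_half_away(np.array([2.49, 2.5, -0.3, -2.5, 0.5])).tolist() == [2, 3, 0, -3, 1]

    def test_regressor_counts_clipped_to_rule_range(self, small_stratified_dataset_module):
        train, test = ps.split_dataset(small_stratified_dataset_module)
        reg = ps.train_model(train, ps.ModelSpec(task="regressor", rule="ro5", n_trees=10))
        counts = ps.predict_counts(reg, test.features)
        assert counts.dtype.kind == "i"
        assert counts.min() >= 0 and counts.max() <= 4

    def test_predictions_invariant_to_row_order(self, trained):
        model, _, test = trained
        perm = np.random.default_rng(0).permutation(test.n)
        direct = ps.predict_counts(model, test.features)[perm]
        permuted = ps.predict_counts(model, test.features[perm])
        assert np.array_equal(direct, permuted)

    def test_prediction_far_from_boundaries_matches_oracle(self, trained):
        model, _, _ = trained
        point = pd.DataFrame(
            [dict(mw=300.0, logp=2.0, hbd=2, hba=5, tpsa=80.0, n_rotb=5, n_carbon=20, n_hetero=5, n_rings=2)]
        )
        assert ps.predict_counts(model, point.to_numpy())[0] == 0

    def test_layout_mismatch_rejected(self, trained):
        model, _, test = trained
        with pytest.raises(FeatureLayoutError):
            ps.predict_counts(model, test.features[:, :5])
        bad = pd.DataFrame(test.features[:, :9], columns=[*test.feature_names[:8], "charge"])
        with pytest.raises(FeatureLayoutError, match="charge"):
            model.estimator.predict(bad)

    def test_monotone_along_mw_path(self, trained):
        model, _, _ = trained
        mids = dict(logp=2.5, hbd=3, hba=6, tpsa=120.0, n_rotb=8, n_carbon=30, n_hetero=8, n_rings=3)
        path = pd.DataFrame([{"mw": mw, **mids} for mw in np.linspace(400, 1600, 60)])
        path = path[list(ps.DESCRIPTOR_KEYS)]
        preds = ps.predict_counts(model, path.to_numpy())
        assert (np.diff(preds) >= 0).all()

    def test_prediction_table_layout(self, trained):
        model, _, test = trained
        out = prediction_table([model], test.features[:5], test.ids[:5])
        assert list(out.columns) == ["id", "rule", "task", "n_trees", "predicted_violations"]
        assert len(out) == 5


class TestPersistence:
    def test_round_trip_preserves_predictions(self, trained, tmp_path):
        model, _, test = trained
        path = tmp_path / "model.joblib"
        ps.save_model(model, path)
        back = ps.load_model(path)
        probe = test.features[:100]
        assert np.array_equal(ps.predict_counts(model, probe), ps.predict_counts(back, probe))
        assert back.spec.n_trees == model.spec.n_trees
        assert back.thresholds_fingerprint == model.thresholds_fingerprint

    def test_corrupted_sidecar_rejected(self, trained, tmp_path):
        model, _, _ = trained
        path = tmp_path / "model.joblib"
        ps.save_model(model, path)
        sidecar = tmp_path / "model.joblib.meta.json"
        sidecar.write_text("{not json")
        with pytest.raises(IntegrityError):
            ps.load_model(path)

    def test_mismatched_sidecar_rejected(self, trained, tmp_path):
        import json

        model, _, _ = trained
        path = tmp_path / "model.joblib"
        ps.save_model(model, path)
        sidecar = tmp_path / "model.joblib.meta.json"
        meta = json.loads(sidecar.read_text())
        meta["spec"]["n_trees"] = 99
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(IntegrityError, match="mismatch"):
            ps.load_model(path)

    def test_missing_sidecar_rejected(self, trained, tmp_path):
        import joblib

        model, _, _ = trained
        path = tmp_path / "bare.joblib"
        joblib.dump(model.estimator, path)
        with pytest.raises(IntegrityError, match="sidecar"):
            ps.load_model(path)
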