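import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import porevoc as pv
from porevoc.analytes import ValidationError
from porevoc.classify import (
    FEATURES,
    GaussianEventClassifier,
    feature_matrix,
    train,
)


@pytest.fixture(scope="module")
def seven_class_events(ag):
    names = ("ethanal", "propanal", "butanal", "pentanal", "hexanal",
             "heptanal", "octanal")
    return pv.sample_labeled_events(
        [ag.analyte(n) for n in names], 300, ag.pore, seed=101)


class TestStratifiedSplit:
    def _events(self, n_per_class=100, classes=("a", "b", "c")):
        rng = np.random.default_rng(0)
        frames = [pd.DataFrame({
            "ires_pct": rng.normal(90 + i, 0.1, n_per_class),
            "duration_s": rng.exponential(0.1, n_per_class),
            "rms_noise_pa": np.abs(rng.normal(1, 0.1, n_per_class)),
            "label": c}) for i, c in enumerate(classes)]
        return pd.concat(frames, ignore_index=True)

    def test_thirty_percent_per_class(self):
        train_df, test_df = pv.stratified_split(self._events(), 0.3, seed=1)
        assert test_df["label"].value_counts().to_dict() == {
            "a": 30, "b": 30, "c": 30}
        assert len(train_df) + len(test_df) == 300

    def test_zero_fraction_gives_empty_test(self):
        train_df, test_df = pv.stratified_split(self._events(), 0.0, seed=1)
        assert test_df.empty and len(train_df) == 300

    def test_deterministic_given_seed(self):
        events = self._events()
        a = pv.stratified_split(events, 0.3, seed=5)
        b = pv.stratified_split(events, 0.3, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_single_event_class_rejected(self):
        events = self._events(n_per_class=1)
        with pytest.raises(ValidationError):
            pv.stratified_split(events, 0.3)


class TestGaussianBaseline:
    def test_widely_separated_classes_are_perfect(self):
        rng = np.random.default_rng(2)
        events = pd.concat([
            pd.DataFrame({"ires_pct": rng.normal(98, 0.05, 200),
                          "duration_s": rng.exponential(0.1, 200),
                          "rms_noise_pa": np.abs(rng.normal(1, 0.1, 200)),
                          "label": "x"}),
            pd.DataFrame({"ires_pct": rng.normal(95, 0.05, 200),
                          "duration_s": rng.exponential(0.1, 200),
                          "rms_noise_pa": np.abs(rng.normal(1, 0.1, 200)),
                          "label": "y"}),
        ], ignore_index=True)
        train_df, test_df = pv.stratified_split(events, 0.3, seed=3)
        model = train(train_df, kind="gaussian")
        assert pv.evaluate(model, test_df).accuracy == 1.0

    def test_matches_brute_force_density_oracle(self, seven_class_events):
        sub = seven_class_events.sample(100, random_state=4)
        model = train(seven_class_events, kind="gaussian")
        est = model.estimator
        X = feature_matrix(sub)
        # oracle: independent per-class Gaussian densities, argmax
        dens = np.column_stack([
            multivariate_normal(mean=est.means_[k],
                                cov=est.covariances_[k]).logpdf(X)
            for k in range(len(est.classes_))])
        oracle = est.classes_[np.argmax(dens, axis=1)]
        assert np.array_equal(model.predict(sub), oracle)

    def test_affine_feature_rescaling_invariance(self, seven_class_events):
        X = feature_matrix(seven_class_events)
        y = seven_class_events["label"].to_numpy()
        base = GaussianEventClassifier().fit(X, y).predict(X)
        X2 = X.copy()
        X2[:, 0] = 7.0 * X2[:, 0] - 300.0
        scaled = GaussianEventClassifier().fit(X2, y).predict(X2)
        assert (base == scaled).mean() > 0.999

    def test_feature_order_permutation_invariance(self, seven_class_events):
        X = feature_matrix(seven_class_events)
        y = seven_class_events["label"].to_numpy()
        base = GaussianEventClassifier().fit(X, y).predict(X)
        perm = X[:, [2, 0, 1]]
        permuted = GaussianEventClassifier().fit(perm, y).predict(perm)
        assert np.array_equal(base, permuted)

    def test_permuted_labels_fall_to_chance(self, seven_class_events):
        rng = np.random.default_rng(6)
        shuffled = seven_class_events.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        train_df, test_df = pv.stratified_split(shuffled, 0.3, seed=6)
        model = train(train_df, kind="gaussian")
        acc = pv.evaluate(model, test_df).accuracy
        assert acc < 0.3  # chance level is 1/7


class TestSevenAldehydeTask:
    def test_accuracy_high_for_both_kinds(self, seven_class_events):
        train_df, test_df = pv.stratified_split(seven_class_events, 0.3,
                                                seed=7)
        for kind in ("gaussian", "forest"):
            model = train(train_df, kind=kind, seed=7,
                          **({"n_estimators": 100} if kind == "forest"
                             else {}))
            assert pv.evaluate(model, test_df).accuracy >= 0.95

    def test_chain_isomers_confound_reference_pore(self, ag,
                                                   seven_class_events):
        # butanal vs 2-methylpropanal differ by only ~0.2% in level:
        # accuracy drops well below the straight-chain series task
        pair = pv.sample_labeled_events(
            [ag.analyte("butanal"), ag.analyte("2-methylpropanal")],
            1000, ag.pore, seed=8)
        tr_p, te_p = pv.stratified_split(pair, 0.3, seed=8)
        pair_acc = pv.evaluate(train(tr_p, kind="gaussian"), te_p).accuracy

        tr7, te7 = pv.stratified_split(seven_class_events, 0.3, seed=8)
        seven_acc = pv.evaluate(train(tr7, kind="gaussian"), te7).accuracy
        assert pair_acc < 0.99  # ~0.2% level gap vs ~0.05% spread
        assert pair_acc < seven_acc

    def test_accuracy_monotone_in_level_separation(self, ag):
        from porevoc.analytes import AnalyteSpec, DiastereomerSpec

        def accuracy(delta, seed):
            a = AnalyteSpec("a", 0.0, 1.0,
                            (DiastereomerSpec("A", 97.0 + delta, 7.0),))
            b = AnalyteSpec("b", 0.0, 1.0,
                            (DiastereomerSpec("A", 97.0, 7.0),))
            events = pv.sample_labeled_events([a, b], 200, ag.pore, seed=seed)
            tr, te = pv.stratified_split(events, 0.3, seed=seed)
            return pv.evaluate(train(tr, kind="gaussian"), te).accuracy

        deltas = (0.05, 0.2, 0.8)
        means = [np.mean([accuracy(d, s) for s in range(5)]) for d in deltas]
        assert means[0] <= means[1] + 0.01
        assert means[1] <= means[2] + 0.01


class TestModelPersistence:
    def test_gaussian_json_roundtrip(self, seven_class_events, tmp_path):
        model = train(seven_class_events, kind="gaussian")
        path = tmp_path / "model.json"
        model.save(path)
        back = pv.ClassifierModel.load(path)
        assert np.array_equal(back.predict(seven_class_events),
                              model.predict(seven_class_events))

    def test_forest_sidecar_roundtrip(self, seven_class_events, tmp_path):
        model = train(seven_class_events, kind="forest", seed=9,
                      n_estimators=50)
        path = tmp_path / "model.json"
        model.save(path)
        back = pv.ClassifierModel.load(path)
        assert np.array_equal(back.predict(seven_class_events),
                              model.predict(seven_class_events))


class TestEvaluate:
    def test_empty_test_set_defined(self, seven_class_events):
        model = train(seven_class_events, kind="gaussian")
        cm = pv.evaluate(model, seven_class_events.iloc[0:0])
        assert np.isnan(cm.accuracy)
        assert (cm.counts.to_numpy() == 0).all()

    def test_unseen_class_rejected(self, seven_class_events, ag):
        model = train(seven_class_events, kind="gaussian")
        alien = pv.sample_labeled_events([ag.analyte("benzaldehyde")], 10,
                                         ag.pore, seed=10)
        with pytest.raises(ValidationError):
            pv.evaluate(model, alien)

    def test_row_sums_match_class_counts(self, seven_class_events):
        tr, te = pv.stratified_split(seven_class_events, 0.3, seed=11)
        model = train(tr, kind="gaussian")
        cm = pv.evaluate(model, te)
        expected = te["label"].value_counts()
        for cls in cm.counts.index:
            assert cm.counts.loc[cls].sum() == expected[cls]

    def test_flagged_events_rejected_from_features(self):
        df = pd.DataFrame({"ires_pct": [97.0, np.nan],
                           "duration_s": [0.1, 0.1],
                           "rms_noise_pa": [1.0, 1.0]})
        with pytest.raises(ValidationError):
            feature_matrix(df)
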