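"""ARD sparse logistic decoder against brute-force and sklearn oracles."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from awakerest import decoder as dec
from awakerest.preprocess import SampleMatrix


def _samples(X, y=None, run_ids=None, voxel_ids=None):
    n = X.shape[0]
    return SampleMatrix(
        data=X,
        labels=None if y is None else np.asarray(y),
        run_ids=np.arange(n) % 10 if run_ids is None else np.asarray(run_ids),
        voxel_ids=np.arange(X.shape[1]) if voxel_ids is None else np.asarray(voxel_ids),
    )


def _toy(n_per_class=10, noise=0.1, seed=0, n_noise_vox=1):
    """Separable 2-class toy: class A at (+1, 0...), class B at (-1, 0...)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, noise, size=(2 * n_per_class, 1 + n_noise_vox))
    X[:n_per_class, 0] += 1.0
    X[n_per_class:, 0] -= 1.0
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return _samples(X, y, run_ids=np.arange(2 * n_per_class) % 5)


class TestFit:
    def test_separable_toy_keeps_informative_prunes_noise(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = dec.fit(_toy())
        assert 0 in model.retained_index
        assert 1 not in model.retained_index
        assert model.weights[1] == 0.0

    def test_separable_toy_training_accuracy_perfect(self):
        toy = _toy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = dec.fit(toy)
        p = dec.predict_proba(model, toy)[:, 1]
        pred = np.where(p >= 0.5, model.class_labels[1], model.class_labels[0])
        assert np.mean(pred == toy.labels) == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            dec.fit(_samples(X, ["A"] * 10))

    def test_deterministic_without_seed(self, decoder_dataset):
        m1 = dec.fit(decoder_dataset["samples"])
        m2 = dec.fit(decoder_dataset["samples"])
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.bias == m2.bias

    def test_duplicating_samples_preserves_decision_function(self):
        toy = _toy(noise=0.5, seed=3)
        dup = _samples(
            np.vstack([toy.data, toy.data]),
            np.concatenate([toy.labels, toy.labels]),
            run_ids=np.concatenate([toy.run_ids, toy.run_ids]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1, m2 = dec.fit(toy), dec.fit(dup)
        grid = _samples(np.random.default_rng(1).standard_normal((50, 2)))
        p1 = dec.predict_proba(m1, grid)[:, 1]
        p2 = dec.predict_proba(m2, grid)[:, 1]
        assert np.mean((p1 >= 0.5) == (p2 >= 0.5)) == 1.0


class TestPredictProba:
    def test_zero_input_zero_bias_gives_half(self):
        model = dec.ARDLogisticModel(
            weights=np.array([0.7, -0.2]),
            bias=0.0,
            relevance=np.ones(2),
            retained_index=np.arange(2),
            voxel_ids=np.arange(2),
            class_labels=("B", "A"),
            n_iterations=1,
            converged=True,
        )
        p = dec.predict_proba(model, _samples(np.zeros((1, 2))))
        assert p[0, 0] == pytest.approx(0.5)
        assert p.sum(axis=1) == pytest.approx(1.0)

    def test_saturation_for_large_scores(self):
        model = dec.ARDLogisticModel(
            weights=np.array([1.0]),
            bias=0.0,
            relevance=np.ones(1),
            retained_index=np.arange(1),
            voxel_ids=np.arange(1),
            class_labels=("B", "A"),
            n_iterations=1,
            converged=True,
        )
        p = dec.predict_proba(model, _samples(np.array([[50.0], [-50.0]])))
        assert p[0, 1] > 1 - 1e-12
        assert p[1, 1] < 1e-12

    def test_probabilities_match_dot_product_recomputation(self, fitted_model, decoder_dataset):
        samples = decoder_dataset["samples"]
        p = dec.predict_proba(fitted_model, samples)
        z = samples.data @ fitted_model.weights + fitted_model.bias
        np.testing.assert_allclose(p[:, 1], 1.0 / (1.0 + np.exp(-z)), atol=1e-12)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_voxel_mismatch_rejected(self, fitted_model):
        bad = _samples(np.zeros((2, 3)), voxel_ids=np.array([100, 101, 102]))
        with pytest.raises(ValueError, match="voxel"):
            dec.predict_proba(fitted_model, bad)


class TestAgreementWithRegularizedLogisticOracle:
    def test_agreement_on_well_separated_data(self):
        rng = np.random.default_rng(7)
        agree = []
        for seed in range(5):
            train = _toy(n_per_class=20, noise=0.4, seed=seed, n_noise_vox=3)
            test = _toy(n_per_class=50, noise=0.4, seed=100 + seed, n_noise_vox=3)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = dec.fit(train)
            positive = model.class_labels[1]
            ours = dec.predict_proba(model, test)[:, 1] >= 0.5
            clf = LogisticRegression(C=1.0).fit(train.data, train.labels == positive)
            theirs = clf.predict_proba(test.data)[:, 1] >= 0.5
            agree.append(np.mean(ours == theirs))
        assert np.mean(agree) >= 0.95


class TestSparsityEnrichment:
    def test_retained_voxels_enriched_for_informative(self):
        """With few informative voxels planted among many, the retained set
        is enriched (hypergeometric p < 0.01 per seed)."""
        from awakerest import preprocess as pp
        from awakerest import synthetic as syn

        design = syn.DecoderScanDesign()
        pvals = []
        for seed in range(8):
            tuning = syn.make_tuning(40, 6, 0.5, seed=seed)
            runs, labels = syn.generate_decoder_scan(design, tuning, seed=seed + 50)
            samples, _ = pp.preprocess_decoder_runs(runs, labels, design)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = dec.fit(samples)
            informative = set(np.flatnonzero(tuning.beta != 0.0).tolist())
            retained = set(model.retained_index.tolist())
            k = len(informative & retained)
            p = sps.hypergeom.sf(k - 1, 40, len(informative), len(retained))
            pvals.append(p)
        assert all(p < 0.01 for p in pvals)


class TestCrossValidation:
    def test_ten_folds_under_default_design(self, decoder_dataset):
        cv = dec.cross_validate_loro(decoder_dataset["samples"])
        assert cv.n_folds == 10
        assert cv.mean_accuracy > 0.6  # genuine signal present

    def test_strong_signal_high_accuracy(self):
        from awakerest import preprocess as pp
        from awakerest import synthetic as syn

        design = syn.DecoderScanDesign()
        tuning = syn.make_tuning(24, 12, 0.8, seed=5)
        runs, labels = syn.generate_decoder_scan(design, tuning, seed=6)
        samples, _ = pp.preprocess_decoder_runs(runs, labels, design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cv = dec.cross_validate_loro(samples)
        assert cv.mean_accuracy > 0.9

    def test_permuted_labels_give_chance_accuracy(self, decoder_dataset):
        samples = decoder_dataset["samples"]
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(3):
            perm = SampleMatrix(
                data=samples.data,
                labels=rng.permutation(samples.labels),
                run_ids=samples.run_ids,
                voxel_ids=samples.voxel_ids,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                accs.append(dec.cross_validate_loro(perm).mean_accuracy)
        # binomial 99% band around 0.5 for 3 x 180 test decisions
        assert abs(np.mean(accs) - 0.5) < 2.58 * 0.5 / np.sqrt(3 * 180)

    def test_two_runs_minimum(self):
        X = np.random.default_rng(0).standard_normal((8, 2))
        s = _samples(X, ["A", "B"] * 4, run_ids=np.zeros(8, dtype=int))
        with pytest.raises(ValueError, match="2 runs"):
            dec.cross_validate_loro(s)


class TestCombineRois:
    def test_concatenation_counts(self):
        rng = np.random.default_rng(0)
        y = ["A", "B"] * 5
        rois = [
            _samples(rng.standard_normal((10, n)), y, voxel_ids=np.arange(n) + off)
            for n, off in ((100, 0), (80, 1000), (60, 2000))
        ]
        combined = dec.combine_rois(rois)
        assert combined.n_voxels == 240

    def test_single_roi_is_identity(self):
        s = _toy()
        out = dec.combine_rois([s])
        np.testing.assert_array_equal(out.data, s.data)

    def test_duplicate_voxel_ids_rejected(self):
        s = _toy()
        with pytest.raises(ValueError, match="duplicate"):
            dec.combine_rois([s, s])

    def test_sample_axis_mismatch_rejected(self):
        a = _toy(n_per_class=10)
        b = _toy(n_per_class=8)
        with pytest.raises(ValueError, match="sample axis"):
            dec.combine_rois([a, b])

    def test_combined_roi_decodes_at_least_as_well_as_best_single(self):
        from awakerest import preprocess as pp
        from awakerest import synthetic as syn
        from awakerest import workflow as wf

        design = syn.DecoderScanDesign()
        tunings = {r: syn.make_tuning(16, 8, 0.5, seed=i) for i, r in enumerate("ABC")}
        full = syn.TuningMap(
            beta_a=np.concatenate([tunings[r].beta_a for r in "ABC"]),
            beta_b=np.concatenate([tunings[r].beta_b for r in "ABC"]),
        )
        runs, labels = syn.generate_decoder_scan(design, full, seed=9)
        samples, _ = pp.preprocess_decoder_runs(runs, labels, design)
        accs = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for i, r in enumerate("ABC"):
                sub = wf._subset(samples, 16 * i, 16 * (i + 1))
                accs[r] = dec.cross_validate_loro(sub).mean_accuracy
            accs["combined"] = dec.cross_validate_loro(samples).mean_accuracy
        best_single = max(v for k, v in accs.items() if k != "combined")
        assert accs["combined"] >= best_single - 0.05
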