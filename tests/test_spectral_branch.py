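"""Spectral network, hidden-feature extraction, baselines, node sweep."""

import numpy as np
import pytest

from pearfuse.spectral_branch import (
    BASELINE_PRESETS, MLPConfig, PLSDAClassifier, extract_spectral_features,
    run_node_sweep, train_baseline, train_spectral_mlp,
)


class TestSpectralMLP:
    def test_separable_toy_data_fit_perfectly(self, separable_spectra):
        X, y = separable_spectra
        model = train_spectral_mlp((X, y), MLPConfig(n_hidden=10, seed=0,
                                                     early_stopping=False))
        assert np.mean(model.predict(X) == y) == 1.0

    def test_feature_length_equals_hidden_width(self, separable_spectra):
        X, y = separable_spectra
        model = train_spectral_mlp((X, y), MLPConfig(n_hidden=30, seed=0,
                                                     early_stopping=False))
        F = extract_spectral_features(model, X)
        assert F.shape == (len(X), 30)

    def test_features_non_negative_and_deterministic(self, separable_spectra):
        X, y = separable_spectra
        model = train_spectral_mlp((X, y), MLPConfig(n_hidden=15, seed=1,
                                                     early_stopping=False))
        F1 = extract_spectral_features(model, X)
        F2 = extract_spectral_features(model, X)
        assert np.all(F1 >= 0.0)
        assert np.array_equal(F1, F2)

    def test_zero_input_zero_bias_gives_zero_features(self, separable_spectra):
        X, y = separable_spectra
        model = train_spectral_mlp((X, y), MLPConfig(n_hidden=5, seed=0,
                                                     early_stopping=False))
        model._clf.intercepts_[0][:] = 0.0
        F = extract_spectral_features(model, np.zeros((1, 2)))
        assert np.array_equal(F, np.zeros((1, 5)))

    def test_training_seed_determinism(self, separable_spectra):
        X, y = separable_spectra
        cfg = MLPConfig(n_hidden=12, seed=3, early_stopping=False)
        a = train_spectral_mlp((X, y), cfg)
        b = train_spectral_mlp((X, y), cfg)
        assert np.array_equal(a._clf.coefs_[0], b._clf.coefs_[0])

    def test_grid_mismatch_rejected(self, separable_spectra):
        X, y = separable_spectra
        model = train_spectral_mlp((X, y), MLPConfig(n_hidden=5, seed=0,
                                                     early_stopping=False))
        with pytest.raises(ValueError, match="grid mismatch"):
            model.predict(np.zeros((1, 3)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_spectral_mlp((np.zeros((5, 2)), np.zeros(5, int)),
                               MLPConfig(n_hidden=5))

    def test_invalid_hidden_width_rejected(self):
        with pytest.raises(ValueError, match="n_hidden"):
            MLPConfig(n_hidden=0)


class TestNodeSweep:
    def test_full_grid_has_ten_rows(self, separable_spectra):
        X, y = separable_spectra
        cfg = MLPConfig(max_epochs=30, early_stopping=False)
        df = run_node_sweep((X, y), (X, y), base_config=cfg)
        assert len(df) == 10
        assert list(df["n_hidden"]) == list(range(10, 101, 10))
        assert df["best"].sum() == 1

    def test_single_cell_grid(self, separable_spectra):
        X, y = separable_spectra
        df = run_node_sweep((X, y), (X, y), grid=(30,),
                            base_config=MLPConfig(max_epochs=30,
                                                  early_stopping=False))
        assert len(df) == 1 and bool(df["best"].iloc[0])

    def test_best_at_least_median(self, tiny_split):
        tr, va = tiny_split
        df = run_node_sweep((tr.spectra, tr.y), (va.spectra, va.y),
                            grid=(10, 30, 50),
                            base_config=MLPConfig(max_epochs=60,
                                                  early_stopping=False))
        best = df.loc[df["best"], "accuracy"].iloc[0]
        assert best >= df["accuracy"].median()

    def test_empty_grid_rejected(self, separable_spectra):
        X, y = separable_spectra
        with pytest.raises(ValueError, match="non-empty"):
            run_node_sweep((X, y), (X, y), grid=())


class TestBaselines:
    def test_presets_match_published_tuning_table(self):
        assert BASELINE_PRESETS["PLS-DA"].hyperparameters == {"n_components": 8}
        assert BASELINE_PRESETS["SVM"].hyperparameters == {
            "C": 601, "gamma": 0.15, "kernel": "poly"}
        assert BASELINE_PRESETS["random-forest"].hyperparameters == {
            "max_depth": 20, "n_estimators": 15, "min_samples_split": 3}
        # the boosting presets are printed identically in the source table
        assert (BASELINE_PRESETS["AdaBoost"].hyperparameters
                == BASELINE_PRESETS["XGBoost"].hyperparameters
                == {"n_estimators": 50, "learning_rate": 1.0})

    @pytest.mark.parametrize("family", list(BASELINE_PRESETS))
    def test_each_family_fits_separable_toy_data(self, family, separable_spectra):
        X, y = separable_spectra
        if family == "PLS-DA":
            model = train_baseline((X, y), "PLS-DA") if X.shape[1] >= 8 else \
                PLSDAClassifier(n_components=2).fit(X, y)
        else:
            model = train_baseline((X, y), family, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_plsda_rank_guard(self, separable_spectra):
        X, y = separable_spectra
        with pytest.raises(ValueError, match="exceeds data rank"):
            PLSDAClassifier(n_components=8).fit(X, y)

    def test_baselines_run_on_spectra(self, tiny_split):
        tr, va = tiny_split
        model = train_baseline((tr.spectra, tr.y), "random-forest", seed=0)
        pred = model.predict(va.spectra)
        assert pred.shape == va.y.shape
        assert set(np.unique(pred)) <= {0, 1}


class TestNullSimulation:
    def test_uninformative_spectra_stay_near_chance(self):
        """Classifiers on label-free spectra score near 0.5 (3-seed median)."""
        from pearfuse.acquisition import split_indices
        from pearfuse.synthetic_data import SyntheticConfig, generate_paired_dataset

        accs = {name: [] for name in ("MLP", "PLS-DA", "SVM", "random-forest",
                                      "AdaBoost", "XGBoost")}
        for seed in range(3):
            cfg = SyntheticConfig(n_per_class=50, image_size_px=16,
                                  seed=seed).null()
            ds = generate_paired_dataset(cfg)
            tr_i, va_i = split_indices(ds.labels, 0.7, seed)
            tr, va = ds.subset(tr_i), ds.subset(va_i)
            mlp = train_spectral_mlp((tr.spectra, tr.y),
                                     MLPConfig(n_hidden=30, seed=seed,
                                               max_epochs=60,
                                               early_stopping=False))
            accs["MLP"].append(np.mean(mlp.predict(va.spectra) == va.y))
            for name in BASELINE_PRESETS:
                model = train_baseline((tr.spectra, tr.y), name, seed=seed)
                accs[name].append(np.mean(model.predict(va.spectra) == va.y))
        for name, vals in accs.items():
            assert 0.35 <= float(np.median(vals)) <= 0.65, (name, vals)
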