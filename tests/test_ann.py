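"""Autoencoder augmentation and MLP predictor behavior."""

import numpy as np
import pandas as pd
import pytest

from medopt.ann import (
    AugmentationConfig,
    AutoencoderConfig,
    FeedForwardNet,
    NormalizationSpec,
    PredictorConfig,
    augment,
    cross_validate_predictor,
    evaluate,
    rescale,
    search_autoencoder,
    train_autoencoder,
    train_predictor,
    validate_on_original,
)
from medopt import reference as ref
from medopt.errors import RangeError, ValidationError

# small, fast schedule for structural tests (full schedule is exercised by
# the end-to-end pipeline fixture in test_acceptance)
FAST_AE = dict(max_epochs=8000, patience=1000)


class TestRescale:
    def test_published_normalization_ranges(self):
        df = pd.DataFrame(
            {"cellulose": [50.0, 0.0, 25.0], "SA2BSS": [25.0, 10.0, 40.0]}
        )
        unit = rescale(df, ref.NORMALIZATION, "to_unit")
        assert unit["cellulose"].tolist() == [1.0, 0.0, 0.5]
        assert unit["SA2BSS"].iloc[0] == pytest.approx(0.5)  # (25-10)/30
        assert unit["SA2BSS"].iloc[1] == 0.0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "urea": rng.uniform(0, 10, 20),
                "PA2DSS": rng.uniform(10, 40, 20),
            }
        )
        back = rescale(rescale(df, ref.NORMALIZATION, "to_unit"), ref.NORMALIZATION, "to_original")
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_out_of_range_names_attribute(self):
        df = pd.DataFrame({"urea": [11.0]})
        with pytest.raises(RangeError, match="urea"):
            rescale(df, ref.NORMALIZATION, "to_unit")

    def test_bad_spec_rejected(self):
        with pytest.raises(ValidationError):
            NormalizationSpec({"x": (5.0, 5.0)})


class TestAutoencoder:
    def test_affine_manifold_reconstruction(self, rank4_manifold):
        """A 4-dim affine manifold in 6-dim space is representable at
        embedding width 4: reconstruction R^2 >= 0.97."""
        cfg = AutoencoderConfig(seed=1, **FAST_AE)
        _, _, report = train_autoencoder(rank4_manifold, cfg)
        assert report["reconstruction_r2"] >= 0.97

    def test_reconstruction_not_worse_than_mean_predictor(self, rank4_manifold):
        cfg = AutoencoderConfig(seed=2, max_epochs=500, patience=200)
        _, _, report = train_autoencoder(rank4_manifold, cfg)
        assert report["reconstruction_mse"] <= rank4_manifold.var() + 1e-9

    def test_decoder_output_in_unit_interval(self, rank4_manifold):
        cfg = AutoencoderConfig(seed=3, max_epochs=200, patience=100)
        _, decoder, _ = train_autoencoder(rank4_manifold, cfg)
        wild = np.random.default_rng(0).uniform(-5, 5, size=(100, 4))
        out = decoder.predict(wild)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_fixed_seed_bit_stable(self, rank4_manifold):
        cfg = AutoencoderConfig(seed=4, max_epochs=300, patience=100)
        _, _, r1 = train_autoencoder(rank4_manifold[:100], cfg)
        _, _, r2 = train_autoencoder(rank4_manifold[:100], cfg)
        assert r1["reconstruction_mse"] == r2["reconstruction_mse"]

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValidationError):
            train_autoencoder(np.full((10, 3), 2.0), AutoencoderConfig(seed=0))


class TestSearchAutoencoder:
    def test_singleton_grid_returned(self, rank4_manifold):
        cfg = AutoencoderConfig(encoder_hidden=(6,), decoder_hidden=(6,), max_epochs=200, patience=100)
        best, table = search_autoencoder(rank4_manifold[:100], [cfg], seed=0)
        assert best.encoder_hidden == (6,)
        assert len(table) == 1

    def test_selection_prefers_better_reconstruction_and_is_deterministic(
        self, rank4_manifold
    ):
        """A crippled 1-neuron bottleneck loses to the width-4 embedding."""
        grid = [
            AutoencoderConfig(encoder_hidden=(6,), decoder_hidden=(6,), embedding_dim=1,
                              max_epochs=2000, patience=400),
            AutoencoderConfig(encoder_hidden=(6,), decoder_hidden=(6,), embedding_dim=4,
                              max_epochs=2000, patience=400),
        ]
        best1, table = search_autoencoder(rank4_manifold[:200], grid, seed=1)
        assert best1.embedding_dim == 4
        best2, _ = search_autoencoder(rank4_manifold[:200], grid, seed=1)
        assert best2 == best1

    def test_empty_grid_rejected(self, rank4_manifold):
        with pytest.raises(ValidationError):
            search_autoencoder(rank4_manifold, [], seed=0)


@pytest.fixture(scope="module")
def decoder(rank4_manifold):
    cfg = AutoencoderConfig(seed=5, max_epochs=500, patience=200)
    _, dec, _ = train_autoencoder(rank4_manifold, cfg)
    return dec


class TestAugment:
    def test_default_interval_and_exact_row_count(self, decoder):
        cfg = AugmentationConfig(seed=0)
        assert cfg.interval == (-1.0, 2.5)
        assert cfg.n_samples == 10_000
        aug = augment(decoder, cfg)
        assert len(aug.data) == 10_000
        vals = aug.data.to_numpy()
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0)

    def test_seed_reproducibility(self, decoder):
        a = augment(decoder, AugmentationConfig(n_samples=50, seed=7))
        b = augment(decoder, AugmentationConfig(n_samples=50, seed=7))
        c = augment(decoder, AugmentationConfig(n_samples=50, seed=8))
        assert a.data.equals(b.data)
        assert not a.data.equals(c.data)

    def test_augmented_means_match_decoder_image(self, decoder):
        """Means of a large augmentation agree with independent replicates
        within 3 sampling standard errors."""
        big = augment(decoder, AugmentationConfig(n_samples=4000, seed=1))
        reps = [
            augment(decoder, AugmentationConfig(n_samples=4000, seed=100 + i)).data.mean()
            for i in range(3)
        ]
        ref_mean = pd.concat(reps, axis=1).mean(axis=1)
        se = big.data.std() / np.sqrt(len(big.data))
        assert ((big.data.mean() - ref_mean).abs() <= 3 * se + 1e-3).all()

    def test_bad_sample_count_rejected(self):
        with pytest.raises(ValidationError):
            AugmentationConfig(n_samples=0)


@pytest.fixture(scope="module")
def toy_data():
    """Smooth nonlinear surface on the unit cube."""
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 1, size=(2000, 4))
    y = 0.3 + 0.3 * X[:, 0] - 0.2 * X[:, 1] ** 2 + 0.1 * X[:, 2] * X[:, 3]
    return X, y


class TestPredictor:
    def test_exactly_three_hidden_layers(self, toy_data):
        X, y = toy_data
        cfg = PredictorConfig(hidden_width=5, max_epochs=5, seed=0)
        net, _ = train_predictor(X, y, cfg)
        assert net.sizes == [4, 5, 5, 5, 1]
        assert net.activations == ["elu", "elu", "elu", "sigmoid"]

    def test_learns_smooth_surface(self, toy_data):
        X, y = toy_data
        net, report = train_predictor(X, y, PredictorConfig(max_epochs=150, seed=1))
        assert report["train_r2"] > 0.95

    def test_constant_target_degenerate_case(self, toy_data):
        X, _ = toy_data
        y = np.full(len(X), 0.4)
        net, report = train_predictor(X[:500], y[:500], PredictorConfig(max_epochs=800, seed=2))
        assert report["train_mse"] <= np.var(y[:500]) + 1e-6

    def test_l2_monotonicity(self, toy_data):
        """Raising the l2 coefficient from 0.01 to 1.0 cannot reduce the
        training MSE of the converged fit."""
        X, y = toy_data
        from dataclasses import replace

        base = PredictorConfig(max_epochs=120, seed=3)
        _, weak = train_predictor(X, y, base)
        _, strong = train_predictor(X, y, replace(base, l2=1.0))
        assert strong["train_mse"] >= weak["train_mse"] - 1e-9

    def test_perfect_and_mean_oracle_r2(self, toy_data):
        X, y = toy_data

        class Oracle:
            def predict(self, Z):
                return (0.3 + 0.3 * Z[:, 0] - 0.2 * Z[:, 1] ** 2 + 0.1 * Z[:, 2] * Z[:, 3])[:, None]

        class Mean:
            def predict(self, Z):
                return np.full((len(Z), 1), y.mean())

        _, r2 = validate_on_original(Oracle(), X, y)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        _, r2m = validate_on_original(Mean(), X, y)
        assert r2m == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def small_data():
    rng = np.random.default_rng(5)
    X = rng.uniform(0, 1, size=(300, 4))
    y = 0.4 + 0.2 * X[:, 0] - 0.15 * X[:, 1]
    return X, y


class TestCrossValidation:
    def test_folds_partition_rows(self, small_data):
        from sklearn.model_selection import KFold

        X, _ = small_data
        splits = list(KFold(5, shuffle=True, random_state=0).split(X))
        all_val = np.concatenate([va for _, va in splits])
        assert sorted(all_val) == list(range(len(X)))

    def test_singleton_grid_returns_it_with_fold_records(self, small_data):
        X, y = small_data
        cfg = PredictorConfig(hidden_width=4, max_epochs=30, seed=0)
        best, table = cross_validate_predictor(X, y, [cfg], folds=5, seed=1)
        assert best.hidden_width == 4
        assert len(table) == 5
        assert sorted(table["fold"]) == list(range(5))

    def test_sabotaged_config_loses(self, small_data):
        """A 30x learning rate burns the fit; CV must not select it."""
        X, y = small_data
        good = PredictorConfig(hidden_width=6, max_epochs=60, seed=0)
        bad = PredictorConfig(hidden_width=6, learning_rate=0.09, lr_decay=1.0,
                              optimizer="momentum", max_epochs=60, seed=0)
        best, table = cross_validate_predictor(X, y, [good, bad], folds=5, seed=2)
        assert best == good
        means = table.groupby("grid_index")["val_mse"].mean()
        assert means[0] <= means[1]

    def test_bad_folds_rejected(self, small_data):
        X, y = small_data
        with pytest.raises(ValidationError):
            cross_validate_predictor(X, y, [PredictorConfig()], folds=1, seed=0)


def test_divergence_raises_helpful_error(rank4_manifold):
    cfg = AutoencoderConfig(learning_rate=0.03, seed=0, max_epochs=200, patience=100)
    from medopt.ann import _train_net

    rng = np.random.default_rng(0)
    net = FeedForwardNet([6, 4, 6], ["identity", "identity"], rng)
    from medopt.errors import DivergenceError

    with pytest.raises(DivergenceError, match="learning rate"):
        _train_net(
            net,
            rank4_manifold,
            rank4_manifold,
            learning_rate=1e4,
            lr_decay=1.0,
            max_epochs=200,
            rng=rng,
        )
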