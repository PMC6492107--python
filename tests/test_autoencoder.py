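"""Network construction, the XCov cost, training mechanics and model selection."""

import numpy as np
import pytest

from normdae import (
    ModelConfig,
    build_model,
    covariate_performance,
    default_cohort_spec,
    encode_labels,
    generate_cohort,
    reconstruct,
    train,
    xcov_cost,
)
from normdae.io_tables import LabelCoding, apply_normalization, fit_normalization
from normdae.normative_autoencoder import _Adam, candidate_grid, select_architecture

from conftest import make_mini_table


def tiny_config(**kw):
    base = dict(input_dim=7, h1_units=6, z_units=4, h2_units=5,
                n_age_classes=3, n_sex_classes=2, epochs=2, batch_size=4,
                seed=3)
    base.update(kw)
    return ModelConfig(**base)


class TestBuild:
    def test_decoder_input_width_is_z_plus_heads(self):
        net = build_model(ModelConfig())
        assert net.params["W2"].shape[0] == 75 + 16 + 2

    def test_layer_widths_follow_config(self):
        net = build_model(ModelConfig(h1_units=100, z_units=75, h2_units=100))
        assert net.params["W1"].shape == (104, 100)
        assert net.params["Wz"].shape == (100, 75)
        assert net.params["W2"].shape == (93, 100)
        assert net.params["Wo"].shape == (100, 104)

    def test_same_seed_identical_initial_weights(self):
        a = build_model(ModelConfig(seed=7))
        b = build_model(ModelConfig(seed=7))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_bottleneck_invariant_enforced(self):
        with pytest.raises(ValueError, match="z_units"):
            ModelConfig(h1_units=50, z_units=50).validate()

    def test_lr_ordering_enforced(self):
        with pytest.raises(ValueError, match="lr_final"):
            ModelConfig(lr_initial=0.001, lr_final=0.01).validate()


class TestXCov:
    def test_constant_z_gives_zero(self):
        z = np.ones((10, 4))
        y = np.random.default_rng(0).random((10, 5))
        assert xcov_cost(z, y) == 0.0

    def test_single_matching_column_half_v_squared(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(30)
        v = col.var()  # population variance of the batch
        assert xcov_cost(col[:, None], col[:, None]) == pytest.approx(
            0.5 * v ** 2, rel=1e-12)

    def test_matches_double_loop_definition(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            z = rng.standard_normal((20, 5))
            y = rng.standard_normal((20, 5))
            total = 0.0
            for i in range(5):
                for j in range(5):
                    cij = np.mean((z[:, i] - z[:, i].mean())
                                  * (y[:, j] - y[:, j].mean()))
                    total += cij ** 2
            assert xcov_cost(z, y) == pytest.approx(0.5 * total, abs=1e-10)

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((15, 4))
        y = rng.standard_normal((15, 3))
        perm = rng.permutation(15)
        assert xcov_cost(z[perm], y[perm]) == pytest.approx(
            xcov_cost(z, y), rel=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            xcov_cost(np.ones((1, 3)), np.ones((1, 2)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Backprop through SELU layers, softmax heads, XCov and L2."""
        cfg = tiny_config(l2_coefficient=1e-3, corruption_sd=0.0)
        net = build_model(cfg)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 7))
        y_age = np.eye(3)[rng.integers(0, 3, 8)]
        y_sex = np.eye(2)[rng.integers(0, 2, 8)]

        def objective():
            cache = net.forward(x)
            terms = net.loss_terms(cache, x, y_age, y_sex)
            return terms["total"] + terms["l2_penalty"]

        grads = net.gradients(net.forward(x), x, y_age, y_sex)
        eps = 1e-6
        for key, grad in grads.items():
            p = net.params[key]
            flat_indices = list(np.ndindex(*p.shape))[::5]
            for idx in flat_indices:
                orig = p[idx]
                p[idx] = orig + eps
                up = objective()
                p[idx] = orig - eps
                down = objective()
                p[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, abs=2e-6), key


class TestTraining:
    def test_lr_schedule_endpoints(self):
        cfg = ModelConfig(epochs=500)
        lrs = cfg.learning_rates()
        assert lrs[0] == pytest.approx(0.05)
        assert lrs[-1] == pytest.approx(0.0005, abs=1e-9)
        assert np.all(np.diff(lrs) < 0)

    def test_constant_dataset_learned_to_high_precision(self):
        """A constant table z-scores to all zeros, which the net must learn."""
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        table = make_mini_table(np.tile(base, (16, 1)), ages=[23] * 16)
        cfg = tiny_config(corruption_sd=0.0, epochs=200, batch_size=16,
                          l2_coefficient=0.0)
        trained = train(build_model(cfg), table)
        assert trained.history["recon_mse"].iloc[-1] < 1e-3

    def test_history_decomposes_into_terms(self, small_cohort):
        _, reference, _ = small_cohort
        cfg = ModelConfig(epochs=5, seed=1, loss_weights=(1.0, 0.5, 2.0, 1.5))
        trained = train(build_model(cfg), reference)
        h = trained.history
        assert len(h) == cfg.epochs
        recombined = (1.0 * h["recon_mse"] + 0.5 * h["ce_age"]
                      + 2.0 * h["ce_sex"] + 1.5 * h["xcov"])
        np.testing.assert_allclose(h["total_loss"], recombined, atol=1e-6)
        assert np.all(np.diff(h["lr"]) < 0)

    def test_training_history_fully_deterministic(self, small_cohort):
        _, reference, _ = small_cohort
        runs = []
        for _ in range(2):
            cfg = ModelConfig(epochs=4, seed=5)
            runs.append(train(build_model(cfg), reference).history)
        assert runs[0].equals(runs[1])

    def test_zero_corruption_trains_on_clean_input(self, small_cohort):
        """One full-batch step with corruption_sd=0 equals a manual Adam step
        on the uncorrupted batch — the denoising target is the input itself."""
        _, reference, _ = small_cohort
        table = reference.subset_rows(range(32))
        cfg = ModelConfig(epochs=1, batch_size=32, corruption_sd=0.0, seed=2)
        trained = train(build_model(cfg), table)

        net = build_model(cfg)  # manual replica of the single step
        norm = fit_normalization(table, source="reference")
        x = apply_normalization(table, norm)
        y_age, y_sex = encode_labels(table, LabelCoding())
        order = net.rng.permutation(32)
        cache = net.forward(x[order])
        grads = net.gradients(cache, x[order], y_age[order], y_sex[order])
        _Adam(net.params).step(net.params, grads, cfg.learning_rates()[0])
        for k in net.params:
            np.testing.assert_array_equal(trained.params[k], net.params[k])

    def test_holdout_error_tracked_and_training_fits_train_set(self, small_cohort):
        _, reference, _ = small_cohort
        hold = reference.subset_rows(range(40))
        tr_tab = reference.subset_rows(range(40, 200))
        cfg = ModelConfig(epochs=40, seed=0)
        trained = train(build_model(cfg), tr_tab, holdout=hold)
        assert "val_recon" in trained.history
        x = apply_normalization(tr_tab, trained.normalization)
        xhat, _, _, _ = reconstruct(trained, tr_tab)
        train_mse = np.mean((x - xhat) ** 2)
        assert train_mse <= trained.history["val_recon"].iloc[-1] * 1.05


class TestInference:
    def test_reconstruction_shapes_and_determinism(self, trained_small,
                                                   small_cohort):
        _, _, clinical = small_cohort
        out1 = reconstruct(trained_small, clinical)
        out2 = reconstruct(trained_small, clinical)
        assert out1[0].shape == (len(clinical), 104)
        assert out1[1].shape == (len(clinical), 16)
        assert out1[2].shape == (len(clinical), 2)
        assert out1[3].shape == (len(clinical), 75)
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a, b)

    def test_covariate_performance_recovers_strong_effects(
            self, trained_small, small_cohort):
        _, _, clinical = small_cohort
        mae, bacc = covariate_performance(trained_small, clinical)
        # synthetic age/sex effects are strong; both heads must beat chance
        assert mae < (37 - 22) / 3
        assert bacc > 0.7

    def test_chance_level_balanced_accuracy(self):
        """All-male predictions on a balanced sample give 50% by definition."""
        from sklearn.metrics import balanced_accuracy_score
        truth = ["M"] * 10 + ["F"] * 10
        assert balanced_accuracy_score(truth, ["M"] * 20) == 0.5


class TestArchitectureSelection:
    def test_candidate_combinatorics(self):
        assert candidate_grid((10, 25)) == [(25, 10)]
        assert len(candidate_grid((10, 25, 50, 75, 100))) == 10

    def test_empty_candidate_set_rejected(self, small_cohort):
        _, reference, _ = small_cohort
        with pytest.raises(ValueError, match="z < h1"):
            select_architecture(reference, unit_grid=(10,), k_folds=2)

    def test_returns_argmin_of_cv_table(self, small_cohort):
        _, reference, _ = small_cohort
        base = ModelConfig(epochs=3, seed=0)
        best, cv = select_architecture(reference, unit_grid=(4, 6, 8),
                                       k_folds=2, base_config=base)
        assert len(cv) == 3
        idx = cv["mean_val_recon"].idxmin()
        assert (best.h1_units, best.z_units) == (
            cv.loc[idx, "h1_units"], cv.loc[idx, "z_units"])
        assert best.h2_units == best.h1_units


class TestDisentanglement:
    def test_xcov_reduces_latent_age_correlation(self):
        """With the XCov penalty active, latent units decorrelate from age
        (checked across 5 seeds against an XCov-weight-0 ablation)."""
        spec = default_cohort_spec(seed=0, n_reference=300, n_controls=2,
                                   n_patients=2)
        reference, _ = generate_cohort(spec)

        def latent_age_corr(weights, seed):
            cfg = ModelConfig(h1_units=40, z_units=15, h2_units=40,
                              epochs=120, seed=seed, loss_weights=weights)
            trained = train(build_model(cfg), reference)
            _, _, _, z = reconstruct(trained, reference)
            ages = reference.ages
            cors = [abs(np.corrcoef(z[:, k], ages)[0, 1])
                    for k in range(z.shape[1]) if z[:, k].std() > 1e-12]
            return float(np.mean(cors))

        wins = sum(
            latent_age_corr((1, 1, 1, 1), seed)
            < latent_age_corr((1, 1, 1, 0), seed)
            for seed in range(5)
        )
        assert wins >= 4
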