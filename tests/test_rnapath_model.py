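import numpy as np
import pandas as pd
import pytest

import rnapath as rp
from rnapath.tile_bags import BagValidationError


class TestPreprocessExpression:
    def test_kept_gene_log_transformed(self):
        tpm = pd.DataFrame([[15.0, 15.0]], index=["g"], columns=["s0", "s1"])
        out = rp.preprocess_expression(tpm)
        assert np.allclose(out.to_numpy(), np.log2(16.0))

    def test_boundary_tpm_10_dropped(self):
        tpm = pd.DataFrame([[10.0, 10.0, 10.0]], index=["g"], columns=["s0", "s1", "s2"])
        assert rp.preprocess_expression(tpm).empty

    def test_kept_set_matches_counting_oracle(self, rng):
        tpm = pd.DataFrame(
            rng.uniform(0, 30, size=(100, 40)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(40)],
        )
        out = rp.preprocess_expression(tpm)
        need = int(np.ceil(0.05 * 40))
        expected = [g for g in tpm.index if (tpm.loc[g] > 10).sum() >= need]
        assert list(out.index) == expected

    def test_negative_tpm_rejected(self):
        tpm = pd.DataFrame([[-1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="non-negative"):
            rp.preprocess_expression(tpm)


class TestForwardPass:
    def test_zero_weights_clip_negative_bias(self):
        model = rp.RNAPathModel(W=np.zeros((3, 2)), b=np.array([2.0, -1.0]), gene_names=["a", "b"])
        scores = rp.predict_tiles(model, np.random.default_rng(0).standard_normal((5, 3)))
        assert np.array_equal(scores, np.tile([2.0, 0.0], (5, 1)))

    def test_zero_embedding_scores_relu_bias(self):
        model = rp.RNAPathModel(W=np.ones((3, 2)), b=np.array([0.5, -0.5]), gene_names=["a", "b"])
        assert np.array_equal(rp.predict_tiles(model, np.zeros((1, 3)))[0], [0.5, 0.0])

    def test_matches_elementwise_oracle(self, rng):
        model = rp.RNAPathModel(W=rng.standard_normal((6, 4)), b=rng.standard_normal(4),
                                gene_names=list("abcd"))
        X = rng.standard_normal((20, 6))
        scores = rp.predict_tiles(model, X)
        for p in range(20):
            for g in range(4):
                assert abs(scores[p, g] - max(0.0, X[p] @ model.W[:, g] + model.b[g])) < 1e-10

    def test_sample_prediction_is_exact_tile_mean(self, rng):
        model = rp.RNAPathModel(W=rng.standard_normal((6, 4)), b=rng.standard_normal(4),
                                gene_names=list("abcd"))
        X = rng.standard_normal((30, 6))
        assert np.max(np.abs(rp.predict_sample(model, X) - rp.predict_tiles(model, X).mean(axis=0))) < 1e-12

    def test_single_tile_and_duplication_invariance(self, rng):
        model = rp.RNAPathModel(W=rng.standard_normal((5, 3)), b=np.zeros(3), gene_names=list("abc"))
        X = rng.standard_normal((1, 5))
        assert np.allclose(rp.predict_sample(model, X), rp.predict_tiles(model, X)[0])
        X = rng.standard_normal((8, 5))
        assert np.allclose(rp.predict_sample(model, np.vstack([X, X])), rp.predict_sample(model, X), atol=1e-12)

    def test_permutation_equivariance_and_invariance(self, rng):
        model = rp.RNAPathModel(W=rng.standard_normal((5, 3)), b=rng.standard_normal(3),
                                gene_names=list("abc"))
        X = rng.standard_normal((12, 5))
        perm = rng.permutation(12)
        assert np.allclose(rp.predict_tiles(model, X[perm]), rp.predict_tiles(model, X)[perm],
                           atol=1e-12)
        assert np.allclose(rp.predict_sample(model, X[perm]), rp.predict_sample(model, X), atol=1e-12)

    def test_scores_nonnegative(self, rng):
        model = rp.RNAPathModel(W=rng.standard_normal((5, 3)), b=rng.standard_normal(3),
                                gene_names=list("abc"))
        assert (rp.predict_tiles(model, rng.standard_normal((50, 5))) >= 0).all()

    def test_dimension_mismatch(self):
        model = rp.RNAPathModel(W=np.zeros((4, 2)), b=np.zeros(2), gene_names=["a", "b"])
        with pytest.raises(BagValidationError):
            rp.predict_tiles(model, np.zeros((3, 5)))


class TestSplits:
    def test_donor_disjoint_and_fractions(self):
        donor_of = {f"s{i}": f"d{i // 2}" for i in range(100)}  # 50 donors x 2 samples
        splits = rp.split_by_donor(donor_of, (0.8, 0.1, 0.1), seed=3)
        donors = {k: {donor_of[s] for s in v} for k, v in splits.items()}
        assert not donors["train"] & donors["val"]
        assert not donors["train"] & donors["test"]
        assert not donors["val"] & donors["test"]
        assert len(donors["train"]) == 40 and len(donors["val"]) == 5

    def test_leaky_split_detected(self):
        donor_of = {"s0": "d0", "s1": "d0"}
        with pytest.raises(ValueError, match="d0"):
            rp.rnapath_model.assert_donor_disjoint({"train": ["s0"], "test": ["s1"]}, donor_of)


class TestTraining:
    def _constant_cohort(self, c=3.0, n=12, k=10, d=4, g=5, seed=0):
        rng = np.random.default_rng(seed)
        bags = {f"s{i}": rng.standard_normal((k, d)) for i in range(n)}
        expr = pd.DataFrame(np.full((g, n), c), index=[f"g{i}" for i in range(g)],
                            columns=list(bags))
        donor_of = {f"s{i}": f"d{i}" for i in range(n)}
        return bags, expr, donor_of

    def test_constant_target_fits_to_tolerance(self):
        bags, expr, donor_of = self._constant_cohort(c=3.0)
        config = rp.TrainConfig(max_epochs=40, seed=0)
        model, history = rp.train(bags, expr, donor_of, config=config)
        val = history["splits"]["val"] or history["splits"]["train"]
        mse = np.mean([
            np.mean((rp.predict_sample(model, bags[s]) - expr[s].to_numpy()) ** 2) for s in val
        ])
        assert mse < 1e-3

    def _affine_cohort(self, n=16, k=12, d=4, g=5, seed=0):
        rng = np.random.default_rng(seed)
        bags = {f"s{i}": rng.standard_normal((k, d)) for i in range(n)}
        W = rng.standard_normal((d, g))
        b = rng.uniform(0.5, 1.5, g)
        expr = pd.DataFrame(
            {s: np.maximum(bags[s] @ W + b, 0.0).mean(axis=0) for s in bags},
            index=[f"g{i}" for i in range(g)],
        )
        donor_of = {f"s{i}": f"d{i}" for i in range(n)}
        return bags, expr, donor_of

    def test_loss_decreases_on_noiseless_cohort(self):
        bags, expr, donor_of = self._affine_cohort(seed=1)
        _, history = rp.train(bags, expr, donor_of, config=rp.TrainConfig(max_epochs=15, seed=1))
        assert history["train_mse"][-1] < history["train_mse"][0]

    def test_identical_seed_identical_weights(self):
        bags, expr, donor_of = self._constant_cohort(seed=5)
        config = rp.TrainConfig(max_epochs=8, seed=123)
        m1, _ = rp.train(bags, expr, donor_of, config=config)
        m2, _ = rp.train(bags, expr, donor_of, config=config)
        assert np.array_equal(m1.W, m2.W) and np.array_equal(m1.b, m2.b)

    def test_gene_grouping_changes_nothing_material(self):
        """Gradient accumulation over gene groups with one update per sample:
        grouping is a memory detail, so any group size accumulates to the
        same full-MSE gradient and the trajectories coincide under one seed."""
        bags, expr, donor_of = self._affine_cohort(g=6, seed=2)
        hist = {}
        models = {}
        for gs in (500, 2):
            config = rp.TrainConfig(max_epochs=20, seed=2, gene_group_size=gs)
            models[gs], hist[gs] = rp.train(bags, expr, donor_of, config=config)
        for gs in (500, 2):
            assert hist[gs]["train_mse"][-1] < hist[gs]["train_mse"][0]
        # 6 genes in groups of 2: every group has equal size, so accumulated
        # gradients match the single-group gradient exactly
        assert np.allclose(models[500].W, models[2].W, atol=1e-10)

    def test_missing_gene_and_leaky_splits_rejected(self):
        bags, expr, donor_of = self._constant_cohort()
        with pytest.raises(ValueError, match="missing"):
            rp.train(bags, expr, donor_of, gene_names=["ghost"])
        donor_of_leaky = dict.fromkeys(bags, "d0")
        with pytest.raises(ValueError, match="d0"):
            rp.train(bags, expr, donor_of_leaky,
                     splits={"train": ["s0"], "val": ["s1"], "test": ["s2"]})

    def test_parameter_recovery_at_reference_scale(self, recovery_run):
        """On a cohort generated by the model's own hypothesis class
        (200 samples, 100 tiles, D=32, G=50, 5% noise), training from scratch
        recovers held-out per-gene Pearson r >= 0.9 for >= 90% of genes."""
        res = rp.evaluate(
            recovery_run["model"], recovery_run["bags"], recovery_run["cohort"].expression,
            recovery_run["history"]["splits"]["test"],
        )
        r = res["r"].to_numpy()
        assert np.mean(r >= 0.9) >= 0.9
        assert np.nanmedian(r) > 0.9


class TestEvaluate:
    def _setup(self, rng, n=6):
        model = rp.RNAPathModel(W=rng.standard_normal((4, 3)), b=np.ones(3), gene_names=list("abc"))
        bags = {f"s{i}": rng.standard_normal((10, 4)) for i in range(n)}
        preds = pd.DataFrame({s: rp.predict_sample(model, bags[s]) for s in bags}, index=list("abc"))
        return model, bags, preds

    def test_perfect_predictions_r_one(self, rng):
        model, bags, preds = self._setup(rng)
        res = rp.evaluate(model, bags, preds, list(bags))
        assert np.allclose(res["r"], 1.0)

    def test_anticorrelated_r_minus_one(self, rng):
        model, bags, preds = self._setup(rng)
        res = rp.evaluate(model, bags, -preds + 5.0, list(bags))
        assert np.allclose(res["r"], -1.0)

    def test_matches_covariance_oracle(self, rng):
        model, bags, preds = self._setup(rng, n=10)
        truth = preds + rng.standard_normal(preds.shape)
        res = rp.evaluate(model, bags, truth, list(bags))
        for i, g in enumerate("abc"):
            x = preds.loc[g].to_numpy()
            y = truth.loc[g].to_numpy()
            expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert res.loc[g, "r"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_not_zeroed(self, rng):
        model = rp.RNAPathModel(W=np.zeros((4, 2)), b=np.array([1.0, 2.0]), gene_names=["a", "b"])
        bags = {f"s{i}": rng.standard_normal((5, 4)) for i in range(4)}
        truth = pd.DataFrame(rng.standard_normal((2, 4)), index=["a", "b"], columns=list(bags))
        res = rp.evaluate(model, bags, truth, list(bags))
        assert not res["defined"].any()
        assert res["r"].isna().all()

    def test_too_few_samples(self, rng):
        model, bags, preds = self._setup(rng)
        with pytest.raises(ValueError, match=">= 3"):
            rp.evaluate(model, bags, preds, ["s0", "s1"])


class TestHeatmap:
    def test_cell_averages_covering_tiles(self):
        # two tiles, both covering cell (0,0): scores 1 and 3 -> mean 2
        model = rp.RNAPathModel(W=np.ones((1, 1)), b=np.zeros(1), gene_names=["g"])
        bag = rp.TileBag(
            sample_id="s", donor_id="d", tissue="t",
            embeddings=np.array([[1.0], [3.0]]),
            coords=np.array([[0, 0], [64, 0]], dtype=np.int64),
            tile_size_px=128, stride_px=64,
        )
        sp = rp.heatmap(model, bag, "g")
        assert sp.values[0, 0] == pytest.approx(2.0)
        assert sp.coverage[0, 0] == 2

    def test_nonoverlapping_equals_tile_scores(self, small_cohort):
        spec = small_cohort.spec
        model = rp.RNAPathModel(W=small_cohort.true_W, b=small_cohort.true_b,
                                gene_names=spec.gene_names)
        bag = small_cohort.bags[0]
        sp = rp.heatmap(model, bag, "gene_0")
        scores = rp.predict_tiles(model, bag)[:, 0]
        cells = rp.base_grid_index(bag)
        assert np.allclose(sp.values[cells[:, 0], cells[:, 1]], scores)
        assert (sp.coverage == 1).all()

    def test_planted_marker_gene_enriched_in_its_region(self, small_cohort):
        """Class-marker genes score higher inside their substructure than
        outside on the 75%-overlap heatmap, in >= 95% of samples carrying
        both regions."""
        spec = small_cohort.spec
        model = rp.RNAPathModel(W=small_cohort.true_W, b=small_cohort.true_b,
                                gene_names=spec.gene_names)
        hits = trials = 0
        for i, grid in enumerate(small_cohort.label_grids):
            if not (grid == 0).any() or (grid == 0).all():
                continue
            bag, _ = rp.generate_overlapping_bag(grid, spec, f"ov{i}", "d", i)
            sp = rp.heatmap(model, bag, "gene_0")  # marker of class 0
            inside = sp.values[grid == 0].mean()
            outside = sp.values[grid != 0].mean()
            trials += 1
            hits += int(inside > outside)
        assert trials > 0
        assert hits / trials >= 0.95

    def test_unknown_gene(self, rng):
        model = rp.RNAPathModel(W=np.zeros((2, 1)), b=np.zeros(1), gene_names=["g"])
        bag = rp.TileBag(sample_id="s", donor_id="d", tissue="t",
                         embeddings=np.zeros((1, 2)), coords=np.zeros((1, 2), dtype=np.int64),
                         tile_size_px=128, stride_px=128)
        with pytest.raises(KeyError):
            rp.heatmap(model, bag, "zzz")


class TestModelIO:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = rp.RNAPathModel(W=rng.standard_normal((4, 3)), b=rng.standard_normal(3),
                                gene_names=["x", "y", "z"], tissue="artery")
        path = str(tmp_path / "model.npz")
        rp.save_model(model, path)
        back = rp.load_model(path)
        assert np.array_equal(back.W, model.W) and np.array_equal(back.b, model.b)
        assert back.gene_names == model.gene_names and back.tissue == "artery"
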