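"""Clock training, prediction and cross-validation contracts."""

import numpy as np
import pandas as pd
import pytest

from clockforge import (ElasticNetClock, GeneratorConfig, SpeciesDesign,
                        evaluate_predictions, generate_panel, kfold_cv, loocv,
                        predict_clock, train_clock)
from clockforge.io import ClockModel, SpeciesParams


class TestTrain:
    def test_noiseless_recovery(self):
        config = GeneratorConfig(
            n_probes=600, n_age_probes=300, n_sex_probes=0,
            n_species_marker_probes=0, noise_sd=0.0,
            species={"cat": SpeciesDesign(n_samples=60, age_range=(0.2, 21.0),
                                          max_lifespan=30.0)},
            seed=2)
        matrix, sheet, _, _ = generate_panel(config)
        model = train_clock(matrix, sheet, target="raw_age", seed=0)
        pred = predict_clock(model, matrix, sheet)
        assert np.corrcoef(pred, sheet["age"])[0, 1] > 0.999

    def test_constant_target_rejected(self, cat_panel):
        _, (matrix, sheet, _, _) = cat_panel
        flat = sheet.copy()
        flat["age"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            train_clock(matrix, flat, target="raw_age", seed=0)

    def test_same_seed_identical_coefficients(self, cat_panel):
        _, (matrix, sheet, _, _) = cat_panel
        m1 = train_clock(matrix, sheet, target="raw_age", seed=4)
        m2 = train_clock(matrix, sheet, target="raw_age", seed=4)
        assert m1.probes == m2.probes
        assert np.array_equal(m1.coefficients, m2.coefficients)
        assert m1.intercept == m2.intercept

    def test_too_few_samples_rejected(self, rng):
        X = pd.DataFrame(rng.uniform(size=(10, 20)))
        sheet = pd.DataFrame({"species": ["cat"] * 10,
                              "age": rng.uniform(1, 10, 10)}, index=X.index)
        with pytest.raises(ValueError, match="20 samples"):
            train_clock(X, sheet, target="raw_age")

    def test_alpha_out_of_range_rejected(self, rng):
        est = ElasticNetClock(alpha=1.5)
        with pytest.raises(ValueError, match="alpha"):
            est.fit(rng.uniform(size=(30, 5)), rng.uniform(1, 10, 30))

    def test_dual_target_requires_species(self, rng):
        est = ElasticNetClock(target="loglinear_age")
        with pytest.raises(ValueError, match="species"):
            est.fit(rng.uniform(size=(30, 5)), rng.uniform(1, 10, 30))

    def test_zero_weight_species_reduces_to_single_species(self, dual_panel):
        """Zero-weighting one species of a dual panel reproduces the
        clock trained on the other species alone."""
        _, (matrix, sheet, _, _) = dual_panel
        params = {"cat": SpeciesParams(30.0, 1.0), "human": SpeciesParams(122.0, 15.0)}
        cats = sheet["species"] == "cat"
        est_w = ElasticNetClock(target="loglinear_age", species_params=params,
                                random_state=0, n_lambda=20)
        est_w.fit(matrix.data, sheet["age"], species=sheet["species"].to_numpy(),
                  sample_weight=cats.to_numpy().astype(float))
        est_s = ElasticNetClock(target="loglinear_age", species_params=params,
                                random_state=0, n_lambda=20)
        est_s.fit(matrix.data.loc[cats], sheet.loc[cats, "age"],
                  species=sheet.loc[cats, "species"].to_numpy())
        assert np.array_equal(est_w.coef_, est_s.coef_)
        assert est_w.intercept_ == est_s.intercept_


class TestPredict:
    def test_zero_coefficient_clock_constant_inverse(self):
        from clockforge.transforms import loglinear
        params = {"cat": SpeciesParams(30.0, 1.0)}
        model = ClockModel(probes=[], coefficients=np.array([]),
                           intercept=loglinear(5.0, 1.0, 0.0), alpha=0.5,
                           penalty=1.0, target="loglinear_age",
                           species_params=params, training_species=["cat"])
        X = pd.DataFrame(np.random.default_rng(0).uniform(size=(4, 3)),
                         columns=list("abc"))
        sheet = pd.DataFrame({"species": ["cat"] * 4, "age": [1.0] * 4}, index=X.index)
        assert np.allclose(predict_clock(model, X, sheet), 5.0)

    def test_probe_column_order_irrelevant(self, cat_panel):
        _, (matrix, sheet, _, _) = cat_panel
        model = train_clock(matrix, sheet, target="raw_age", seed=0)
        pred = predict_clock(model, matrix, sheet)
        shuffled = matrix.data.iloc[:, ::-1]
        pred2 = predict_clock(model, shuffled, sheet)
        assert np.array_equal(pred.to_numpy(), pred2.to_numpy())

    def test_matches_dot_product_oracle(self, cat_panel):
        """Predictions equal an independent intercept + coef . beta
        recomputation followed by the inverse transform."""
        _, (matrix, sheet, _, _) = cat_panel
        params = {"cat": SpeciesParams(30.0, 1.0)}
        model = train_clock(matrix, sheet, species_params=params,
                            target="relative_age", seed=0)
        pred = predict_clock(model, matrix, sheet)
        manual = model.intercept + matrix.data[model.probes].to_numpy() @ model.coefficients
        assert np.max(np.abs(pred.to_numpy() - manual)) < 1e-10

    def test_missing_model_probe_rejected(self, cat_panel):
        _, (matrix, sheet, _, _) = cat_panel
        model = train_clock(matrix, sheet, target="raw_age", seed=0)
        reduced = matrix.data.drop(columns=model.probes[:1])
        with pytest.raises(KeyError, match="model probe"):
            predict_clock(model, reduced, sheet)

    def test_unknown_species_under_relative_target(self, cat_panel):
        _, (matrix, sheet, _, _) = cat_panel
        model = train_clock(matrix, sheet,
                            species_params={"cat": SpeciesParams(30.0, 1.0)},
                            target="relative_age", seed=0)
        alien = sheet.copy()
        alien["species"] = "axolotl"
        with pytest.raises(KeyError, match="axolotl"):
            predict_clock(model, matrix, alien)


class TestEvaluate:
    def test_hand_computed_three_points(self):
        out = evaluate_predictions([1, 2, 3], [1, 2, 4])
        assert out.loc["overall", "medae"] == 0.0
        assert out.loc["overall", "R"] == pytest.approx(0.9820, abs=5e-5)

    def test_perfect_predictions(self):
        out = evaluate_predictions([1, 2, 3.0], [1, 2, 3.0])
        assert out.loc["overall", "R"] == pytest.approx(1.0)
        assert out.loc["overall", "medae"] == 0.0

    def test_offset_decouples_r_from_medae(self):
        truth = np.array([1.0, 5.0, 9.0, 13.0])
        out = evaluate_predictions(truth + 10, truth)
        assert out.loc["overall", "R"] == pytest.approx(1.0)
        assert out.loc["overall", "medae"] == pytest.approx(10.0)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            evaluate_predictions([1, 2, 3], [5, 5, 5])

    def test_per_group_metrics(self):
        out = evaluate_predictions([1, 2, 3, 4, 5, 7.0], [1, 2, 3, 4, 5, 6.0],
                                   groups=["a", "a", "a", "b", "b", "b"])
        assert set(out.index) == {"overall", "a", "b"}
        assert out.loc["a", "medae"] == 0.0


def _tiny_panel(seed=9, n=30):
    config = GeneratorConfig(
        n_probes=120, n_age_probes=40, n_sex_probes=10, n_species_marker_probes=0,
        species={"cat": SpeciesDesign(n_samples=n, age_range=(0.2, 21.0),
                                      max_lifespan=30.0)},
        seed=seed)
    return generate_panel(config)


class TestCrossValidation:
    def test_loocv_fold_bookkeeping(self):
        matrix, sheet, _, _ = _tiny_panel()
        result = loocv(matrix, sheet, target="raw_age", seed=0, n_lambda=15)
        folds = result.predictions["fold"]
        assert sorted(folds) == list(range(len(sheet)))  # each sample out once
        assert result.predictions["predicted"].notna().all()

    def test_loocv_no_leakage_of_own_target(self):
        """Perturbing one sample's age must not change that sample's
        own out-of-fold prediction (it is excluded from its fold)."""
        matrix, sheet, _, _ = _tiny_panel()
        r1 = loocv(matrix, sheet, target="raw_age", seed=0, n_lambda=15)
        perturbed = sheet.copy()
        victim = sheet.index[4]
        perturbed.loc[victim, "age"] = 400.0
        r2 = loocv(matrix, perturbed, target="raw_age", seed=0, n_lambda=15)
        assert (r1.predictions.loc[victim, "predicted"]
                == r2.predictions.loc[victim, "predicted"])

    def test_pure_noise_panel_no_positive_association(self):
        """Under the null (no age probes) LOOCV must find no positive
        association.  Note R is *negatively* biased here, not zero: the
        held-out prediction shrinks toward the training mean, which
        excludes the held-out age and is therefore anti-correlated
        with it (exactly -1 in the intercept-only limit).  The spread
        of predictions also collapses relative to the age spread."""
        config = GeneratorConfig(
            n_probes=120, n_age_probes=0, n_sex_probes=0, n_species_marker_probes=0,
            species={"cat": SpeciesDesign(n_samples=30, age_range=(0.2, 21.0),
                                          max_lifespan=30.0)},
            seed=13)
        matrix, sheet, _, _ = generate_panel(config)
        result = loocv(matrix, sheet, target="raw_age", seed=0, n_lambda=15)
        pred = result.predictions["predicted"]
        assert result.metrics().loc["overall", "R"] < 0.3
        assert pred.std() < 0.5 * sheet["age"].std()

    def test_kfold_equals_loocv_when_k_is_n(self):
        """k = n reduces to the leave-one-out scheme: the singleton
        fold assignment is seed-independent, and with the same seed
        for the internal penalty search the predictions are
        bit-identical to loocv's."""
        matrix, sheet, _, _ = _tiny_panel()
        r_loo = loocv(matrix, sheet, target="raw_age", seed=0, n_lambda=15)
        r_kn = kfold_cv(matrix, sheet, target="raw_age", k=len(sheet), seed=0,
                        n_lambda=15)
        assert np.array_equal(r_loo.predictions["predicted"].to_numpy(),
                              r_kn.predictions["predicted"].to_numpy())
        r_kn2 = kfold_cv(matrix, sheet, target="raw_age", k=len(sheet), seed=99,
                         n_lambda=15)
        assert np.array_equal(r_kn.predictions["fold"].to_numpy(),
                              r_kn2.predictions["fold"].to_numpy())

    def test_fold_sizes_balanced_within_strata(self, dual_panel):
        _, (matrix, sheet, _, _) = dual_panel
        from clockforge.clock import kfold_cv as kf
        result = kf(matrix.data.iloc[:, :50], sheet, target="raw_age", k=7, seed=0,
                    n_lambda=5)
        frame = result.predictions
        for sp in frame["species"].unique():
            sizes = frame[frame["species"] == sp]["fold"].value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_k_bounds(self):
        matrix, sheet, _, _ = _tiny_panel()
        with pytest.raises(ValueError, match="k"):
            kfold_cv(matrix, sheet, k=1)
        with pytest.raises(ValueError, match="k"):
            kfold_cv(matrix, sheet, k=100)

    def test_fit_error_names_fold(self):
        matrix, sheet, _, _ = _tiny_panel()
        flat = sheet.copy()
        flat["age"] = 1.0
        with pytest.raises(RuntimeError, match="fold 0"):
            loocv(matrix, flat, target="raw_age", n_lambda=15)
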