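import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from widqt._solver import lambda_max, logistic_path
from widqt.evaluation import roc_auc
from widqt.qt_index import (IndexModel, compute_index, finalize_index,
                            fit_penalized_classifier, load_index, save_index,
                            select_model)
from widqt.synthetic_data import CohortConfig, generate_cohort


def _toy_model(weights, cpgs=None, mu=0.0, sigma=1.0, penalty="l1"):
    cpgs = cpgs or [f"cg{i}" for i in range(len(weights))]
    return IndexModel(cpg_ids=cpgs, weights=np.asarray(weights, float),
                      intercept=0.0, mu=mu, sigma=sigma, penalty=penalty,
                      lam=0.01)


class TestSolver:
    def test_all_zero_at_lambda_max(self, rng):
        X = rng.uniform(0, 1, (80, 12))
        y = rng.integers(0, 2, 80).astype(float)
        lam = lambda_max(X, y)
        coefs, _ = logistic_path(X, y, np.array([lam * 1.0001]), alpha=1.0)
        assert np.count_nonzero(coefs) == 0
        coefs, _ = logistic_path(X, y, np.array([lam * 0.5]), alpha=1.0)
        assert np.count_nonzero(coefs) > 0

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    @pytest.mark.parametrize("alpha", [1.0, 0.0])
    def test_matches_glmnet_reference(self, tmp_path, rng, alpha):
        """Cross-check the path solver against the R glmnet implementation."""
        n, p = 150, 25
        X = rng.uniform(0, 1, (n, p))
        y = rng.integers(0, 2, n).astype(float)
        X[:, :4] += 0.4 * y[:, None]
        lam = lambda_max(X, y)
        path = np.geomspace(lam, lam * 1e-2, 12)
        coefs, intercepts = logistic_path(X, y, path, alpha, tol=1e-7)
        np.savetxt(tmp_path / "X.txt", X)
        np.savetxt(tmp_path / "y.txt", y)
        np.savetxt(tmp_path / "lam.txt", path)
        script = f"""
        suppressMessages(library(glmnet))
        X <- as.matrix(read.table("{tmp_path}/X.txt"))
        y <- scan("{tmp_path}/y.txt", quiet=TRUE)
        lam <- scan("{tmp_path}/lam.txt", quiet=TRUE)
        fit <- glmnet(X, y, family="binomial", alpha={alpha}, lambda=lam,
                      standardize=FALSE, thresh=1e-12)
        write.table(as.matrix(t(fit$beta)), "{tmp_path}/W.txt",
                    row.names=FALSE, col.names=FALSE)
        write(fit$a0, "{tmp_path}/b.txt", ncolumns=1)
        """
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref_w = np.loadtxt(tmp_path / "W.txt")
        ref_b = np.loadtxt(tmp_path / "b.txt")
        assert np.abs(coefs - ref_w).max() < 5e-3
        assert np.abs(intercepts - ref_b).max() < 5e-3


class TestFitPenalizedClassifier:
    def test_separable_data_training_auc_one(self, rng):
        n = 120
        y = pd.Series(np.repeat([0, 1], n // 2))
        betas = pd.DataFrame(rng.uniform(0.3, 0.7, (5, n)),
                             index=[f"cg{i}" for i in range(5)],
                             columns=[f"S{j}" for j in range(n)])
        betas.iloc[0] = 0.1 + 0.8 * y.to_numpy()    # perfectly separating
        y.index = betas.columns
        model, _ = fit_penalized_classifier(betas, y, penalty="l1", k_folds=5)
        scores = compute_index(betas, model)
        assert roc_auc(scores, y).auc == 1.0

    def test_deterministic_under_seed(self, small_cohort, small_split):
        betas = small_cohort.betas_by_tissue["cervical"]
        mq = small_cohort.mqtl_cpgs
        labels = small_cohort.phenotypes["case"]
        tr = small_split["train"]
        m1, _ = fit_penalized_classifier(betas.loc[mq, tr], labels.loc[tr],
                                         seed=3)
        m2, _ = fit_penalized_classifier(betas.loc[mq, tr], labels.loc[tr],
                                         seed=3)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.lam == m2.lam

    def test_chosen_lambda_in_cv_curve(self, small_cohort, small_split):
        betas = small_cohort.betas_by_tissue["cervical"]
        mq = small_cohort.mqtl_cpgs
        tr = small_split["train"]
        _, report = fit_penalized_classifier(
            betas.loc[mq, tr], small_cohort.phenotypes.loc[tr, "case"])
        assert report.chosen_lambda in report.cv_curve
        assert report.cv_curve[report.chosen_lambda] \
            == min(report.cv_curve.values())

    def test_invalid_inputs(self, rng):
        betas = pd.DataFrame(rng.uniform(0, 1, (3, 10)),
                             columns=[f"S{j}" for j in range(10)])
        single = pd.Series(1, index=betas.columns)
        with pytest.raises(ValueError):
            fit_penalized_classifier(betas, single)
        both = pd.Series([0, 1] * 5, index=betas.columns)
        with pytest.raises(ValueError):
            fit_penalized_classifier(betas, both, k_folds=1)
        with pytest.raises(ValueError):
            fit_penalized_classifier(betas, both, k_folds=11)


class TestSelectModel:
    @staticmethod
    def _internal_set(rng, n=60):
        betas = pd.DataFrame(rng.uniform(0, 1, (2, n)),
                             index=["cg0", "cg1"],
                             columns=[f"S{j}" for j in range(n)])
        labels = pd.Series((betas.loc["cg0"] > 0.5).astype(int),
                           index=betas.columns)
        return betas, labels

    def test_higher_auc_wins(self, rng):
        betas, labels = self._internal_set(rng)
        from widqt.qt_index import TrainReport
        informative = _toy_model([1.0, 0.0])    # tracks the label-driving CpG
        noise = _toy_model([0.0, 1.0])
        reports = [TrainReport({}, 0.01, 1), TrainReport({}, 0.01, 1)]
        best = select_model([(noise, reports[0]), (informative, reports[1])],
                            betas, labels)
        assert best is informative
        assert reports[1].internal_validation_auc == 1.0

    def test_tie_breaks_to_sparser(self, rng):
        betas, labels = self._internal_set(rng)
        from widqt.qt_index import TrainReport
        dense = _toy_model([1.0, 1e-9])
        sparse = _toy_model([1.0, 0.0])
        # identical scores up to 1e-9 -> identical AUC; sparser must win
        best = select_model([(dense, TrainReport({}, 0.01, 2)),
                             (sparse, TrainReport({}, 0.01, 1))],
                            betas, labels)
        assert best is sparse

    def test_empty_candidates_rejected(self, rng):
        betas, labels = self._internal_set(rng)
        with pytest.raises(ValueError):
            select_model([], betas, labels)


class TestFinalizeIndex:
    def test_discovery_scores_standardized(self, small_cohort, small_split):
        betas = small_cohort.betas_by_tissue["cervical"]
        mq = small_cohort.mqtl_cpgs
        disc = small_split["discovery"]
        labels = small_cohort.phenotypes.loc[disc, "case"]
        model, _ = finalize_index("l1", betas.loc[mq, disc], labels, seed=0)
        scores = compute_index(betas.loc[mq, disc], model)
        assert abs(scores.mean()) < 1e-10
        assert abs(scores.std(ddof=1) - 1.0) < 1e-10

    def test_refit_deterministic(self, small_cohort, small_split):
        betas = small_cohort.betas_by_tissue["cervical"]
        mq = small_cohort.mqtl_cpgs
        disc = small_split["discovery"]
        labels = small_cohort.phenotypes.loc[disc, "case"]
        m1, _ = finalize_index("l1", betas.loc[mq, disc], labels, seed=5)
        m2, _ = finalize_index("l1", betas.loc[mq, disc], labels, seed=5)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert (m1.mu, m1.sigma) == (m2.mu, m2.sigma)

    def test_all_zero_weights_raise(self, rng):
        # pure-noise labels at tiny n: lasso returns the empty model
        betas = pd.DataFrame(rng.uniform(0, 1, (4, 40)),
                             columns=[f"S{j}" for j in range(40)])
        labels = pd.Series(rng.permutation([0, 1] * 20),
                           index=betas.columns)
        with pytest.raises(ValueError, match="degenerate|sigma"):
            finalize_index("l1", betas, labels, k_folds=4, seed=1)

    def test_support_recovery_under_large_sparse_effects(self):
        precisions = []
        for seed in range(5):
            cfg = CohortConfig(n_train=400, n_internal=200, n_validation=0,
                               n_snps=20, n_mqtl_cpgs=120,
                               n_background_cpgs=80, case_effect=2.0,
                               n_case_cpgs=8, noise_sd=0.4, seed=seed)
            bundle = generate_cohort(cfg)
            ph = bundle.phenotypes
            disc = ph.index[ph["set"] != "validation"]
            betas = bundle.betas_by_tissue["cervical"]
            model, _ = finalize_index("l1", betas.loc[bundle.mqtl_cpgs, disc],
                                      ph.loc[disc, "case"], seed=seed)
            truth = set(bundle.truth["case_effect_cpgs"])
            selected = set(model.nonzero_cpgs())
            precisions.append(len(selected & truth) / max(len(selected), 1))
        assert np.mean(precisions) > 0.95


class TestComputeIndex:
    def test_identity_and_hand_arithmetic(self):
        betas = pd.DataFrame({"S1": [0.5, 0.5]}, index=["cg0", "cg1"])
        ident = _toy_model([1.0], cpgs=["cg0"])
        assert compute_index(betas, ident)["S1"] == pytest.approx(0.5)
        model = _toy_model([2.0, -1.0], mu=0.1, sigma=2.0)
        assert compute_index(betas, model)["S1"] == pytest.approx(0.2)

    def test_missing_cpg_named_in_error(self):
        betas = pd.DataFrame({"S1": [0.5]}, index=["cg0"])
        model = _toy_model([1.0, 1.0], cpgs=["cg0", "cg_absent"])
        with pytest.raises(KeyError, match="cg_absent"):
            compute_index(betas, model)

    def test_affine_shift_absorbed_by_mu(self, rng):
        # adding a constant CpG with weight c shifts every raw sum by c;
        # refitting mu leaves the standardized scores unchanged
        betas = pd.DataFrame(rng.uniform(0, 1, (3, 20)),
                             index=["cg0", "cg1", "cg2"],
                             columns=[f"S{j}" for j in range(20)])
        base = _toy_model([0.7, -0.2, 0.4], mu=0.3, sigma=1.7)
        shifted_betas = pd.concat(
            [betas, pd.DataFrame(1.0, index=["cg_const"],
                                 columns=betas.columns)])
        c = 5.0
        shifted = IndexModel(cpg_ids=base.cpg_ids + ["cg_const"],
                             weights=np.append(base.weights, c),
                             intercept=0.0, mu=base.mu + c, sigma=base.sigma,
                             penalty="l1", lam=0.01)
        pd.testing.assert_series_equal(compute_index(betas, base),
                                       compute_index(shifted_betas, shifted))

    def test_roundtrip_serialization(self, tmp_path, rng):
        model = _toy_model(rng.normal(0, 1, 4), mu=0.2, sigma=1.3)
        save_index(model, tmp_path / "w.tsv", tmp_path / "s.json")
        loaded = load_index(tmp_path / "w.tsv", tmp_path / "s.json")
        np.testing.assert_allclose(loaded.weights, model.weights, rtol=1e-12)
        assert (loaded.mu, loaded.sigma, loaded.penalty) \
            == (model.mu, model.sigma, model.penalty)
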