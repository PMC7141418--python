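import numpy as np
import pandas as pd
import pytest

from gsweave import (
    GenotypeMatrix,
    PhenotypeVector,
    SimConfig,
    fit,
    predict_gebv,
    simulate_population,
)
from gsweave.core import vanraden_design
from gsweave.predictors import (
    fit_bayes,
    fit_brnn,
    fit_gblup,
    fit_penalized,
    fit_rf,
    fit_rkhs,
    fit_svm,
)

EFFECT_METHODS = ["GBLUP", "RR", "LASSO", "BRR"]


def _pheno(values, ids):
    return PhenotypeVector(pd.Series(np.asarray(values, float), index=ids))


@pytest.fixture(scope="module")
def pop():
    cfg = SimConfig(n_lines=100, n_markers=200, n_chromosomes=5,
                    n_qtl=30, h2_target=0.5, seed=7)
    return simulate_population(cfg)


class TestGBLUP:
    def test_constant_phenotype_rejected(self, pop):
        geno = pop[0]
        with pytest.raises(ValueError, match="variance"):
            fit_gblup(geno, _pheno(np.ones(geno.n_lines), geno.line_ids))

    def test_gebv_track_tbv_and_improve_with_heritability(self):
        cors = []
        for h2 in (0.2, 0.5, 0.8):
            cfg = SimConfig(n_lines=100, n_markers=300, n_chromosomes=5,
                            n_qtl=30, h2_target=h2, seed=3)
            geno, _, pheno, truth = simulate_population(cfg)
            model = fit_gblup(geno, pheno)
            cors.append(np.corrcoef(model.fitted_gebv,
                                    truth.tbv.loc[geno.line_ids])[0, 1])
        assert cors[0] > 0
        assert cors[0] < cors[1] < cors[2]

    def test_equals_ridge_regression_with_matched_penalty(self, pop):
        geno, _, pheno, _ = pop
        model = fit_gblup(geno, pheno)
        y = pheno.aligned_to(geno.line_ids)
        W, p, c = vanraden_design(geno.dosage)
        n = geno.n_lines
        delta = model.extra["delta"]
        # closed-form ridge with penalty matched to the variance ratio
        H = W @ W.T / c + delta * np.eye(n)
        Hinv = np.linalg.inv(H)
        ones = np.ones(n)
        mu = (ones @ Hinv @ y) / (ones @ Hinv @ ones)
        beta = np.linalg.solve(W.T @ W + c * delta * np.eye(W.shape[1]),
                               W.T @ (y - mu))
        gebv_ridge = mu + W @ beta
        scale = np.std(model.fitted_gebv)
        assert np.max(np.abs(gebv_ridge - model.fitted_gebv)) / scale < 1e-6

    def test_pev_and_reliability(self, pop):
        geno, _, pheno, _ = pop
        model = fit_gblup(geno, pheno)
        assert model.pev is not None and np.all(model.pev >= 0)
        rel = model.reliability
        assert np.all(rel >= 0) and np.all(rel <= 1)


class TestEGBLUP:
    def test_epistatic_kernel_has_unit_diagonal(self, pop):
        geno, _, pheno, _ = pop
        model = fit("EGBLUP", geno, pheno, n_iter=600, burn_in=200, seed=1)
        H = model.kernel_components[1]["K"]
        np.testing.assert_allclose(np.diag(H), 1.0, atol=1e-8)

    def test_close_to_gblup_on_additive_trait(self, pop):
        """On a purely additive trait the epistatic component should stay
        small and the GEBV should agree closely with plain GBLUP."""
        geno, _, pheno, _ = pop
        g = fit("GBLUP", geno, pheno)
        e = fit("EGBLUP", geno, pheno, n_iter=3000, burn_in=1000, seed=1)
        assert np.corrcoef(g.fitted_gebv, e.fitted_gebv)[0, 1] > 0.9
        s_add, s_epi = e.mcmc["sigma2_k"]
        assert s_add > s_epi


class TestPenalized:
    def test_ridge_matches_closed_form(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(10, 20)).astype(float)
        geno = GenotypeMatrix([f"l{i}" for i in range(10)],
                              [f"m{j}" for j in range(20)], dosage)
        y = rng.normal(size=10)
        pheno = _pheno(y, geno.line_ids)
        lam = 3.7
        model = fit_penalized(geno, pheno, penalty="RR", lambda_grid=[lam])
        Xs = (dosage - dosage.mean(0)) / np.where(dosage.std(0) > 0, dosage.std(0), 1)
        yc = y - y.mean()
        beta = np.linalg.solve(Xs.T @ Xs + lam * np.eye(20), Xs.T @ yc)
        fitted_closed = y.mean() + Xs @ beta
        np.testing.assert_allclose(model.fitted_gebv, fitted_closed, atol=1e-8)

    def test_lasso_recovers_sparse_signal(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(60, 40)).astype(float)
        geno = GenotypeMatrix([f"l{i}" for i in range(60)],
                              [f"m{j}" for j in range(40)], dosage)
        y = 4.0 * dosage[:, 7] + rng.normal(scale=0.5, size=60)
        model = fit_penalized(geno, _pheno(y, geno.line_ids), penalty="LASSO")
        beta = np.abs(model.beta)
        assert beta[7] > 0
        assert np.argmax(beta) == 7
        assert np.mean(beta < 1e-10) > 0.5  # most effects exactly zero

    def test_large_penalty_shrinks_to_intercept(self, pop):
        geno, _, pheno, _ = pop
        model = fit_penalized(geno, pheno, penalty="RR", lambda_grid=[1e12])
        assert np.std(model.fitted_gebv) < 1e-4

    def test_empty_grid_rejected(self, pop):
        geno, _, pheno, _ = pop
        with pytest.raises(ValueError, match="empty"):
            fit_penalized(geno, pheno, penalty="RR", lambda_grid=[])


class TestBayes:
    def test_null_trait_shrinks_gebv(self, pop):
        geno = pop[0]
        rng = np.random.default_rng(2)
        y = rng.normal(size=geno.n_lines)        # pure noise, h2 = 0
        model = fit_bayes(geno, _pheno(y, geno.line_ids), prior="BRR",
                          n_iter=2000, burn_in=500, seed=4)
        assert np.var(model.fitted_gebv - model.mu) < 0.25 * np.var(y)

    def test_bb_bc_with_full_slab_reduce_to_ba_brr(self, pop):
        """Fixing the inclusion probability at ~1 collapses the mixture
        priors onto their slab distributions."""
        geno, _, pheno, _ = pop
        kw = dict(n_iter=2500, burn_in=500, seed=9)
        bb = fit_bayes(geno, pheno, prior="BB", pi0=0.9999, pi_counts=1e9, **kw)
        ba = fit_bayes(geno, pheno, prior="BA", **kw)
        bc = fit_bayes(geno, pheno, prior="BC", pi0=0.9999, pi_counts=1e9, **kw)
        brr = fit_bayes(geno, pheno, prior="BRR", **kw)
        assert np.corrcoef(bb.fitted_gebv, ba.fitted_gebv)[0, 1] > 0.95
        assert np.corrcoef(bc.fitted_gebv, brr.fitted_gebv)[0, 1] > 0.95

    def test_seeded_chains_reproducible(self, pop):
        geno, _, pheno, _ = pop
        a = fit_bayes(geno, pheno, prior="BL", n_iter=500, burn_in=100, seed=3)
        b = fit_bayes(geno, pheno, prior="BL", n_iter=500, burn_in=100, seed=3)
        np.testing.assert_array_equal(a.fitted_gebv, b.fitted_gebv)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_burn_in_validation(self, pop):
        geno, _, pheno, _ = pop
        with pytest.raises(ValueError, match="burn_in"):
            fit_bayes(geno, pheno, prior="BRR", n_iter=100, burn_in=100)


class TestRKHS:
    def test_tiny_bandwidth_degenerates_to_intercept(self, pop):
        geno, _, pheno, _ = pop
        model = fit_rkhs(geno, pheno, bandwidths=[1e-8],
                         n_iter=800, burn_in=200, seed=0)
        assert np.std(model.fitted_gebv) < 0.2 * np.std(
            pheno.aligned_to(geno.line_ids))

    def test_vanraden_kernel_reproduces_gblup(self, pop):
        """Plugging the additive relationship matrix in as the kernel
        should give the GBLUP solution up to Monte Carlo error."""
        from gsweave.core import compute_relationship
        from gsweave._kernels import kernel_gibbs

        geno, _, pheno, _ = pop
        g = fit("GBLUP", geno, pheno)
        G = compute_relationship(geno).A
        res = kernel_gibbs([G], pheno.aligned_to(geno.line_ids),
                           n_iter=3000, burn_in=1000, seed=2)
        assert np.corrcoef(g.fitted_gebv, res["mu"] + res["g"])[0, 1] > 0.99

    def test_empty_bandwidths_rejected(self, pop):
        geno, _, pheno, _ = pop
        with pytest.raises(ValueError, match="bandwidth"):
            fit_rkhs(geno, pheno, bandwidths=[])


class TestMLMethods:
    def test_rf_learns_single_split_signal(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(80, 30)).astype(float)
        geno = GenotypeMatrix([f"l{i}" for i in range(80)],
                              [f"m{j}" for j in range(30)], dosage)
        y = (dosage[:, 4] >= 1).astype(float)
        model = fit_rf(geno, _pheno(y, geno.line_ids), n_trees=200, seed=0)
        r2 = np.corrcoef(model.fitted_gebv, y)[0, 1] ** 2
        assert r2 > 0.9

    def test_rf_invariant_to_marker_column_order(self, pop):
        geno, _, pheno, _ = pop
        shuffled = geno.subset_markers(
            np.random.default_rng(0).permutation(geno.marker_ids))
        a = fit_rf(geno, pheno, n_trees=50, seed=1)
        b = fit_rf(shuffled, pheno, n_trees=50, seed=1)
        np.testing.assert_allclose(a.fitted_gebv, b.fitted_gebv)

    def test_svm_fits_linear_trait(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(60, 20)).astype(float)
        geno = GenotypeMatrix([f"l{i}" for i in range(60)],
                              [f"m{j}" for j in range(20)], dosage)
        effects = rng.normal(size=20)
        y = dosage @ effects
        model = fit_svm(geno, _pheno(y, geno.line_ids), cost=100.0, epsilon=0.01)
        assert np.corrcoef(model.fitted_gebv, y)[0, 1] > 0.95

    def test_svm_duplicate_points_predict_identically(self, pop):
        geno, _, pheno, _ = pop
        model = fit_svm(geno, pheno)
        dup = geno.subset_lines(geno.line_ids[:5])
        pred = predict_gebv(model, dup)
        again = predict_gebv(model, dup)
        np.testing.assert_array_equal(pred["gebv"], again["gebv"])

    def test_brnn_fits_noiseless_linear_trait(self):
        rng = np.random.default_rng(6)
        dosage = rng.integers(0, 3, size=(60, 50)).astype(float)
        geno = GenotypeMatrix([f"l{i}" for i in range(60)],
                              [f"m{j}" for j in range(50)], dosage)
        y = dosage @ rng.normal(size=50)
        model = fit_brnn(geno, _pheno(y, geno.line_ids), seed=2)
        assert np.corrcoef(model.fitted_gebv, y)[0, 1] > 0.9

    def test_brnn_seeded_reproducible(self, pop):
        geno, _, pheno, _ = pop
        a = fit_brnn(geno, pheno, epochs=3, seed=5)
        b = fit_brnn(geno, pheno, epochs=3, seed=5)
        np.testing.assert_array_equal(a.fitted_gebv, b.fitted_gebv)

    def test_parameter_validation(self, pop):
        geno, _, pheno, _ = pop
        with pytest.raises(ValueError):
            fit_rf(geno, pheno, n_trees=0)
        with pytest.raises(ValueError):
            fit_svm(geno, pheno, cost=-1.0)
        with pytest.raises(ValueError):
            fit_brnn(geno, pheno, neurons=0)


class TestPredictGEBV:
    def test_training_set_returns_fitted_values(self, pop):
        geno, _, pheno, _ = pop
        for method in ("GBLUP", "RR", "RF"):
            model = fit(method, geno, pheno, **({"seed": 0} if method == "RF" else {}))
            pred = predict_gebv(model, geno)
            np.testing.assert_allclose(pred["gebv"].to_numpy(),
                                       model.fitted_gebv, atol=1e-5)

    def test_effect_model_is_a_dot_product(self, pop):
        geno, _, pheno, _ = pop
        model = fit("GBLUP", geno, pheno)
        mean_line = GenotypeMatrix(
            ["mean", "pad"], geno.marker_ids,
            np.vstack([geno.dosage.mean(axis=0), geno.dosage[0]]),
            validate_integer=False,
        )
        pred = predict_gebv(model, mean_line)
        expected = model.mu + (geno.dosage.mean(axis=0) - model.centers) @ model.beta
        assert pred["gebv"].iloc[0] == pytest.approx(expected)

    def test_rows_follow_ids_not_positions(self, pop):
        geno, _, pheno, _ = pop
        model = fit("GBLUP", geno, pheno)
        shuffled = geno.subset_lines(
            np.random.default_rng(1).permutation(geno.line_ids))
        pred = predict_gebv(model, shuffled).set_index("line_id")
        base = predict_gebv(model, geno).set_index("line_id")
        np.testing.assert_allclose(pred.loc[geno.line_ids, "gebv"],
                                   base.loc[geno.line_ids, "gebv"])

    def test_marker_mismatch_reported(self, pop):
        geno, _, pheno, _ = pop
        model = fit("GBLUP", geno, pheno)
        subset = geno.subset_markers(geno.marker_ids[:-5])
        with pytest.raises(ValueError, match="mismatch"):
            predict_gebv(model, subset)

    def test_location_equivariance_of_effect_methods(self, pop):
        geno, _, pheno, _ = pop
        shift = 37.5
        shifted = PhenotypeVector(pheno.values + shift)
        for method in ("GBLUP", "RR"):
            a = fit(method, geno, pheno)
            b = fit(method, geno, shifted)
            assert b.mu == pytest.approx(a.mu + shift, rel=1e-5, abs=1e-5)
            np.testing.assert_allclose(
                b.fitted_gebv - b.fitted_gebv.mean(),
                a.fitted_gebv - a.fitted_gebv.mean(), atol=1e-5)

    def test_unknown_method_rejected(self, pop):
        geno, _, pheno, _ = pop
        with pytest.raises(ValueError, match="unknown method"):
            fit("XGBOOST", geno, pheno)
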