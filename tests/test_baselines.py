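"""Dosage conversion, GRM, rrBLUP/gBLUP and their equivalence."""

import numpy as np
import pandas as pd
import pytest

import novgmdeep as ng
from novgmdeep.io import Coding, RawGenotypeTable, VariantClass


def _phased_table(calls_by_marker):
    marker_ids = list(calls_by_marker)
    n = len(next(iter(calls_by_marker.values())))
    accs = [f"a{i}" for i in range(n)]
    df = pd.DataFrame(calls_by_marker, index=accs)
    return RawGenotypeTable(
        accessions=accs, marker_ids=marker_ids, coding=Coding.PHASED_VCF,
        calls=df, chrom=["1"] * len(marker_ids),
        pos=list(range(1, len(marker_ids) + 1)),
        variant_classes=[VariantClass.DEL] * len(marker_ids),
    )


class TestToDosage:
    def test_phased_mapping(self):
        table = _phased_table({"m1": ["0|0", "1|1", "0|1"]})
        d = ng.to_dosage(table)
        np.testing.assert_array_equal(d.Z.ravel(), [0.0, 2.0, 1.0])

    def test_missing_imputed_to_column_mean(self):
        table = _phased_table({"m1": ["0|0", "1|1", ".|."]})
        d = ng.to_dosage(table)
        assert d.Z[2, 0] == pytest.approx(1.0)  # mean of {0, 2}
        assert d.n_imputed == 1

    def test_coded_mapping(self):
        df = pd.DataFrame({"m1": [1.0, -1.0], "m2": [0.0, np.nan]},
                          index=["a0", "a1"])
        table = RawGenotypeTable(
            accessions=["a0", "a1"], marker_ids=["m1", "m2"],
            coding=Coding.INTEGER_CODED, calls=df,
        )
        d = ng.to_dosage(table)
        np.testing.assert_array_equal(d.Z[:, 0], [0.0, 2.0])
        assert d.Z[1, 1] == pytest.approx(1.0)  # imputed to column mean

    def test_multiallelic_treated_as_missing(self):
        table = _phased_table({"m1": ["0|0", "2|2", "1|1"]})
        d = ng.to_dosage(table)
        assert d.Z[1, 0] == pytest.approx(1.0)  # mean of {0, 2}


class TestRrblup:
    def test_noiseless_ols_limit(self):
        rng = np.random.default_rng(0)
        n, m = 60, 10
        Z = rng.integers(0, 3, size=(n, m)).astype(float)
        beta = rng.normal(size=m)
        y = Z @ beta + 3.0
        fit = ng.rrblup_fit(Z, y, lam=1e-8)
        np.testing.assert_allclose(fit.predict(Z), y, atol=1e-5)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        Z = rng.integers(0, 3, size=(30, 5)).astype(float)
        y = rng.normal(size=30)
        fit = ng.rrblup_fit(Z, y, lam=1e12)
        np.testing.assert_allclose(fit.effects, 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.predict(Z), np.mean(y), atol=1e-3)

    def test_constant_phenotype_rejected(self):
        Z = np.ones((12, 3))
        with pytest.raises(ValueError, match="constant"):
            ng.rrblup_fit(Z, np.full(12, 5.0))

    def test_heritability_recovery(self):
        """REML h2 within +/-0.15 of truth, averaged over 10 replicates."""
        errors = []
        for s in range(10):
            cfg = ng.SimConfig(n_accessions=400, n_markers=500, n_causal=30,
                               heritability=0.8, seed=100 + s)
            table = ng.simulate_genotypes(cfg)
            pheno, _ = ng.simulate_phenotypes(table, cfg)
            y = np.asarray([pheno.values[a] for a in table.accessions])
            fit = ng.rrblup_fit(ng.to_dosage(table).Z, y)
            errors.append(abs(fit.h2 - 0.8))
        assert np.mean(errors) < 0.15

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(3)
        Z = rng.integers(0, 3, size=(40, 20)).astype(float)
        y = Z[:, 0] * 2 + rng.normal(size=40)
        perm = rng.permutation(20)
        f1 = ng.rrblup_fit(Z, y)
        f2 = ng.rrblup_fit(Z[:, perm], y)
        np.testing.assert_allclose(
            f1.predict(Z), f2.predict(Z[:, perm]), atol=1e-8
        )


class TestGrm:
    def test_symmetric(self):
        rng = np.random.default_rng(4)
        K = ng.grm(rng.integers(0, 3, size=(15, 40)).astype(float))
        np.testing.assert_array_equal(K, K.T)

    def test_duplicated_accession_rows(self):
        rng = np.random.default_rng(5)
        Z = rng.integers(0, 3, size=(10, 30)).astype(float)
        Zdup = np.vstack([Z, Z[0]])
        K = ng.grm(Zdup)
        assert K[0, 10] == pytest.approx(K[0, 0])

    def test_mean_diagonal_near_one_at_hardy_weinberg(self):
        cfg = ng.SimConfig(n_accessions=200, n_markers=1000,
                           scheme=ng.GenotypeScheme.CODED, n_causal=10,
                           missing_rate=0.0, seed=7)
        K = ng.grm(ng.to_dosage(ng.simulate_genotypes(cfg)))
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.1)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ng.grm(np.full((5, 4), 2.0))


class TestGblup:
    def test_identity_kernel_gives_no_information(self):
        rng = np.random.default_rng(6)
        y = rng.normal(5.0, 1.0, size=25)
        fit = ng.gblup_fit(np.eye(25), y)
        # no relatedness between new and observed accessions -> prediction = mu
        pred = fit.predict(np.zeros((4, 25)))
        np.testing.assert_allclose(pred, fit.mu, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ng.gblup_fit(np.eye(4), np.ones(5) + np.arange(5))

    def test_equivalence_with_rrblup(self):
        """gBLUP on K = ZZ'/c reproduces rrBLUP predictions to 1e-6."""
        cfg = ng.SimConfig(n_accessions=120, n_markers=300, n_causal=30,
                           heritability=0.8, seed=3)
        table = ng.simulate_genotypes(cfg)
        pheno, _ = ng.simulate_phenotypes(table, cfg)
        y = np.asarray([pheno.values[a] for a in table.accessions])
        Z = ng.to_dosage(table).Z
        Ztr, Zte, ytr = Z[:100], Z[100:], y[:100]
        c = float(Ztr.shape[1])
        pred_rr = ng.rrblup_fit(Ztr, ytr).predict(Zte)
        gb = ng.gblup_fit(Ztr @ Ztr.T / c, ytr)
        pred_gb = gb.predict(Zte @ Ztr.T / c)
        np.testing.assert_allclose(pred_rr, pred_gb, atol=1e-6)

    def test_accession_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        Z = rng.integers(0, 3, size=(30, 50)).astype(float)
        y = Z @ rng.normal(size=50) * 0.2 + rng.normal(size=30)
        perm = rng.permutation(30)
        K = ng.grm(Z)
        f1 = ng.gblup_fit(K, y)
        f2 = ng.gblup_fit(K[np.ix_(perm, perm)], y[perm])
        np.testing.assert_allclose(
            f1.effects[perm], f2.effects, atol=1e-6
        )

    def test_simulated_prediction_benchmark(self):
        """Held-out PCC >= 0.5 on h2=0.8 additive data, mean of 5 replicates."""
        pccs = []
        for s in range(5):
            cfg = ng.SimConfig(n_accessions=400, n_markers=500, n_causal=30,
                               heritability=0.8, seed=s)
            table = ng.simulate_genotypes(cfg)
            pheno, _ = ng.simulate_phenotypes(table, cfg)
            y = np.asarray([pheno.values[a] for a in table.accessions])
            Z = ng.to_dosage(table).Z
            split = ng.make_split(len(y), seed=s)
            tr, te = list(split.train_indices), list(split.test_indices)
            est = ng.GBLUPRegressor().fit(Z[tr], y[tr])
            pccs.append(ng.pcc(est.predict(Z[te]), y[te]))
        assert np.mean(pccs) >= 0.5

    def test_linear_baseline_beats_cnn_at_small_n(self):
        """On small-n additive data the linear mixed model outperforms the CNN."""
        cfg = ng.SimConfig(n_accessions=100, n_markers=200, n_causal=20,
                           heritability=0.8, seed=21)
        table = ng.simulate_genotypes(cfg)
        pheno, _ = ng.simulate_phenotypes(table, cfg)
        y = np.asarray([pheno.values[a] for a in table.accessions])
        Z = ng.to_dosage(table).Z
        X = ng.build_tensor(table, "SV6").data
        split = ng.make_split(len(y), seed=0)
        tr, te = list(split.train_indices), list(split.test_indices)
        rr_pcc = ng.pcc(ng.rrblup_fit(Z[tr], y[tr]).predict(Z[te]), y[te])
        spec = ng.ModelSpec(max_epochs=40)
        m = ng.build_and_fit(spec, (X[tr[:60]], y[tr[:60]]),
                             (X[tr[60:]], y[tr[60:]]), seed=0)
        cnn_pred = ng.predict(m, X[te])
        cnn_pcc = (
            ng.pcc(cnn_pred, y[te]) if np.ptp(cnn_pred) > 0 else 0.0
        )
        assert rr_pcc > cnn_pcc


class TestSklearnEstimators:
    def test_rrblup_estimator_attributes(self):
        rng = np.random.default_rng(9)
        Z = rng.integers(0, 3, size=(50, 30)).astype(float)
        y = Z @ rng.normal(size=30) * 0.3 + rng.normal(size=50)
        est = ng.RRBLUPRegressor().fit(Z, y)
        assert est.coef_.shape == (30,)
        assert est.sigma2_u_ >= 0 and est.sigma2_e_ >= 0
        assert est.lambda_ == pytest.approx(est.sigma2_e_ / est.sigma2_u_)

    def test_estimators_clone_and_score(self):
        from sklearn.base import clone

        rng = np.random.default_rng(10)
        Z = rng.integers(0, 3, size=(60, 40)).astype(float)
        y = Z @ rng.normal(size=40) * 0.3 + rng.normal(size=60)
        for est in [ng.RRBLUPRegressor(), ng.GBLUPRegressor()]:
            c = clone(est).fit(Z[:50], y[:50])
            assert np.isfinite(c.score(Z[50:], y[50:]))
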