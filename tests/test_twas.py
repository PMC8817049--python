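"""Summary-statistics association machinery: harmonization rules, burden
identities, permutation degeneracies, added-last reductions, GReX."""

import numpy as np
import pandas as pd
import pytest

from medtwas import twas
from medtwas.simulate import SimConfig, simulate_genotypes
from medtwas.train import ExpressionModel
from medtwas.twas import (
    UntestableError,
    added_last,
    burden_z,
    grex_assoc,
    harmonize,
    impute_grex,
    ld_matrix,
    permutation_test,
)


def _model(weights, chrom=1, a1="G", a2="A", cls=None):
    """Weight table on synthetic variant coordinates."""
    m = len(weights)
    wf = pd.DataFrame({
        "variant": [f"snp_0_{i}" for i in range(m)],
        "chrom": chrom,
        "pos": [1 + i * 1000 for i in range(m)],
        "a1": a1,
        "a2": a2,
        "weight": weights,
        "cls": cls if cls is not None else ["local"] * m,
        "mediator": "",
    })
    return ExpressionModel(gene="g", method="local", weights=wf)


def _gwas(z, chrom=1, a1="G", a2="A", n=10_000):
    m = len(z)
    return pd.DataFrame({
        "snp": [f"snp_0_{i}" for i in range(m)],
        "chrom": chrom,
        "pos": [1 + i * 1000 for i in range(m)],
        "a1": a1, "a2": a2, "z": z, "n": n,
    })


def _ref(sigma, chrom=1, a1="G", a2="A"):
    m = sigma.shape[0]
    tab = pd.DataFrame({
        "id": [f"snp_0_{i}" for i in range(m)],
        "chrom": chrom,
        "pos": [1 + i * 1000 for i in range(m)],
        "a1": a1, "a2": a2,
    })
    return twas.LDReference(variants=tab, sigma=np.asarray(sigma, float), shrink=0.0)


class TestBurden:
    def test_unit_weight_identity_ld(self):
        zt, p = burden_z([0, 1, 0], [1.5, -2.2, 0.3], np.eye(3))
        assert zt == pytest.approx(-2.2)

    def test_perfect_ld_closed_form(self):
        zt, _ = burden_z([1, 1], [2, 2], np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert zt == pytest.approx(2.0)

    def test_zero_variance_untestable(self):
        with pytest.raises(UntestableError):
            burden_z([0.0, 0.0], [1.0, 1.0], np.eye(2))


class TestHarmonize:
    def test_identical_panels_no_flips(self):
        model = _model([0.5, -0.3, 0.2])
        h = harmonize(model, _gwas([1.0, 2.0, 3.0]), _ref(np.eye(3)))
        assert h.n_flipped == 0 and h.n_dropped == 0
        np.testing.assert_allclose(h.z, [1.0, 2.0, 3.0])

    def test_swapped_alleles_flip_z_but_not_burden(self):
        model = _model([0.5, -0.3, 0.2])
        ref = _ref(np.eye(3))
        h1 = harmonize(model, _gwas([1.0, 2.0, 3.0]), ref)
        h2 = harmonize(model, _gwas([-1.0, -2.0, -3.0], a1="A", a2="G"), ref)
        assert h2.n_flipped == 3
        assert burden_z(h1.w, h1.z, h1.sigma)[0] == pytest.approx(
            burden_z(h2.w, h2.z, h2.sigma)[0])

    def test_ambiguous_variant_dropped_and_counted(self):
        model = _model([0.5, 0.5], a1="A", a2="T")
        h = None
        with pytest.raises(UntestableError):
            # every variant ambiguous -> nothing matched
            harmonize(model, _gwas([1.0, 1.0], a1="A", a2="T"), _ref(np.eye(2), a1="A", a2="T"))

    def test_low_coverage_skipped(self):
        model = _model([1.0, 0.0, 0.0])
        model.weights.loc[0, "pos"] = 999_999_999  # unmatched heavy weight
        with pytest.raises(UntestableError, match="weight mass"):
            harmonize(model, _gwas([1.0, 2.0, 3.0]), _ref(np.eye(3)))


class TestPermutation:
    def test_single_snp_degenerate_p_one(self):
        p = permutation_test(np.array([0.7]), np.array([5.0]), np.eye(1), B=200)
        assert p == 1.0

    def test_exchangeable_null_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for i in range(200):
            w = rng.standard_normal(8)
            z = rng.standard_normal(8)
            pvals.append(permutation_test(w, z, np.eye(8), B=199, seed=i))
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_diffuse_weights_on_single_big_hit(self):
        """One huge GWAS SNP with diffuse weights: burden p tiny but the
        permutation p stays large — the expression weights add nothing."""
        m = 20
        rng = np.random.default_rng(3)
        w = rng.normal(1.0, 0.05, m)
        w[7] = 0.8  # the huge GWAS hit carries the smallest weight
        z = np.zeros(m)
        z[7] = 30.0
        _, p_burden = burden_z(w, z, np.eye(m))
        p_perm = permutation_test(w, z, np.eye(m), B=499, seed=1)
        assert p_burden < 1e-6
        assert p_perm > 0.5


class TestAddedLast:
    def test_independent_loci_reduce_to_marginal(self):
        w_l, w_d = np.array([1.0, 0.5]), np.array([0.8])
        z_l, z_d = np.array([1.0, 2.0]), np.array([3.0])
        s_ll, s_dd = np.eye(2), np.eye(1)
        s_dl = np.zeros((1, 2))
        stat, _ = added_last(w_l, w_d, z_l, z_d, s_ll, s_dd, s_dl)
        marginal = (w_d @ z_d) / np.sqrt(w_d @ s_dd @ w_d)
        assert stat == pytest.approx(marginal)

    def test_full_collinearity_untestable(self):
        w_l = np.array([1.0])
        w_d = np.array([2.0])
        s = np.array([[1.0]])
        with pytest.raises(UntestableError):
            added_last(w_l, w_d, np.array([1.0]), np.array([2.0]), s, 4 * s / 4, 2 * s / np.sqrt(4))

    def test_empty_distal_untestable(self):
        with pytest.raises(UntestableError):
            added_last(np.array([1.0]), np.array([]), np.array([1.0]),
                       np.array([]), np.eye(1), np.empty((0, 0)), np.empty((0, 1)))


class TestGrex:
    def test_zero_weights_zero_grex(self):
        cfg = SimConfig(n_blocks=1, variants_per_block=3, n_genes=1,
                        n_mediators=1, seed=1)
        g = simulate_genotypes(cfg, 50, seed=1)
        model = _model([0.0, 0.0, 0.0])
        grex, cov = impute_grex(g, model)
        np.testing.assert_allclose(grex, 0.0)

    def test_training_cohort_r2_consistency(self, small_bundle):
        from medtwas import qtl, train
        b = small_bundle
        feat = b.expression.features.iloc[0]
        yr, _ = qtl.residualize(b.expression.values[:, 0], b.covariates)
        model = train.train_local("gene_0", b.expression.values[:, 0],
                                  b.genotypes, int(feat["chrom"]), int(feat["pos"]),
                                  b.covariates, seed=0, compute_h2=False)
        grex, cov = impute_grex(b.genotypes, model)
        assert cov == pytest.approx(1.0)
        # in-sample squared correlation equals the model's own prediction R2
        pred = model.predict(b.genotypes.standardized(), list(b.genotypes.variants["id"]))
        np.testing.assert_allclose(grex, pred, atol=1e-8)

    def test_portability_to_second_cohort(self, small_bundle):
        """Weights trained in cohort 1 predict expression in an independent
        cohort simulated from the same variant panel and truth."""
        from medtwas import qtl, train
        from medtwas.simulate import simulate_genotypes as sg
        b = small_bundle
        cfg2 = SimConfig(**{**vars(b.config), "seed": 999})
        geno2 = sg(cfg2, 400, seed=999)
        from medtwas.simulate import simulate_mediators, simulate_expression, TruthLedger
        med2, truth2 = simulate_mediators(geno2, cfg2, seed=1000)
        expr2, truth2 = simulate_expression(geno2, med2, cfg2, truth2, seed=1001)
        feat = b.expression.features.iloc[0]
        ma = __import__("medtwas").qtl.mediator_gene_assoc(b.mediators, b.expression, b.covariates)
        model = train.metwas_train("gene_0", b.expression.values[:, 0],
                                   b.genotypes, b.mediators, ma,
                                   int(feat["chrom"]), int(feat["pos"]),
                                   b.covariates, seed=0, compute_h2=False)
        grex2, cov = impute_grex(geno2, model)
        assert cov == pytest.approx(1.0)
        assert np.std(grex2) > 0

    def test_sign_coherence_under_allele_flip(self, small_bundle):
        from medtwas import train
        b = small_bundle
        feat = b.expression.features.iloc[0]
        model = train.train_local("gene_0", b.expression.values[:, 0],
                                  b.genotypes, int(feat["chrom"]), int(feat["pos"]),
                                  seed=0, compute_h2=False)
        ref = ld_matrix(b.ref_genotypes)
        h1 = harmonize(model, b.sumstats, ref)
        flipped = b.sumstats.copy()
        flipped[["a1", "a2"]] = flipped[["a2", "a1"]].to_numpy()
        flipped["z"] = -flipped["z"]
        h2 = harmonize(model, flipped, ref)
        assert burden_z(h1.w, h1.z, h1.sigma)[0] == pytest.approx(
            burden_z(h2.w, h2.z, h2.sigma)[0], abs=1e-12)


class TestGrexAssoc:
    def test_effect_recovered_with_coverage(self, rng):
        cover = 0
        for i in range(100):
            r = np.random.default_rng(i)
            grex = r.standard_normal(500)
            y = grex + r.standard_normal(500)
            res = grex_assoc(grex, y)
            cover += res["ci_low"] <= 1.0 <= res["ci_high"]
        assert 88 <= cover <= 99

    def test_permuted_phenotype_null(self, rng):
        pvals = [
            grex_assoc(np.random.default_rng(i).standard_normal(200),
                       np.random.default_rng(1000 + i).standard_normal(200))["p"]
            for i in range(100)
        ]
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_grex_rejected(self):
        with pytest.raises(UntestableError):
            grex_assoc(np.zeros(50), np.random.default_rng(0).standard_normal(50))

    def test_logistic_family(self, rng):
        grex = rng.standard_normal(400)
        p = 1 / (1 + np.exp(-grex))
        y = (rng.random(400) < p).astype(float)
        res = grex_assoc(grex, y, family="logistic")
        assert res["effect"] > 0.5
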